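import numpy as np
import pytest

from clonescan import SimConfig, simulate
from clonescan.io import Alignment, DistanceMatrix, SnpMatrix


@pytest.fixture(scope="session")
def tiny_clonal():
    """Small clonal simulation shared across tests (fast, deterministic)."""
    return simulate(
        SimConfig(
            mode="clonal", N=30, generations=80, mat_codons=12, ptg_codons=12,
            n_snps=40, mu_coding=2e-3, mu_snp=5e-3, omega=0.3, sample_n=8,
            seed=11,
        )
    )


@pytest.fixture
def toy_alignment():
    return Alignment(
        ids=["A", "B", "C"],
        seqs=["ACGTACGTA", "ACGTACGTG", "ACGTACCTA"],
        locus_name="toy",
    )


@pytest.fixture
def toy_distance_matrix():
    vals = np.array(
        [
            [0.0, 0.1, 0.4, 0.5],
            [0.1, 0.0, 0.45, 0.55],
            [0.4, 0.45, 0.0, 0.2],
            [0.5, 0.55, 0.2, 0.0],
        ]
    )
    return DistanceMatrix(["A", "B", "C", "D"], vals)


@pytest.fixture
def toy_snp_matrix():
    """4 isolates x 6 loci with depth/support/coordinates for filter tests.

    locus composition (alleles by isolate order):
      L1 (0,1,0,1)  inside the excluded region
      L2 (0,0,0,1)  minor-allele count 1
      L3 (0,1,1,0)  one call at depth 9 (isolate 2's '1')
      L4 (1,0,1,0)  one call at support exactly 0.8 (isolate 1's '1')
      L5 (0,1,0,1)  clean
      L6 (1,1,0,0)  clean
    """
    alleles = np.array(
        [
            [0, 0, 0, 1, 0, 1],
            [1, 0, 1, 0, 1, 1],
            [0, 0, 1, 1, 0, 0],
            [1, 1, 0, 0, 1, 0],
        ],
        dtype=np.int8,
    )
    depth = np.full((4, 6), 20, dtype=np.int32)
    depth[1, 2] = 9
    support = np.full((4, 6), 0.95)
    support[0, 3] = 0.8
    coords = [
        ("chr1", 100, 101),
        ("chr1", 500, 501),
        ("chr2", 10, 11),
        ("chr2", 50, 51),
        ("chr3", 5, 6),
        ("chr3", 80, 81),
    ]
    return SnpMatrix(
        isolate_ids=["i1", "i2", "i3", "i4"],
        locus_ids=["L1", "L2", "L3", "L4", "L5", "L6"],
        alleles=alleles,
        depth=depth,
        support=support,
        coords=coords,
    )
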