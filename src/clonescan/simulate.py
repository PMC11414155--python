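"""Haploid Wright–Fisher simulator of clonal vs mating-type-constrained
sexual populations.

Each individual carries a mating-type (MAT) coding haplotype, a second
protein-coding locus (a phosphate-transporter-like gene, PTG) and a vector
of unlinked neutral biallelic SNP loci. Coding loci evolve under purifying
selection implemented as biased mutation acceptance: a proposed
non-synonymous change is accepted with probability ``omega``, synonymous
changes always, premature stop codons never. Reproduction is either
strictly clonal (each child copies one parent) or sexual with mating
restricted to parents whose MAT haplotypes differ, followed by free
reassortment of the MAT locus, the PTG locus and every SNP locus.

Under clonality all three datasets record the same genealogy, so their
distance matrices correlate; under sexuality recombination decouples them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._codon_tables import AA, BASES, CODON_INDEX, SENSE_CODONS, STOP_CODONS
from .io import (
    Alignment,
    SnpMatrix,
    write_alignment,
    write_metadata,
    write_snp_matrix,
)

logger = logging.getLogger(__name__)

_BASE_TO_INT = {b: i for i, b in enumerate(BASES)}
_INT_TO_BASE = np.array(list(BASES))


@dataclass
class SimConfig:
    """Parameters of one simulation run.

    Defaults mirror the real study's locus sizes (87 MAT codons = 261 bp
    amplicon, 213 PTG codons = 639 bp CDS) and a genome-wide panel of 2000
    unlinked SNPs; mutation rates are chosen to yield measurable
    polymorphism within a few hundred generations at desk scale.
    """

    mode: str = "clonal"  # "clonal" or "sexual"
    N: int = 200
    generations: int = 500
    mat_codons: int = 87
    ptg_codons: int = 213
    n_snps: int = 2000
    mu_coding: float = 1e-4
    mu_snp: float = 5e-4
    omega: float = 0.3
    sample_n: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("clonal", "sexual"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if not (0 < self.sample_n <= self.N):
            raise ValueError("sample_n must be in [1, N]")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        for name in ("mu_coding", "mu_snp"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0.0 < self.omega <= 1.0):
            raise ValueError("omega must be in (0, 1]")
        if self.mat_codons < 2 or self.ptg_codons < 2:
            raise ValueError("coding loci need at least 2 codons")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")


@dataclass
class SimOutput:
    """The three emitted datasets plus truth metadata."""

    config: SimConfig
    mat_alignment: Alignment
    ptg_alignment: Alignment
    snp_matrix: SnpMatrix
    truth: pd.DataFrame
    clonal_fallback_generations: list[int] = field(default_factory=list)
    genealogy: Optional[np.ndarray] = None  # (generations, N, 2) parent ids


def _random_coding_ancestor(rng: np.random.Generator, n_codons: int) -> np.ndarray:
    """Random stop-free coding haplotype as a base-index vector."""
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    seq = "".join(SENSE_CODONS[i] for i in idx)
    return np.array([_BASE_TO_INT[b] for b in seq], dtype=np.int8)


def _mutate_coding(
    genomes: np.ndarray, mu: float, omega: float, rng: np.random.Generator
) -> None:
    """In-place coding mutation with purifying acceptance bias."""
    N, L = genomes.shape
    k = rng.binomial(N * L, mu)
    if k == 0:
        return
    flat = rng.choice(N * L, size=k, replace=False)
    for f in flat:
        i, pos = divmod(int(f), L)
        old_base = int(genomes[i, pos])
        new_base = (old_base + 1 + int(rng.integers(0, 3))) % 4
        c0 = 3 * (pos // 3)
        codon = genomes[i, c0 : c0 + 3]
        old_codon = "".join(_INT_TO_BASE[codon])
        new_codon = (
            old_codon[: pos - c0]
            + str(_INT_TO_BASE[new_base])
            + old_codon[pos - c0 + 1 :]
        )
        if new_codon in STOP_CODONS:
            continue  # premature stops always rejected
        if AA[new_codon] != AA[old_codon] and rng.random() >= omega:
            continue  # non-synonymous rejected with prob 1-omega
        genomes[i, pos] = new_base


def _mutate_snps(snps: np.ndarray, mu: float, rng: np.random.Generator) -> None:
    N, L = snps.shape
    k = rng.binomial(N * L, mu)
    if k == 0:
        return
    flat = rng.choice(N * L, size=k, replace=False)
    snps.flat[flat] ^= 1


def _random_bits(rng: np.random.Generator, n: int, m: int) -> np.ndarray:
    """Fair-coin boolean matrix (n, m) drawn via packed random bytes."""
    nbytes = (n * m + 7) // 8
    bits = np.unpackbits(np.frombuffer(rng.bytes(nbytes), dtype=np.uint8))
    return bits[: n * m].view(bool).reshape(n, m)


def _haplotype_groups(mat: np.ndarray) -> np.ndarray:
    """Integer group id per row, identical rows sharing an id."""
    seen: dict[bytes, int] = {}
    group = np.empty(mat.shape[0], dtype=np.int64)
    rows = np.ascontiguousarray(mat)
    for i in range(mat.shape[0]):
        key = rows[i].tobytes()
        group[i] = seen.setdefault(key, len(seen))
    return group


def _sexual_parents(
    mat: np.ndarray, N: int, rng: np.random.Generator
) -> Optional[tuple[np.ndarray, np.ndarray]]:
    """Parent pairs with different MAT haplotypes, or None if monomorphic."""
    group = _haplotype_groups(mat)
    if group.max() == 0:
        return None
    p1 = rng.integers(0, N, size=N)
    p2 = rng.integers(0, N, size=N)
    conflict = group[p1] == group[p2]
    while conflict.any():
        p2[conflict] = rng.integers(0, N, size=int(conflict.sum()))
        conflict = group[p1] == group[p2]
    return p1, p2


def simulate(config: SimConfig) -> SimOutput:
    """Run one clonal or sexual Wright–Fisher simulation.

    The population starts monomorphic from a single random stop-free
    ancestor, so every observed polymorphism arises in-run. Identical
    configs produce bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    N = config.N
    Lm, Lp = 3 * config.mat_codons, 3 * config.ptg_codons

    anc_mat = _random_coding_ancestor(rng, config.mat_codons)
    anc_ptg = _random_coding_ancestor(rng, config.ptg_codons)
    anc_snp = rng.integers(0, 2, size=config.n_snps, dtype=np.int8)
    mat = np.tile(anc_mat, (N, 1))
    ptg = np.tile(anc_ptg, (N, 1))
    snp = np.tile(anc_snp, (N, 1))

    fallback: list[int] = []
    genealogy = np.zeros((config.generations, N, 2), dtype=np.int32)

    for gen in range(config.generations):
        if config.mode == "clonal":
            parents = None
        else:
            parents = _sexual_parents(mat, N, rng)
            if parents is None:
                fallback.append(gen)
        if parents is None:
            p = rng.integers(0, N, size=N)
            mat, ptg, snp = mat[p].copy(), ptg[p].copy(), snp[p].copy()
            genealogy[gen, :, 0] = p
            genealogy[gen, :, 1] = p
        else:
            p1, p2 = parents
            coin_mat = rng.integers(0, 2, size=N, dtype=np.uint8).view(bool)
            coin_ptg = rng.integers(0, 2, size=N, dtype=np.uint8).view(bool)
            coin_snp = _random_bits(rng, N, config.n_snps)
            mat = np.where(coin_mat[:, None], mat[p1], mat[p2])
            ptg = np.where(coin_ptg[:, None], ptg[p1], ptg[p2])
            snp = np.where(coin_snp, snp[p1], snp[p2])
            genealogy[gen, :, 0] = p1
            genealogy[gen, :, 1] = p2
        _mutate_coding(mat, config.mu_coding, config.omega, rng)
        _mutate_coding(ptg, config.mu_coding, config.omega, rng)
        _mutate_snps(snp, config.mu_snp, rng)

    if fallback:
        logger.info(
            "sexual mode fell back to clonal in %d generation(s)", len(fallback)
        )

    idx = np.sort(rng.choice(N, size=config.sample_n, replace=False))
    width = max(2, len(str(config.sample_n)))
    ids = [f"iso{k + 1:0{width}d}" for k in range(config.sample_n)]

    def decode(rows: np.ndarray) -> list[str]:
        return ["".join(_INT_TO_BASE[r]) for r in rows]

    mat_aln = Alignment(ids=ids, seqs=decode(mat[idx]), frame=0, locus_name="MAT")
    ptg_aln = Alignment(ids=ids, seqs=decode(ptg[idx]), frame=0, locus_name="PTG")

    # SNP loci laid out on a synthetic contig, well clear of the (separate)
    # MAT/PTG contigs so region exclusion can be exercised explicitly
    coords = [("genome", 100 * k, 100 * k + 1) for k in range(config.n_snps)]
    n_digits = len(str(config.n_snps))
    snp_m = SnpMatrix(
        isolate_ids=ids,
        locus_ids=[f"snp{k + 1:0{n_digits}d}" for k in range(config.n_snps)],
        alleles=snp[idx].astype(np.int8),
        depth=np.full((config.sample_n, config.n_snps), 12, dtype=np.int32),
        support=np.ones((config.sample_n, config.n_snps)),
        coords=coords,
    )

    # MAT haplotype group of each sampled isolate, as truth metadata
    mat_group = _haplotype_groups(mat[idx])
    truth = pd.DataFrame(
        {
            "isolate_id": ids,
            "species": "simulated",
            "origin": f"sim-{config.mode}",
            "mat_type": [f"H{g + 1}" for g in mat_group],
            "population_index": idx,
        }
    )
    return SimOutput(
        config=config,
        mat_alignment=mat_aln,
        ptg_alignment=ptg_aln,
        snp_matrix=snp_m,
        truth=truth,
        clonal_fallback_generations=fallback,
        genealogy=genealogy,
    )


FIXTURES = {
    "tiny": dict(
        N=20,
        generations=60,
        mat_codons=10,
        ptg_codons=10,
        n_snps=30,
        mu_coding=2e-3,
        mu_snp=5e-3,
        sample_n=6,
    ),
    "paper_like": dict(
        N=200,
        generations=500,
        mat_codons=87,
        ptg_codons=213,
        n_snps=2000,
        mu_coding=1e-4,
        mu_snp=5e-4,
        sample_n=27,
    ),
}


def make_fixture(
    name: str, seed: int, outdir=None, mode: str = "clonal"
) -> SimOutput:
    """Simulate a named fixture and optionally write its three datasets.

    ``tiny`` is a 6-isolate fast unit-test fixture; ``paper_like`` mirrors
    the real study's shape (27 isolates, ~2000 SNP loci, full-size coding
    loci).
    """
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    config = SimConfig(mode=mode, seed=seed, **FIXTURES[name])
    out = simulate(config)
    if outdir is not None:
        outdir = Path(str(outdir))
        outdir.mkdir(parents=True, exist_ok=True)
        write_alignment(out.mat_alignment, outdir / "mat.fasta")
        write_alignment(out.ptg_alignment, outdir / "ptg.fasta")
        write_snp_matrix(out.snp_matrix, outdir / "snps.tsv")
        write_metadata(
            out.truth.drop(columns=["population_index"]),
            outdir / "metadata.tsv",
        )
    return out
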