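"""Pairwise divergence measures.

Tamura 3-parameter and p-distance on nucleotide alignments (pairwise
deletion of gapped/ambiguous columns), quality filtering of SNP genotype
matrices, and binary Jaccard distance between isolates' SNP profiles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io import DEPTH_UNKNOWN, MISSING, Alignment, DistanceMatrix, SnpMatrix

logger = logging.getLogger(__name__)

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}


class SaturatedPairError(ValueError):
    """Divergence too large for the distance correction; carries pair labels."""

    def __init__(self, message: str, pairs: Optional[list] = None):
        super().__init__(message)
        self.pairs = pairs or []


@dataclass
class PairCounts:
    """Transition/transversion counts for one sequence pair.

    ``theta`` is the G+C fraction pooled over both sequences at the usable
    (unambiguous, ungapped in both) sites.
    """

    usable_sites: int
    transitions: int
    transversions: int
    theta: float


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


_LUT = np.zeros(256, dtype=np.int8)
for ch, code in _ENC.items():
    _LUT[ord(ch)] = code
_IS_BASE = np.zeros(256, dtype=bool)
for ch in "ACGT":
    _IS_BASE[ord(ch)] = True
_IS_GC = np.zeros(256, dtype=bool)
for ch in "GC":
    _IS_GC[ord(ch)] = True
_IS_PURINE = np.zeros(256, dtype=bool)
for ch in "AG":
    _IS_PURINE[ord(ch)] = True


def pair_counts(a: str, b: str) -> PairCounts:
    """Count transitions (A<->G, C<->T), transversions and pooled GC over the
    columns where both sequences carry an unambiguous base."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    xa, xb = _encode(a), _encode(b)
    usable = _IS_BASE[xa] & _IS_BASE[xb]
    n_use = int(usable.sum())
    if n_use == 0:
        raise ValueError("no comparable sites")
    ua, ub = xa[usable], xb[usable]
    diff = ua != ub
    transitions = int((diff & (_IS_PURINE[ua] == _IS_PURINE[ub])).sum())
    transversions = int(diff.sum()) - transitions
    gc = int(_IS_GC[ua].sum() + _IS_GC[ub].sum())
    return PairCounts(
        usable_sites=n_use,
        transitions=transitions,
        transversions=transversions,
        theta=gc / (2 * n_use),
    )


def tamura3p_from_counts(
    counts: PairCounts, labels: tuple[str, str] = ("a", "b")
) -> float:
    """Tamura (1992) 3-parameter distance from pair counts."""
    P = counts.transitions / counts.usable_sites
    Q = counts.transversions / counts.usable_sites
    if P == 0.0 and Q == 0.0:
        return 0.0
    theta = counts.theta
    h = 2.0 * theta * (1.0 - theta)
    if h == 0.0 and P > 0.0:
        raise SaturatedPairError(
            f"saturated pair {labels}: h = 0 with transitions present",
            pairs=[labels],
        )
    arg1 = 1.0 - (P / h if h > 0 else 0.0) - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0.0 or arg2 <= 0.0:
        raise SaturatedPairError(
            f"saturated pair {labels}: log argument <= 0 (P={P:.4f}, Q={Q:.4f})",
            pairs=[labels],
        )
    return -h * math.log(arg1) - 0.5 * (1.0 - h) * math.log(arg2)


def tamura3p(a: str, b: str, labels: tuple[str, str] = ("a", "b")) -> float:
    """Tamura 3-parameter distance (substitutions/site) for one pair."""
    return tamura3p_from_counts(pair_counts(a, b), labels)


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites over the pairwise-usable columns."""
    c = pair_counts(a, b)
    return (c.transitions + c.transversions) / c.usable_sites


def alignment_distance_matrix(
    aln: Alignment, model: str = "tamura3p"
) -> DistanceMatrix:
    """All-pairs distance matrix under the requested model.

    Saturated pairs abort with an error listing every offending pair rather
    than propagating NaN into downstream permutation tests.
    """
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    if model not in ("tamura3p", "p_distance"):
        raise ValueError(f"unknown model {model!r}")
    n = aln.n
    values = np.zeros((n, n))
    saturated: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                if model == "tamura3p":
                    d = tamura3p(
                        aln.seqs[i], aln.seqs[j], (aln.ids[i], aln.ids[j])
                    )
                else:
                    d = p_distance(aln.seqs[i], aln.seqs[j])
            except SaturatedPairError:
                saturated.append((aln.ids[i], aln.ids[j]))
                continue
            values[i, j] = values[j, i] = d
    if saturated:
        raise SaturatedPairError(
            f"saturated pairs in {aln.locus_name or 'alignment'}: {saturated}",
            pairs=saturated,
        )
    return DistanceMatrix(list(aln.ids), values)


# ---------------------------------------------------------------------------
# SNP filtering and Jaccard distance


def _overlaps(coord, regions: Sequence[tuple[str, int, int]]) -> bool:
    if coord is None:
        return False
    contig, start, end = coord
    for rc, rs, re_ in regions:
        if contig == rc and start < re_ and rs < end:
            return True
    return False


def filter_snp_matrix(
    m: SnpMatrix,
    min_depth: int = 10,
    min_support: float = 0.8,
    exclude_regions: Optional[Sequence[tuple[str, int, int]]] = None,
    min_allele_count: int = 2,
    max_obs_het: float = 0.0,
    return_report: bool = False,
):
    """Quality-filter a SNP matrix.

    Genotype-level: calls with depth < ``min_depth`` or support <=
    ``min_support`` (strict, i.e. support must exceed the threshold) become
    missing; both rules are skipped with a warning when the input carries no
    depth/support metadata (genepop dialect). Locus-level: loci overlapping
    ``exclude_regions``, loci whose minor-allele count over non-missing
    isolates falls below ``min_allele_count``, and loci with within-isolate
    heterozygosity above ``max_obs_het`` are dropped (the last is vacuous for
    haploid single-call input and exists for multi-call data). Idempotent.
    """
    alleles = m.alleles.copy()
    depth = m.depth.copy()
    support = m.support.copy()
    report = {
        "cells_failed_depth": 0,
        "cells_failed_support": 0,
        "loci_in_excluded_regions": 0,
        "loci_below_min_allele_count": 0,
        "loci_above_max_obs_het": 0,
        "loci_in": len(m.locus_ids),
        "loci_out": 0,
    }

    called = alleles != MISSING
    has_depth = depth != DEPTH_UNKNOWN
    if called.any() and not has_depth[called].any():
        logger.warning("no depth metadata: depth filter skipped")
    else:
        bad = called & has_depth & (depth < min_depth)
        report["cells_failed_depth"] = int(bad.sum())
        alleles[bad] = MISSING

    called = alleles != MISSING
    has_support = ~np.isnan(support)
    if called.any() and not has_support[called].any():
        logger.warning("no support metadata: support filter skipped")
    else:
        bad = called & has_support & (support <= min_support)
        report["cells_failed_support"] = int(bad.sum())
        alleles[bad] = MISSING

    keep = np.ones(len(m.locus_ids), dtype=bool)
    if exclude_regions:
        if m.coords is None:
            logger.warning("no locus coordinates: region exclusion skipped")
        else:
            for k, coord in enumerate(m.coords):
                if _overlaps(coord, exclude_regions):
                    keep[k] = False
            report["loci_in_excluded_regions"] = int((~keep).sum())

    called = alleles != MISSING
    n1 = ((alleles == 1) & called).sum(axis=0)
    n0 = ((alleles == 0) & called).sum(axis=0)
    mac = np.minimum(n0, n1)
    low_mac = keep & (mac < min_allele_count)
    report["loci_below_min_allele_count"] = int(low_mac.sum())
    keep &= ~low_mac

    # single-call haploid genotypes have zero within-isolate heterozygosity,
    # so nothing can exceed max_obs_het >= 0 here
    report["loci_above_max_obs_het"] = 0

    out = SnpMatrix(
        isolate_ids=list(m.isolate_ids),
        locus_ids=[l for l, k in zip(m.locus_ids, keep) if k],
        alleles=alleles[:, keep],
        depth=depth[:, keep],
        support=support[:, keep],
        coords=None
        if m.coords is None
        else [c for c, k in zip(m.coords, keep) if k],
    )
    report["loci_out"] = len(out.locus_ids)
    if report["loci_out"] == 0:
        logger.warning("SNP filter removed every locus")
    logger.info("SNP filter report: %s", report)
    if return_report:
        return out, report
    return out


def jaccard_distance_matrix(m: SnpMatrix) -> DistanceMatrix:
    """Binary Jaccard distance between isolates over shared non-missing loci.

    Shared absence (allele 0 in both isolates) is non-informative. A pair
    with no informative loci (denominator 0) gets distance 0 with a warning;
    a pair with no shared non-missing loci at all is an error.
    """
    n = len(m.isolate_ids)
    values = np.zeros((n, n))
    A = m.alleles
    called = A != MISSING
    for i in range(n):
        for j in range(i + 1, n):
            both = called[i] & called[j]
            if not both.any():
                raise ValueError(
                    f"no common non-missing loci for pair "
                    f"({m.isolate_ids[i]!r}, {m.isolate_ids[j]!r})"
                )
            ai, aj = A[i][both], A[j][both]
            a = int(((ai == 1) & (aj == 1)).sum())
            bc = int((ai != aj).sum())
            if a + bc == 0:
                logger.warning(
                    "pair (%s, %s): no informative loci, distance set to 0",
                    m.isolate_ids[i],
                    m.isolate_ids[j],
                )
                d = 0.0
            else:
                d = bc / (a + bc)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(list(m.isolate_ids), values)
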