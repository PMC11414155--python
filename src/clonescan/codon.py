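"""Codon-level selection and codon-usage statistics.

Implements the Nei–Gojobori (1986) method: per-codon synonymous and
non-synonymous site counting (stop mutants excluded from the per-position
fraction), equal-weight averaging of difference counts over all stop-free
minimal mutational pathways, Jukes–Cantor correction, and the codon-based
Z-test of strict neutrality with variances obtained by bootstrapping codon
columns. Also the codon adaptation index (CAI) over a reference codon-usage
table and its null-expected threshold (eCAI) from amino-acid- and
composition-matched random sequences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from ._codon_tables import (
    AA,
    CODON_INDEX,
    CODONS,
    FAMILIES,
    NONSYN_DIFFS,
    NONSYN_SITES,
    SENSE_CODONS,
    STOP_CODONS,
    SYN_DIFFS,
    SYN_SITES,
    encode_codons,
)
from .io import Alignment

logger = logging.getLogger(__name__)


class SaturationError(ValueError):
    """Observed proportion of differences too large for the JC correction."""


def codon_sites(codon: str) -> tuple[float, float]:
    """Synonymous and non-synonymous site counts of one sense codon.

    The two counts always total 3: each position contributes one site,
    partitioned by the fraction of its non-stop single-base mutants that are
    synonymous.
    """
    codon = codon.upper()
    if codon not in CODON_INDEX:
        raise ValueError(f"not a codon: {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site decomposition")
    i = CODON_INDEX[codon]
    return float(SYN_SITES[i]), float(NONSYN_SITES[i])


def codon_pair_differences(a: str, b: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) difference counts between two sense
    codons, averaged over all stop-free minimal mutational pathways."""
    a, b = a.upper(), b.upper()
    for c in (a, b):
        if c not in CODON_INDEX:
            raise ValueError(f"not a codon: {c!r}")
        if c in STOP_CODONS:
            raise ValueError(f"stop codon {c}")
    i, j = CODON_INDEX[a], CODON_INDEX[b]
    return float(SYN_DIFFS[i, j]), float(NONSYN_DIFFS[i, j])


def _jukes_cantor(p: float, what: str = "p") -> float:
    if p >= 0.75:
        raise SaturationError(f"saturated: {what} = {p:.4f} >= 3/4")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _check_coding(seq: str, name: str, allow_terminal_stop: bool = True) -> None:
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence {name!r} length {len(seq)} not divisible by 3")
    n_codons = len(seq) // 3
    for k in range(n_codons):
        cod = seq[3 * k : 3 * k + 3]
        if cod in STOP_CODONS:
            if allow_terminal_stop and k == n_codons - 1:
                continue
            raise ValueError(f"internal stop codon {cod} at codon {k + 1} in {name!r}")


def nei_gojobori_pair(a: str, b: str) -> tuple[float, float, float, float]:
    """Nei–Gojobori proportions and JC-corrected distances for one pair.

    Returns ``(pN, pS, dN, dS)``. Codon columns where either sequence has a
    gap or ambiguous base are excluded pairwise.
    """
    a, b = a.upper(), b.upper()
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    _check_coding(a, "a")
    _check_coding(b, "b")
    xa, xb = encode_codons(a), encode_codons(b)
    valid = (xa >= 0) & (xb >= 0)
    valid &= ~np.isin(xa, list(map(CODON_INDEX.get, STOP_CODONS)))
    valid &= ~np.isin(xb, list(map(CODON_INDEX.get, STOP_CODONS)))
    if not valid.any():
        raise ValueError("no comparable codon columns")
    xa, xb = xa[valid], xb[valid]
    S = float((SYN_SITES[xa] + SYN_SITES[xb]).sum()) / 2.0
    N = float((NONSYN_SITES[xa] + NONSYN_SITES[xb]).sum()) / 2.0
    sd = float(SYN_DIFFS[xa, xb].sum())
    nd = float(NONSYN_DIFFS[xa, xb].sum())
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    return pN, pS, _jukes_cantor(pN, "pN"), _jukes_cantor(pS, "pS")


@dataclass
class CodonSelectionResult:
    """Pair-averaged dN/dS with bootstrap variances and the neutrality Z."""

    dN: float
    dS: float
    var_dN: float
    var_dS: float
    z: float
    p_positive: float
    p_purifying: float
    n_boot: int
    n_pairs: int
    seed: Optional[int] = None
    undefined: bool = False

    def to_dict(self) -> dict:
        return {
            "dN": self.dN,
            "dS": self.dS,
            "var_dN": self.var_dN,
            "var_dS": self.var_dS,
            "z": None if self.undefined else self.z,
            "p_positive": None if self.undefined else self.p_positive,
            "p_purifying": None if self.undefined else self.p_purifying,
            "n_boot": self.n_boot,
            "n_pairs": self.n_pairs,
            "seed": self.seed,
            "undefined": self.undefined,
        }


def _codon_matrix(aln: Alignment) -> np.ndarray:
    """Codon-index matrix (n_seqs x n_codons) from an in-frame alignment.

    Terminal stop columns (stop in any sequence at the last codon) are
    dropped; internal stops raise.
    """
    if aln.frame is None:
        raise ValueError("alignment has no frame annotation")
    usable = aln.length - aln.frame
    n_codons = usable // 3
    if n_codons < 2:
        raise ValueError("alignment shorter than 2 codons")
    rows = []
    stop_idx = set(CODON_INDEX[c] for c in STOP_CODONS)
    for rid, s in zip(aln.ids, aln.seqs):
        sub = s[aln.frame : aln.frame + 3 * n_codons]
        enc = encode_codons(sub)
        internal = [k for k in range(n_codons - 1) if enc[k] in stop_idx]
        if internal:
            raise ValueError(
                f"internal stop codon at codon {internal[0] + 1} in {rid!r}"
            )
        rows.append(enc)
    X = np.vstack(rows)
    if np.isin(X[:, -1], list(stop_idx)).any():
        X = X[:, :-1]
        logger.info("terminal stop codon column dropped")
    return X


def _pair_column_stats(X: np.ndarray):
    """Per-pair, per-column site and difference arrays for bootstrap reuse."""
    n = X.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    P = len(pairs)
    C = X.shape[1]
    s_sites = np.zeros((P, C))
    n_sites = np.zeros((P, C))
    sd = np.zeros((P, C))
    nd = np.zeros((P, C))
    for p, (i, j) in enumerate(pairs):
        xi, xj = X[i], X[j]
        valid = (xi >= 0) & (xj >= 0)
        v = np.flatnonzero(valid)
        s_sites[p, v] = (SYN_SITES[xi[v]] + SYN_SITES[xj[v]]) / 2.0
        n_sites[p, v] = (NONSYN_SITES[xi[v]] + NONSYN_SITES[xj[v]]) / 2.0
        sd[p, v] = SYN_DIFFS[xi[v], xj[v]]
        nd[p, v] = NONSYN_DIFFS[xi[v], xj[v]]
    return s_sites, n_sites, sd, nd


def _pair_mean_d(s_sites, n_sites, sd, nd, w=None) -> tuple[float, float]:
    """Pair-averaged (dN, dS) given optional column resampling weights."""
    if w is None:
        S = s_sites.sum(axis=1)
        N = n_sites.sum(axis=1)
        Sd = sd.sum(axis=1)
        Nd = nd.sum(axis=1)
    else:
        S = s_sites @ w
        N = n_sites @ w
        Sd = sd @ w
        Nd = nd @ w
    with np.errstate(invalid="ignore", divide="ignore"):
        pS = np.where(S > 0, Sd / np.maximum(S, 1e-300), 0.0)
        pN = np.where(N > 0, Nd / np.maximum(N, 1e-300), 0.0)
    if np.any(pS >= 0.75) or np.any(pN >= 0.75):
        raise SaturationError("saturated pair in pair-averaged d")
    dS = -0.75 * np.log1p(-4.0 * pS / 3.0)
    dN = -0.75 * np.log1p(-4.0 * pN / 3.0)
    return float(dN.mean()), float(dS.mean())


def codon_selection_test(
    aln: Alignment, n_boot: int = 999, seed: Optional[int] = None
) -> CodonSelectionResult:
    """Codon-based Z-test of strict neutrality, averaged over sequence pairs.

    Variances of the pair-averaged dN and dS are estimated by resampling
    codon columns with replacement (``n_boot`` replicates). The Z statistic
    is ``(dN - dS) / sqrt(Var(dN) + Var(dS))``; ``p_purifying`` is the lower
    tail P(Z_null <= Z) and ``p_positive`` the upper tail under N(0,1).
    """
    X = _codon_matrix(aln)
    n, C = X.shape
    if n < 2:
        raise ValueError("need at least 2 sequences")
    s_sites, n_sites, sd, nd = _pair_column_stats(X)
    dN, dS = _pair_mean_d(s_sites, n_sites, sd, nd)

    rng = np.random.default_rng(seed)
    reps_N, reps_S = [], []
    skipped = 0
    for _ in range(n_boot):
        counts = np.bincount(rng.integers(0, C, size=C), minlength=C).astype(float)
        try:
            bN, bS = _pair_mean_d(s_sites, n_sites, sd, nd, counts)
        except SaturationError:
            skipped += 1
            continue
        reps_N.append(bN)
        reps_S.append(bS)
    if skipped:
        logger.warning("bootstrap: %d saturated replicates skipped", skipped)
    var_dN = float(np.var(reps_N, ddof=1)) if len(reps_N) > 1 else 0.0
    var_dS = float(np.var(reps_S, ddof=1)) if len(reps_S) > 1 else 0.0

    denom = var_dN + var_dS
    if denom <= 0:
        return CodonSelectionResult(
            dN, dS, var_dN, var_dS, math.nan, math.nan, math.nan,
            n_boot, s_sites.shape[0], seed, undefined=True,
        )
    z = (dN - dS) / math.sqrt(denom)
    return CodonSelectionResult(
        dN=dN,
        dS=dS,
        var_dN=var_dN,
        var_dS=var_dS,
        z=z,
        p_positive=float(stats.norm.sf(z)),
        p_purifying=float(stats.norm.cdf(z)),
        n_boot=n_boot,
        n_pairs=s_sites.shape[0],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Codon usage / CAI


@dataclass
class CodonUsageTable:
    """Per-codon counts from a reference CDS collection and the derived
    relative adaptiveness w = count / max count within the synonymous family.

    Codons unobserved in the reference receive a pseudo-count of 0.5 before
    w is computed.
    """

    counts: dict[str, float]
    w: dict[str, float]

    @classmethod
    def from_counts(cls, counts: dict[str, float]) -> "CodonUsageTable":
        full = {c: float(counts.get(c, 0.0)) for c in SENSE_CODONS}
        n_zero = sum(1 for v in full.values() if v == 0.0)
        if n_zero:
            logger.info("pseudo-count 0.5 applied to %d unobserved codons", n_zero)
        adj = {c: (v if v > 0 else 0.5) for c, v in full.items()}
        w = {}
        for fam in FAMILIES.values():
            fam_max = max(adj[c] for c in fam)
            for c in fam:
                w[c] = adj[c] / fam_max
        return cls(counts=full, w=w)


def build_codon_usage(cds_collection: Iterable[str]) -> CodonUsageTable:
    """Pool codon counts over a collection of coding sequences."""
    counts: dict[str, float] = {c: 0.0 for c in SENSE_CODONS}
    n_seqs = 0
    for k, seq in enumerate(cds_collection):
        seq = seq.upper().replace("U", "T")
        if len(seq) % 3 != 0:
            raise ValueError(
                f"sequence #{k} length {len(seq)} not divisible by 3"
            )
        n_seqs += 1
        for i in range(0, len(seq), 3):
            cod = seq[i : i + 3]
            if cod in counts:
                counts[cod] += 1.0
    if n_seqs == 0:
        raise ValueError("empty CDS collection")
    return CodonUsageTable.from_counts(counts)


#: single-codon families carry no usage information for CAI
_CAI_EXCLUDED = {"ATG", "TGG"} | set(STOP_CODONS)


def _included_codons(seq: str) -> list[str]:
    seq = seq.upper().replace("U", "T")
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        cod = seq[i : i + 3]
        if cod in _CAI_EXCLUDED or cod not in CODON_INDEX:
            continue
        out.append(cod)
    return out


def cai(seq: str, table: CodonUsageTable) -> float:
    """Codon adaptation index: geometric mean of w over informative codons
    (Met, Trp and stop codons excluded)."""
    cods = _included_codons(seq)
    if not cods:
        raise ValueError("no informative codons for CAI")
    logw = [math.log(table.w[c]) for c in cods]
    return math.exp(sum(logw) / len(logw))


@dataclass
class EcaiResult:
    cai: float
    ecai: float
    p: float
    null_q95: float
    n_random: int
    seed: Optional[int]

    def to_dict(self) -> dict:
        return {
            "cai": self.cai,
            "ecai": self.ecai,
            "p": self.p,
            "null_q95": self.null_q95,
            "n_random": self.n_random,
            "seed": self.seed,
        }


def ecai_threshold(
    seq: str,
    table: CodonUsageTable,
    n_random: int = 500,
    seed: Optional[int] = None,
) -> EcaiResult:
    """Null-expected CAI controlling for amino-acid and G+C composition.

    Random sequences preserve the query's exact amino-acid sequence; each
    codon is drawn from its synonymous family with probability proportional
    to the product of the query's overall nucleotide frequencies across the
    codon's three positions (a composition-matched null). The threshold is
    the upper one-sided 95% point under a normal approximation,
    mean + 1.645 sd; the empirical 95th percentile is reported alongside.
    """
    if n_random < 30:
        raise ValueError("n_random < 30: normal approximation unsafe")
    seq = seq.upper().replace("U", "T")
    observed = cai(seq, table)

    base_freq = {b: max(seq.count(b), 1) for b in "ACGT"}
    total = sum(base_freq.values())
    base_p = {b: base_freq[b] / total for b in "ACGT"}

    # amino-acid sequence of the query (informative positions only)
    aas = [AA[c] for c in _included_codons(seq)]
    rng = np.random.default_rng(seed)

    fam_codons: dict[str, list[str]] = {}
    fam_probs: dict[str, np.ndarray] = {}
    for aa, fam in FAMILIES.items():
        weights = np.array(
            [base_p[c[0]] * base_p[c[1]] * base_p[c[2]] for c in fam]
        )
        fam_codons[aa] = fam
        fam_probs[aa] = weights / weights.sum()

    logw = {c: math.log(table.w[c]) for c in SENSE_CODONS}
    null_cais = np.empty(n_random)
    for r in range(n_random):
        acc = 0.0
        for aa in aas:
            fam = fam_codons[aa]
            cod = fam[rng.choice(len(fam), p=fam_probs[aa])]
            acc += logw[cod]
        null_cais[r] = math.exp(acc / len(aas))

    ecai = float(null_cais.mean() + 1.645 * null_cais.std(ddof=1))
    p = float(np.mean(null_cais >= observed))
    return EcaiResult(
        cai=observed,
        ecai=ecai,
        p=p,
        null_q95=float(np.quantile(null_cais, 0.95)),
        n_random=n_random,
        seed=seed,
    )
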