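"""Tests of coupling between evolutionary histories.

Under strict clonality every locus shares one genealogy, so distance
matrices computed from different loci should correlate; recombination
decouples them. This module provides the Mantel permutation test, the
parametric Pearson correlation on distance vectors (reported only alongside
the permutation test), Ward hierarchical clustering, Baker's gamma
dendrogram congruence with a label-permutation null, and one-factor
PERMANOVA.

All permutation p-values use the (1 + exceedances) / (1 + n_perm)
estimator, so p is never exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io import DistanceMatrix

logger = logging.getLogger(__name__)


def _shared_labels(d1: DistanceMatrix, d2: DistanceMatrix) -> list[str]:
    common = [l for l in d1.labels if l in set(d2.labels)]
    if len(common) < 3:
        raise ValueError(
            f"need >= 3 shared labels, found {len(common)}: {common}"
        )
    if len(common) < max(d1.n, d2.n):
        logger.info(
            "label intersection: %d of (%d, %d)", len(common), d1.n, d2.n
        )
    return common


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: Optional[int]
    n: int

    def to_dict(self) -> dict:
        return {"r": self.r, "p": self.p, "n_perm": self.n_perm,
                "seed": self.seed, "n": self.n}


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 9999,
    seed: Optional[int] = None,
) -> MantelResult:
    """Mantel test for positive linear association between two distance
    matrices, on their label intersection.

    The null is generated by jointly permuting rows and columns of the
    second matrix; p is one-tailed (greater).
    """
    common = _shared_labels(d1, d2)
    m1 = d1.restrict(common).values
    m2 = d2.restrict(common).values
    n = len(common)
    iu = np.triu_indices(n, k=1)
    v1, v2 = m1[iu], m2[iu]
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("zero-variance distances: Mantel r undefined")

    # correlation via precentred vectors so the permutation loop is cheap
    c1 = (v1 - v1.mean()) / (v1.std() * np.sqrt(len(v1)))

    def corr(mat2: np.ndarray) -> float:
        v = mat2[iu]
        sd = v.std()
        if sd == 0:
            return 0.0
        return float(c1 @ ((v - v.mean()) / (sd * np.sqrt(len(v)))))

    r_obs = corr(m2)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(m2[np.ix_(perm, perm)]) >= r_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, seed=seed, n=n)


def pearson_distance_correlation(
    d1: DistanceMatrix, d2: DistanceMatrix
) -> tuple[float, float]:
    """Pearson correlation of the two upper-triangle distance vectors with
    the t-distribution p-value on n(n-1)/2 - 2 degrees of freedom.

    Distance-pair entries are not independent observations, so this p-value
    is anti-conservative; report it only alongside the Mantel permutation p.
    """
    common = _shared_labels(d1, d2)
    m1 = d1.restrict(common).values
    m2 = d2.restrict(common).values
    iu = np.triu_indices(len(common), k=1)
    v1, v2 = m1[iu], m2[iu]
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("zero-variance distances: correlation undefined")
    logger.info(
        "parametric p on distance pairs is anti-conservative; prefer the "
        "Mantel permutation p"
    )
    res = stats.pearsonr(v1, v2)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Ward clustering


@dataclass
class Dendrogram:
    """Binary merge tree in scipy linkage convention.

    Leaves are 0..n-1 in ``labels`` order; ``merges[k]`` gives the two
    cluster ids joined at step k into cluster n+k, at height ``heights[k]``.
    Heights are non-decreasing (ultrametric presentation).
    """

    labels: list[str]
    merges: np.ndarray  # (n-1, 2) int
    heights: np.ndarray  # (n-1,) float

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=np.intp)
        self.heights = np.asarray(self.heights, dtype=np.float64)
        n = len(self.labels)
        if n < 2:
            raise ValueError("dendrogram needs at least 2 leaves")
        if self.merges.shape != (n - 1, 2) or self.heights.shape != (n - 1,):
            raise ValueError("merges/heights shape mismatch")
        if np.any(np.diff(self.heights) < -1e-9):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_linkage(self) -> np.ndarray:
        """scipy-style (n-1, 4) linkage array."""
        n = self.n
        sizes = {i: 1 for i in range(n)}
        Z = np.zeros((n - 1, 4))
        for k, ((a, b), h) in enumerate(zip(self.merges, self.heights)):
            size = sizes[int(a)] + sizes[int(b)]
            sizes[n + k] = size
            Z[k] = [a, b, h, size]
        return Z

    def merge_depths(self) -> np.ndarray:
        """For every leaf pair, the number of clusters present when the pair
        first co-clusters (n x n symmetric, diagonal 0)."""
        n = self.n
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        depth = np.zeros((n, n))
        for k, (a, b) in enumerate(self.merges):
            la, lb = members[int(a)], members[int(b)]
            kclust = n - k - 1  # clusters remaining after this merge
            for i in la:
                for j in lb:
                    depth[i, j] = depth[j, i] = kclust
            members[self.n + k] = la + lb
        return depth

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height differences."""
        n = self.n
        node_height = {i: 0.0 for i in range(n)}
        rep: dict[int, str] = {}
        for i, lab in enumerate(self.labels):
            rep[i] = lab
        for k, ((a, b), h) in enumerate(zip(self.merges, self.heights)):
            a, b = int(a), int(b)
            la = h - node_height[a]
            lb = h - node_height[b]
            rep[n + k] = f"({rep[a]}:{la:.10g},{rep[b]}:{lb:.10g})"
            node_height[n + k] = h
        return rep[n + self.n - 2] + ";"


def ward_dendrogram(d: DistanceMatrix) -> Dendrogram:
    """Agglomerative Ward clustering (Ward.D2 convention).

    Lance–Williams updates on squared distances; merge height is the square
    root of the minimised criterion, matching scipy's ``linkage(..,
    'ward')`` on a condensed distance matrix. Ties are broken toward the
    pair whose lexicographically smallest member labels sort first.
    """
    n = d.n
    if n < 2:
        raise ValueError("need at least 2 labels")
    D2 = d.values.astype(float) ** 2
    active: dict[int, dict] = {
        i: {"size": 1, "minlab": d.labels[i]} for i in range(n)
    }
    # working squared-distance store between active cluster ids
    dist2: dict[tuple[int, int], float] = {}
    ids = list(range(n))
    for ii in range(n):
        for jj in range(ii + 1, n):
            dist2[(ii, jj)] = D2[ii, jj]

    def get(a: int, b: int) -> float:
        return dist2[(a, b) if a < b else (b, a)]

    merges = []
    heights = []
    next_id = n
    for _ in range(n - 1):
        best = None
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                v = get(a, b)
                la, lb = active[a]["minlab"], active[b]["minlab"]
                key = (v, min(la, lb), max(la, lb))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        h2 = get(a, b)
        na, nb = active[a]["size"], active[b]["size"]
        new = next_id
        next_id += 1
        for c in ids:
            if c in (a, b):
                continue
            nc = active[c]["size"]
            v = (
                (na + nc) * get(a, c)
                + (nb + nc) * get(b, c)
                - nc * h2
            ) / (na + nb + nc)
            dist2[(min(c, new), max(c, new))] = v
        ids = [c for c in ids if c not in (a, b)] + [new]
        active[new] = {
            "size": na + nb,
            "minlab": min(active[a]["minlab"], active[b]["minlab"]),
        }
        merges.append((a, b))
        heights.append(np.sqrt(h2))
    heights = np.maximum.accumulate(np.array(heights))
    return Dendrogram(list(d.labels), np.array(merges), heights)


# ---------------------------------------------------------------------------
# Baker's gamma


@dataclass
class BakersGammaResult:
    gamma: float
    p: float
    n_perm: int
    seed: Optional[int]

    def to_dict(self) -> dict:
        return {"gamma": self.gamma, "p": self.p, "n_perm": self.n_perm,
                "seed": self.seed}


def bakers_gamma(
    t1: Dendrogram,
    t2: Dendrogram,
    n_perm: int = 1000,
    seed: Optional[int] = None,
) -> BakersGammaResult:
    """Baker's gamma congruence between two dendrograms on one leaf set.

    For every unordered leaf pair the merge depth (number of clusters at
    which the pair first co-clusters) is recorded in each tree; gamma is the
    Spearman rank correlation of the two depth vectors. The null permutes
    the leaf labels of the second tree; p is two-sided on \\|gamma\\|.
    """
    if set(t1.labels) != set(t2.labels):
        diff = sorted(set(t1.labels) ^ set(t2.labels))
        raise ValueError(f"leaf sets differ, symmetric difference: {diff}")
    n = t1.n
    depth1 = t1.merge_depths()
    # align t2's depth matrix to t1's label order
    order = [t2.labels.index(l) for l in t1.labels]
    depth2 = t2.merge_depths()[np.ix_(order, order)]
    iu = np.triu_indices(n, k=1)
    v1 = depth1[iu]

    def gamma_of(mat: np.ndarray) -> float:
        v2 = mat[iu]
        res = stats.spearmanr(v1, v2)
        return float(res.statistic)

    g_obs = gamma_of(depth2)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if abs(gamma_of(depth2[np.ix_(perm, perm)])) >= abs(g_obs):
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return BakersGammaResult(gamma=g_obs, p=p, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p: float
    n_perm: int
    seed: Optional[int]
    factor: str

    def to_dict(self) -> dict:
        return {"pseudo_f": self.pseudo_f, "r2": self.r2, "p": self.p,
                "n_perm": self.n_perm, "seed": self.seed,
                "factor": self.factor}


def permanova(
    d: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: Optional[int] = None,
    factor: str = "group",
) -> PermanovaResult:
    """One-factor PERMANOVA (Anderson 2001) on a distance matrix.

    ``groups`` assigns a group label to each matrix label, in matrix order.
    SS_total = sum of squared distances / n over all pairs; SS_within is the
    group-wise analogue; pseudo-F = (SS_between/(a-1)) / (SS_within/(n-a)).
    The null permutes group labels; p is one-tailed on F.
    """
    n = d.n
    groups = list(groups)
    if len(groups) != n:
        raise ValueError("one group label per matrix label required")
    uniq = sorted(set(groups))
    a = len(uniq)
    if a < 2:
        raise ValueError("need at least 2 groups")
    if a >= n:
        raise ValueError("as many groups as observations: residual df is 0")
    D2 = d.values**2
    iu = np.triu_indices(n, k=1)
    ss_total = float(D2[iu].sum()) / n
    gidx = np.array([uniq.index(g) for g in groups])

    def pseudo_f(gv: np.ndarray) -> float:
        ss_within = 0.0
        for k in range(a):
            sel = np.flatnonzero(gv == k)
            if len(sel) < 2:
                continue
            sub = D2[np.ix_(sel, sel)]
            ss_within += float(np.triu(sub, k=1).sum()) / len(sel)
        ss_between = ss_total - ss_within
        if ss_within <= 0:
            return np.inf
        return (ss_between / (a - 1)) / (ss_within / (n - a))

    f_obs = pseudo_f(gidx)
    ss_w = 0.0
    for k in range(a):
        sel = np.flatnonzero(gidx == k)
        if len(sel) >= 2:
            ss_w += float(np.triu(D2[np.ix_(sel, sel)], k=1).sum()) / len(sel)
    r2 = (ss_total - ss_w) / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if pseudo_f(gidx[rng.permutation(n)]) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermanovaResult(
        pseudo_f=f_obs, r2=float(r2), p=p, n_perm=n_perm, seed=seed,
        factor=factor,
    )
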