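"""Precomputed standard-genetic-code tables for codon-evolution statistics.

Everything here is derived once at import time from Biopython's standard
codon table: per-codon synonymous/non-synonymous site fractions (mutations
to stop codons excluded from the per-position denominator, total sites per
codon fixed at 3) and, for every ordered codon pair, the synonymous and
non-synonymous difference counts averaged with equal weight over all
minimal mutational pathways that avoid stop codons.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"
CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

STOP_CODONS = frozenset(standard_dna_table.stop_codons)
AA = {c: standard_dna_table.forward_table[c] for c in CODONS if c not in STOP_CODONS}
for _stop in STOP_CODONS:
    AA[_stop] = "*"

SENSE_CODONS = [c for c in CODONS if c not in STOP_CODONS]

#: synonymous-family partition of the 61 sense codons, keyed by amino acid
FAMILIES: dict[str, list[str]] = {}
for _c in SENSE_CODONS:
    FAMILIES.setdefault(AA[_c], []).append(_c)


def _syn_sites(codon: str) -> float:
    """Synonymous sites of one codon under Nei–Gojobori counting.

    Per position, the synonymous fraction is taken over the non-stop single
    base mutants; each position contributes one full site, so syn + nonsyn
    always totals 3.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon}")
    s = 0.0
    for pos in range(3):
        syn = 0
        non_stop = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            non_stop += 1
            if AA[mut] == AA[codon]:
                syn += 1
        if non_stop:
            s += syn / non_stop
    return s


# per-codon site arrays indexed by CODON_INDEX; NaN for stops
SYN_SITES = np.full(64, np.nan)
for _c in SENSE_CODONS:
    SYN_SITES[CODON_INDEX[_c]] = _syn_sites(_c)
NONSYN_SITES = 3.0 - SYN_SITES


def _pathway_counts(a: str, b: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) differences between two sense codons.

    Averaged with equal weight over all orderings of the differing
    positions; orderings passing through a stop codon are discarded. If every
    ordering hits a stop, stop-containing pathways are retained as a last
    resort (the classical fallback; only reachable for extreme codon pairs).
    """
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    clean, dirty = [], []
    for order in permutations(diff):
        cur = a
        sd = nd = 0.0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                hit_stop = True
            if AA[nxt] == AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (dirty if hit_stop else clean).append((sd, nd))
    paths = clean if clean else dirty
    sd = float(np.mean([p[0] for p in paths]))
    nd = float(np.mean([p[1] for p in paths]))
    return sd, nd


# 64x64 pairwise difference-count tables; NaN where either codon is a stop
SYN_DIFFS = np.full((64, 64), np.nan)
NONSYN_DIFFS = np.full((64, 64), np.nan)
for _a in SENSE_CODONS:
    for _b in SENSE_CODONS:
        _sd, _nd = _pathway_counts(_a, _b)
        SYN_DIFFS[CODON_INDEX[_a], CODON_INDEX[_b]] = _sd
        NONSYN_DIFFS[CODON_INDEX[_a], CODON_INDEX[_b]] = _nd


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def encode_codons(seq: str) -> np.ndarray:
    """Map an in-frame sequence to codon indices; -1 for codons containing
    anything other than A/C/G/T (gaps, N)."""
    n_codons = len(seq) // 3
    out = np.full(n_codons, -1, dtype=np.int64)
    for k in range(n_codons):
        cod = seq[3 * k : 3 * k + 3]
        idx = 0
        ok = True
        for ch in cod:
            b = _BASE_INDEX.get(ch)
            if b is None:
                ok = False
                break
            idx = idx * 4 + b
        if ok:
            out[k] = idx
    return out


STOP_INDICES = np.array([CODON_INDEX[c] for c in STOP_CODONS])
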