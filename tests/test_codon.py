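import itertools
import math

import numpy as np
import pytest

from clonescan.codon import (
    CodonUsageTable,
    build_codon_usage,
    cai,
    codon_pair_differences,
    codon_selection_test,
    codon_sites,
    ecai_threshold,
    nei_gojobori_pair,
)
from clonescan.io import Alignment

# Independent statement of the standard genetic code for oracle use
# (kept separate from the implementation's Biopython-derived tables).
ORACLE_CODE = {}
_BASES = "TCAG"
_AAS = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, (_a, _b, _c) in enumerate(itertools.product(_BASES, repeat=3)):
    ORACLE_CODE[_a + _b + _c] = _AAS[_i]

ORACLE_SENSE = sorted(c for c, aa in ORACLE_CODE.items() if aa != "*")


def oracle_sites(codon):
    """Enumerate all 9 single-base mutants; synonymous fraction per position
    over non-stop mutants; 3 total sites."""
    syn = 0.0
    for pos in range(3):
        s = t = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if ORACLE_CODE[mut] == "*":
                continue
            t += 1
            if ORACLE_CODE[mut] == ORACLE_CODE[codon]:
                s += 1
        if t:
            syn += s / t
    return syn, 3.0 - syn


def oracle_diffs(a, b):
    """Average syn/nonsyn steps over stop-free orderings of the changes."""
    diff = [i for i in range(3) if a[i] != b[i]]
    paths = []
    for order in itertools.permutations(diff):
        cur, sd, nd, ok = a, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if ORACLE_CODE[nxt] == "*":
                ok = False
                break
            if ORACLE_CODE[nxt] == ORACLE_CODE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:
        return None
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


class TestCodonSites:
    @pytest.mark.parametrize(
        "codon, syn",
        [
            ("TTT", 1 / 3),  # only T->C at position 3 is synonymous
            ("TTA", 2 / 3),  # pos1 T->C and pos3 A->G preserve Leu
            ("ATG", 0.0),  # Met is a single-codon family
        ],
    )
    def test_examples(self, codon, syn):
        s, n = codon_sites(codon)
        assert s == pytest.approx(syn)
        assert s + n == pytest.approx(3.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            codon_sites("TAA")

    def test_all_sense_codons_match_enumeration_oracle(self):
        for codon in ORACLE_SENSE:
            s, n = codon_sites(codon)
            es, en = oracle_sites(codon)
            assert s == pytest.approx(es, abs=1e-9), codon
            assert n == pytest.approx(en, abs=1e-9), codon


class TestNeiGojoboriPair:
    def test_identical(self):
        pn, ps, dn, ds = nei_gojobori_pair("TTTAAA", "TTTAAA")
        assert (pn, ps, dn, ds) == (0.0, 0.0, 0.0, 0.0)

    def test_single_codon_worked_example(self):
        # (TTT, TTA): nd=1, sd=0; S=(1/3+2/3)/2=0.5, N=2.5; pN=0.4
        pn, ps, dn, ds = nei_gojobori_pair("TTT", "TTA")
        assert pn == pytest.approx(0.4)
        assert ps == 0.0
        assert dn == pytest.approx(-0.75 * math.log(1 - 4 / 3 * 0.4), abs=1e-9)
        assert dn == pytest.approx(0.5716, abs=1e-4)
        assert ds == 0.0

    def test_synonymous_change_only(self):
        # GGA -> GGG is synonymous (Gly)
        pn, ps, dn, ds = nei_gojobori_pair("GGATTTAAA", "GGGTTTAAA")
        assert dn == 0.0 and ds > 0.0

    def test_all_codon_pairs_match_pathway_oracle(self):
        for a in ORACLE_SENSE:
            for b in ORACLE_SENSE:
                expect = oracle_diffs(a, b)
                if expect is None:
                    continue
                sd, nd = codon_pair_differences(a, b)
                assert sd == pytest.approx(expect[0], abs=1e-9), (a, b)
                assert nd == pytest.approx(expect[1], abs=1e-9), (a, b)

    def test_gapped_codons_excluded_pairwise(self):
        full = nei_gojobori_pair("TTTAAA", "TTAAAA")
        with_gap = nei_gojobori_pair("TTTAAAGG-", "TTAAAAGGG")
        assert full == with_gap

    def test_internal_stop_raises(self):
        with pytest.raises(ValueError, match="stop"):
            nei_gojobori_pair("TTTTAATTT", "TTTTACTTT")

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            nei_gojobori_pair("TTT", "TTTAAA")


class TestCodonSelectionTest:
    def _aln(self, seqs):
        return Alignment(
            ids=[f"s{i}" for i in range(len(seqs))], seqs=seqs, frame=0
        )

    def test_identical_sequences_flagged_undefined(self):
        res = codon_selection_test(self._aln(["TTTAAACCC"] * 3), n_boot=50, seed=0)
        assert res.dN == res.dS == 0.0
        assert res.undefined

    def test_z_formula_consistency(self, tiny_clonal):
        res = codon_selection_test(tiny_clonal.mat_alignment, n_boot=199, seed=1)
        if not res.undefined:
            expect = (res.dN - res.dS) / math.sqrt(res.var_dN + res.var_dS)
            assert res.z == pytest.approx(expect)
            # the two one-tailed p-values are complementary
            assert res.p_positive + res.p_purifying == pytest.approx(1.0)

    def test_seed_reproducible(self, tiny_clonal):
        a = codon_selection_test(tiny_clonal.mat_alignment, n_boot=99, seed=7)
        b = codon_selection_test(tiny_clonal.mat_alignment, n_boot=99, seed=7)
        assert (a.var_dN, a.var_dS, a.z) == (b.var_dN, b.var_dS, b.z)
        assert a.var_dN >= 0 and a.var_dS >= 0

    def test_variance_shrinks_with_length(self):
        rng = np.random.default_rng(3)

        def make(n_codons, seed):
            rng2 = np.random.default_rng(seed)
            base = "".join(rng2.choice(ORACLE_SENSE, size=n_codons))
            seqs = [base]
            for _ in range(3):
                s = list(base)
                for _ in range(max(2, n_codons // 10)):
                    k = rng2.integers(0, n_codons)
                    s[3 * k : 3 * k + 3] = rng2.choice(ORACLE_SENSE)
                seqs.append("".join(s))
            return self._aln(seqs)

        short = [
            codon_selection_test(make(20, s), n_boot=99, seed=s).var_dN
            for s in range(5)
        ]
        long = [
            codon_selection_test(make(200, s), n_boot=99, seed=s).var_dN
            for s in range(5)
        ]
        assert np.mean(long) < np.mean(short)

    def test_too_short(self):
        with pytest.raises(ValueError):
            codon_selection_test(self._aln(["TTT", "TTA"]), n_boot=10, seed=0)


class TestCodonUsage:
    def test_single_codon_per_family(self):
        # a collection using only GGA for Gly: GGA w=1, unobserved get 0.5/max
        table = build_codon_usage(["GGAGGAGGA"])
        assert table.w["GGA"] == 1.0
        assert table.w["GGG"] == pytest.approx(0.5 / 3.0)

    def test_counts_additive(self):
        t1 = build_codon_usage(["GGATTT"])
        t2 = build_codon_usage(["GGATTT", "GGATTT"])
        assert t2.counts["GGA"] == 2 * t1.counts["GGA"]

    def test_bad_length_named(self):
        with pytest.raises(ValueError, match="#1"):
            build_codon_usage(["GGATTT", "GGAT"])

    def test_empty_collection(self):
        with pytest.raises(ValueError):
            build_codon_usage([])


class TestCai:
    def test_all_preferred_codons_gives_one(self):
        table = build_codon_usage(["GGATTTCCAAGA" * 5])
        assert cai("GGATTTCCAAGA", table) == pytest.approx(1.0)

    def test_geometric_mean(self):
        # two informative codons with w=1 and w=0.25 -> sqrt(0.25) = 0.5
        counts = {c: 0.0 for c in ORACLE_SENSE}
        counts["GGA"] = 4.0
        counts["GGG"] = 1.0
        counts["TTT"] = 4.0
        table = CodonUsageTable.from_counts(counts)
        assert table.w["GGG"] == pytest.approx(0.25)
        assert cai("GGAGGG", table) == pytest.approx(0.5)

    def test_invariant_to_synonymous_reordering(self):
        table = build_codon_usage(["GGAGGGTTATTGCTA" * 3])
        assert cai("GGAGGGTTA", table) == pytest.approx(cai("TTAGGGGGA", table))

    def test_met_trp_stop_excluded(self):
        table = build_codon_usage(["GGAGGA"])
        # ATG and TGG carry no information; GGA has w=1
        assert cai("ATGTGGGGA", table) == pytest.approx(1.0)

    def test_no_informative_codons(self):
        table = build_codon_usage(["GGAGGA"])
        with pytest.raises(ValueError):
            cai("ATGTGG", table)


@pytest.fixture()
def table():
    rng = np.random.default_rng(0)
    seqs = ["".join(rng.choice(ORACLE_SENSE, size=100)) for _ in range(5)]
    return build_codon_usage(seqs)


class TestEcai:

    def test_deterministic(self, table):
        q = "GGATTTCCAAGATTGACC" * 3
        a = ecai_threshold(q, table, n_random=60, seed=5)
        b = ecai_threshold(q, table, n_random=60, seed=5)
        assert a.ecai == b.ecai and a.p == b.p

    def test_p_resolution(self):
        # query made entirely of preferred codons has CAI 1 >= every null
        table = build_codon_usage(["GGATTTCCAAGA" * 10])
        r = ecai_threshold("GGATTTCCAAGA" * 4, table, n_random=50, seed=1)
        assert r.cai == pytest.approx(1.0)
        assert r.p <= 1.0 / 50

    def test_small_n_rejected(self, table):
        with pytest.raises(ValueError, match="n_random"):
            ecai_threshold("GGATTT", table, n_random=10, seed=0)

    def test_threshold_near_null_upper_tail(self, table):
        rng = np.random.default_rng(2)
        q = "".join(rng.choice(ORACLE_SENSE, size=80))
        r = ecai_threshold(q, table, n_random=300, seed=3)
        # normal-approximation point and empirical 95th percentile agree
        assert r.ecai == pytest.approx(r.null_q95, rel=0.05)
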