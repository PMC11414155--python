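"""Detect purifying selection on a simulated coding locus.

The simulator accepts non-synonymous mutations with probability omega
(here 0.3), so realised dN should fall below dS. The Nei-Gojobori
codon-based Z-test quantifies this: Z = (dN - dS)/sqrt(Var dN + Var dS)
with variances from bootstrapping codon columns; a significantly negative
Z rejects strict neutrality in favour of purifying selection.
"""

from clonescan import SimConfig, codon_selection_test, simulate

out = simulate(
    SimConfig(mode="clonal", N=100, generations=300, mu_coding=5e-4,
              omega=0.3, sample_n=12, seed=2)
)

for aln in (out.mat_alignment, out.ptg_alignment):
    res = codon_selection_test(aln, n_boot=999, seed=0)
    print(f"{aln.locus_name} ({aln.length // 3} codons, {res.n_pairs} pairs):")
    print(f"  dN = {res.dN:.4f}, dS = {res.dS:.4f}")
    if res.undefined:
        print("  Z undefined (no variance in the bootstrap)")
    else:
        print(f"  Z = {res.z:.3f}, purifying-selection p = {res.p_purifying:.4f}")

print(
    "\ndN < dS at both loci reflects the simulated purifying pressure; the "
    "one-tailed p is the probability of a Z this negative under neutrality."
)
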