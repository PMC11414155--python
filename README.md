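# clonescan

Congruence-of-loci tests for clonality in haploid populations.

## The problem

Whether a lineage reproduces sexually or clonally leaves a clear genomic
signature. Recombination decouples loci: in a sexual population, divergence
at a mating-type (MAT) locus says nothing about divergence at an unrelated
gene or across thousands of genome-wide SNPs. In a clonal lineage every
locus shares one genealogy, so pairwise divergence measured at any locus
correlates with divergence at every other. This logic is particularly
sharp for organisms like arbuscular mycorrhizal fungi (*Rhizophagus
irregularis* and relatives), where a putative MAT locus exists but direct
evidence of mating is absent: testing whether the MAT locus, a phosphate
transporter gene (PTG) and genome-wide SNPs evolve together or
independently discriminates the two scenarios.

`clonescan` implements that test end to end for three datasets over one
isolate panel:

- an aligned nucleotide FASTA of a MAT-locus amplicon (partial HD2 coding
  region),
- an aligned FASTA of an unrelated protein-coding gene (PTG),
- a genome-wide biallelic SNP genotype matrix with per-call read depth and
  read-support metadata.

## Methods at the core

- **Divergence.** Tamura 3-parameter distance
  `d = -h ln(1 - P/h - Q) - ½(1-h) ln(1 - 2Q)` with `h = 2θ(1-θ)`
  (P, Q = transition/transversion proportions, θ = pooled G+C), p-distance,
  and binary Jaccard distance on quality-filtered SNP profiles
  (depth ≥ 10, support > 0.8, minor-allele count ≥ 2, MAT/PTG regions
  excluded).
- **Congruence.** Mantel permutation tests between distance matrices
  (one-tailed, positive association), Ward (D2) dendrograms with Baker's
  gamma congruence under a label-permutation null, and one-factor PERMANOVA
  (pseudo-F) for metadata factors such as geographic origin and MAT-type.
- **Selection.** Nei–Gojobori dN/dS with equal-weight stop-free pathway
  counting and the codon-based Z-test
  `Z = (dN - dS)/√(Var dN + Var dS)`, variances bootstrapped over codon
  columns (999 replicates by default).
- **Codon usage.** CAI (geometric mean of relative adaptiveness w over
  informative codons) and the eCAI threshold `mean + 1.645·sd` of CAI over
  random sequences matched for amino-acid sequence and nucleotide
  composition.
- **MAT typing.** Nearest-reference typing under a p-distance threshold
  with de novo clustering of novel types, and allele assignment that splits
  a type only on amino-acid (non-synonymous) differences.
- **Simulation.** A haploid Wright–Fisher model with purifying selection on
  two coding loci and unlinked neutral SNPs, reproducing either clonally or
  by MAT-compatible mating with free reassortment — the ground-truth
  generator used to validate every stage.

## Worked example

```python
from clonescan import (SimConfig, simulate, alignment_distance_matrix,
                       filter_snp_matrix, jaccard_distance_matrix, mantel)

out = simulate(SimConfig(mode="clonal", seed=4))
d_mat = alignment_distance_matrix(out.mat_alignment)   # Tamura 3-parameter
d_snp = jaccard_distance_matrix(filter_snp_matrix(out.snp_matrix))
print(mantel(d_mat, d_snp, n_perm=999, seed=0))
```

Running `python examples/01_clonal_vs_sexual_verdict.py` prints, for the
clonal population:

```
  Mantel MAT~PTG: r = +0.889, p = 0.001
  Mantel MAT~SNP: r = +0.930, p = 0.001
  Mantel PTG~SNP: r = +0.843, p = 0.001
  verdict: congruent-clonal-like
```

and for the sexual population simulated with identical parameters:

```
  Mantel MAT~PTG: r = -0.079, p = 0.844
  Mantel MAT~SNP: r = +0.096, p = 0.138
  Mantel PTG~SNP: r = +0.174, p = 0.047
  verdict: mixed
```

The clonal population shows strong positive correlation between every pair
of distance matrices — isolates that diverged at the MAT locus diverged
everywhere — while recombination in the sexual population pushes the
correlations toward zero. Each `examples/` script demonstrates one
capability the same way (selection testing, CAI/eCAI, MAT typing, the full
file-based pipeline).

A thin CLI mirrors the library for shell use:

```bash
clonescan simulate --mode clonal --seed 1 --out data/
clonescan run-all --mat data/mat.fasta --ptg data/ptg.fasta \
    --snps data/snps.tsv --seed 1 --out results/
```

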