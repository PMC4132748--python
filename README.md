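# macrorate

Macrosatellite copy-number genotyping from sequencing read depth, and
mutation-rate estimation of a tandem-repeat array by founder-mutation
tracing.

Macrosatellites — tandem repeats with units longer than 1 kb, such as the
RNU2 array at 17q21 (a 6.1 kb unit present in roughly 5–82 copies per
allele) — are hypervariable but nearly impossible to genotype with
standard platforms, and their mutation rates are poorly known.  This
package implements two complementary approaches for geneticists working on
such loci:

1. **Read-depth genotyping.**  Reads from every repeat unit map onto the
   single unit in the reference, so the mean depth of coverage (DOC) over
   the unit scales with total copy number.  The DOC-estimated diploid copy
   number is

   `DCN = 2 × unit_DOC / genome_DOC`

   with validation statistics (OLS r² against an orthogonal truth set such
   as fiber-FISH counts; Kruskal–Wallis rank tests between populations).

2. **Mutation-rate estimation over deep timescales.**  When the array sits
   in a strong linkage-disequilibrium block with a disease gene carrying
   founder mutations (here BRCA1), apparently unrelated carrier families
   descend from a common ancestor whose age G can be estimated.  Treating
   families as radiating from the MRCA along a star phylogeny, the number
   of array mutations on a lineage of t generations is Poisson(μt), giving

   `log L(μ) = −T₀·μ + Σⱼ log(1 − e^(−tⱼ·μ))`

   where T₀ sums all mutation-free generations and each tⱼ is a lineage on
   which the linked array changed.  The MLE μ̂ is found by solving the
   score equation; 95% CIs invert the Wald test after reparameterising
   with λ = log μ.  Supporting estimators: stepwise-mutation-model
   θ = 4Nₑμ from an allele spectrum (from the mean allele frequency,
   θ̂ = 1/(8x̄²) − ½, and from the distinct-allele count by root-solving a
   calibrated expectation), and a haplotype-decay likelihood that
   estimates G itself from carrier SNP haplotypes.

Seeded synthetic-data generators emulate every input (depth tracks,
star-phylogeny transmissions, coalescent SMM spectra, decaying carrier
haplotypes, mutating pedigrees) so the full pipeline is testable without
access to population-scale sequencing or consortium genotypes.

## Worked example

The packaged inputs are the five-founder-mutation family table (linked
RNU2 alleles, within-family meiosis counts, MRCA ages with CIs) and a
53-allele spectrum (n = 504 haploid genotypes):

```sh
macrorate paper --out-dir run/
```

prints

```
macrorate 0.1.0  (seed 0, config 2788fa4765f483ec)

Lineage accounting
  mutation-free generations (T0): 639
  mutated lineages (t_j):         [73, 61, 72, 72]
  minimum mutation events:        4

Mutation rate (Poisson star-phylogeny MLE)
  mu_hat = 5.197e-03 per generation
  95% Wald CI (log scale): [1.940e-03, 1.392e-02]
  age-CI sensitivity envelope:   [1.470e-03, 1.837e-02]

Scaled mutation parameter (SMM estimators)
  n_A = 53, x_bar = 0.0189, n = 504
  theta_xbar = 350.6
  theta_nA   = 602.2
  4*Ne*mu_hat (Ne = 10000) = 208
```

Reading: across the five founder groups, 639 generations passed the array
on unchanged while on four lineages (61, 73, 72 and 72 generations long) at
least one mutation occurred; the Poisson MLE is μ̂ ≈ 5 × 10⁻³ mutations per
generation.  Rebuilding the counts at the bounds of the MRCA-age CIs
widens the plausible range to the sensitivity envelope.  The
population-scale θ estimates (350.6 and 602.2) are the same order of
magnitude as 4Nₑμ̂ ≈ 208 at Nₑ = 10,000 — an independent consistency check
of the rate.

Individual stages are also available as subcommands (`macrorate dcn`,
`lineages`, `rate`, `theta`, `mrca`, `simulate`) and as library functions.

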