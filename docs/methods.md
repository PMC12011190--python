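# Methods

## Estimator

The D statistic is computed in its frequency-weighted (population
allele-frequency) form. Per site, each panel's derived-allele frequency is
the mean dosage over called samples divided by 2; a heterozygous focal
specimen therefore enters as p2 = 0.5 rather than being hard-called. This
is a deliberate choice over single-base-sampling variants: the input is
called genotypes, and dosages carry strictly more information than a
sampled base. A `hard_call` flag approximates base-sampling deterministically
by rounding each panel frequency to 0 or 1 and dropping sites where a
panel frequency is exactly 0.5 (a random draw would break determinism; a
fixed tie-break toward either allele would bias D).

Polarization: the pipeline assumes genotypes were called against the
outgroup species' reference genome, so the outgroup's allele is the
reference base and p4 = 0 at every site ("reference_allele" mode). A
sample-based outgroup panel ("sample_ids" mode) is available when a
genotyped outgroup is present; any site where that panel is fixed derived
(p4 = 1) contributes weight (0, 0), as it carries no polarizable signal.

Missing data: a panel's frequency uses called samples only, and a site is
skipped for a given test when any required panel has zero called samples.
Zero-filling would deflate p2 toward the ancestral allele and bias D; the
skip rule costs sites, not correctness.

Degenerate input: Σabba + Σbaba = 0 means "no informative sites", which is
not evidence of symmetry, so D is reported as NA with an explicit status
rather than 0.

## Block jackknife

Uncertainty comes from a delete-one-block jackknife over contiguous blocks
of usable sites, using the weighted delete-m form (Busing et al. 1999) so
that the shorter final block is weighted by its size instead of biasing
the variance. Z = D / SE. The default block is 5,000 consecutive sites —
conventional practice for absorbing local linkage disequilibrium in dense
genome-wide data; calibration runs on the simulator use smaller blocks
(100–500 sites) because its sites are independent, and more blocks give a
better-calibrated (closer to normal) Z. With fewer than two blocks the SE
is undefined and reported as NA with a warning.

## Rank-sum comparison

The marine/freshwater contrast is a two-sample Mann-Whitney rank-sum test:
the design has two independent groups, not paired observations, so the
signed-rank variant does not apply. When both groups have at most 8 values
and no ties, the exact null distribution of U is used (the implementation
is cross-checked in the tests against complete enumeration of label
assignments); otherwise the normal approximation with midrank tie
correction and, by default, a continuity correction. Two-sided by default;
sidedness and continuity are switchable in the config. Per-specimen D
values that are NA are dropped (counted in the log) and each group must
retain at least two values.

## Locus scan

Informative sites require the conspecific reference specimen to be
homozygous reference (dosage 0) and the donor reference homozygous
alternative (dosage 2); heterozygous or missing reference genotypes
exclude the site. The conspecific reference is re-selected from the
freshwater specimens as the one with minimal D (ties broken by smallest
sample id), surfaced in the run report for auditability. The call
threshold on the marine alternative-allele frequency is a strict
inequality (> 0.5); a frequency of exactly 0.5 is not a majority. Missing
marine genotypes leave both numerator and denominator; `min_called`
(default 1) guards near-all-missing sites. Gene assignment is positional
interval overlap (0-based half-open internally; BED taken as-is, GFF3
`gene` features converted on read); a site inside several overlapping
genes is assigned all of them, and strand is ignored. "Locus" here means a
single SNP; clustering adjacent hits into regions is left to downstream
tooling.

## Synthetic cohort

The generator is a site-category model, not a coalescent simulation. Each
site is independently an ABBA-type ILS site (probability `pi_ils`/2 — all
focal specimens and the donor derived), a BABA-type ILS site (`pi_ils`/2 —
the conspecific reference and the donor derived), a species-diagnostic
fixed difference (`pi_fixed` — donor derived; each focal haplotype
independently carries the donor allele with that individual's admixture
proportion α), or invariant background. Genotype calls go missing i.i.d.
at `missing_rate`. This yields an exact closed form,

    E[D | α] = α · pi_fixed / (α · pi_fixed + pi_ils),

which is what the calibration tests and the acceptance script check the
estimator against.

Default conditions: `pi_fixed = 0.05`, `pi_ils = 0.10`,
`missing_rate = 0.01` (typical residual missingness for a filtered SNP
set), and admixture proportions `alpha_marine = 0.35`,
`alpha_freshwater = 0.068`, obtained by inverting the closed form against
the observed ecotype group means of D (≈ 0.149 marine, ≈ 0.033
freshwater) so that the synthetic cohort reproduces the introgression
contrast the pipeline is built to detect. The study-analog cohort in
`analysis/` uses 40 marine + 88 freshwater specimens (the real 271/599
split scaled ≈ 6.8×) over 20,000 sites — sizes at which every script and
test runs in seconds while leaving per-specimen jackknife SEs an order of
magnitude below the group contrast.

What the generator does *not* emulate: linkage (sites are independent, so
jackknife blocks are exchangeable by construction), admixture tracts
(admixture is haplotype-wise i.i.d. per site), allele-frequency spectra
within panels (focal lineages are fixed at ILS sites), reference bias, and
genotyping error beyond missingness. Passing tests therefore demonstrate
the correctness and calibration of the estimators under the model's
assumptions, not robustness to LD or to upstream calling artifacts; on
real data the block size is the user's lever against LD, and results
inherit whatever filters produced the input VCF.

A consequence worth noting: with a single per-individual α, the marine
donor-allele frequency at a fixed difference concentrates around α, so at
the cohort default α = 0.35 the strict > 0.5 scan calls almost nothing —
high-frequency introgressed loci require α near fixation, which is why the
planted-recovery analyses use α = 0.8. In real data α varies across loci
(selection can fix donor alleles locally), which the per-site i.i.d. model
deliberately does not capture.

## Numerical and design details

- Dosages are int8 with −1 as the missing sentinel; all frequency math is
  float64.
- Sites are strictly sorted by (chrom, pos); duplicates are an input
  error, multiallelic/indel records are dropped with a logged count.
- The exact rank-sum path is limited to groups of ≤ 8 tie-free values,
  where enumeration (≤ 12,870 assignments) is instant and the normal
  approximation is at its worst.
- Calibration checks pool coverage across the four admixture levels
  (4 × 100 replicates): at a per-replicate miss rate of ~0.3% (|Z| > 3),
  a 99% bound is only statistically meaningful at the pooled sample size.
- Pipeline outputs are byte-deterministic given config and seed; the JSON
  run report carries config echo, stage counts, the selected conspecific
  reference and wall-clock, and partial outputs are removed on failure.

## Limitations

Single-SNP locus granularity; no f4-ratio/fd/windowed variants; no
genotype likelihoods (hard genotype calls in, dosages out); gene
assignment is positional only, with no homology mapping; and the group
comparison is a single test — no multiple-testing machinery is included
because the design performs one comparison.
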