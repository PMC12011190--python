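# introscan

Detection and localization of interspecific introgression from diploid
genotype data, built around the four-taxon ABBA-BABA test (Patterson's D).

The motivating system is gene flow from the three-spined stickleback
(*Gasterosteus aculeatus*) into marine and freshwater ecotypes of the
nine-spined stickleback (*Pungitius pungitius*), with the European seabass
(*Dicentrarchus labrax*) reference genome as the outgroup: if marine
nine-spined sticklebacks adapt to salinity partly through alleles acquired
from the (largely marine) three-spined stickleback, their genomes should
show a systematic excess of ABBA over BABA site patterns relative to
freshwater conspecifics. The package is for population geneticists who have
a multi-sample VCF of biallelic SNPs, per-sample ecotype labels, and one
reference specimen each for the conspecific and donor species, and who want
per-specimen introgression estimates, a group-level test, and a list of
candidate introgressed loci.

## The statistics

For a four-taxon configuration (((P1, P2), P3), O) — P1 a non-introgressed
conspecific reference, P2 the focal specimen, P3 the donor species, O the
outgroup that polarizes alleles — each site contributes frequency weights

    abba = (1 − p1) · p2 · p3 · (1 − p4)
    baba = p1 · (1 − p2) · p3 · (1 − p4)

where p_i is the derived-allele frequency in panel i (mean dosage / 2 over
called samples), and

    D = (Σ abba − Σ baba) / (Σ abba + Σ baba).

Under incomplete lineage sorting alone the two discordant patterns are
equally likely and E[D] = 0; gene flow from P3 into P2 inflates ABBA and
pushes D > 0. Because all genotypes are called against the outgroup
species' reference genome, the default polarization takes the outgroup
allele to be the reference base at every site (p4 = 0). Standard errors
come from a weighted delete-one-block jackknife over contiguous blocks of
sites; the marine/freshwater contrast uses the two-sample rank-sum
(Mann-Whitney) test; introgressed loci are sites homozygous-reference in
the least-introgressed freshwater specimen (minimal D), homozygous-
alternative in the donor specimen, with marine alternative-allele frequency
strictly above 0.5.

## Worked example

The repository is organized as an analysis project: `src/introscan/` holds
the library, and the numbered scripts under `analysis/` run the study on a
synthetic cohort with known admixture truth (no external data needed):

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_per_specimen_dstat.py
python analysis/03_ecotype_comparison.py
python analysis/04_locus_scan.py
```

which prints (seed 1):

```
marine: n = 40, mean D = 0.1558 (range 0.1452 .. 0.1646)
freshwater: n = 88, mean D = 0.0411 (range 0.0325 .. 0.0498)
rank-sum U = 3520.0, two-sided p = 1.494e-19 [normal_approx]
selected conspecific reference (minimal D): fresh_005
514 informative sites -> 278 called loci in 278 distinct genes
planted-site sensitivity at threshold > 0.5: 98.6% (278/282)
```

Reading: every marine specimen carries a clear ABBA excess (mean D ≈ 0.16)
while freshwater specimens sit near zero, the rank-sum test finds the
group difference overwhelmingly significant, and the locus scan recovers
98.6% of the donor alleles planted at high marine frequency. Tables land
in `results/`, the simulated cohort in `scratch/`.

The same chain runs from a single config file:

```bash
introscan run --config examples/run_simulated.yaml
```

and each stage (`introscan simulate / dstat / compare / scan`) is
independently invocable on real VCF + metadata inputs.

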