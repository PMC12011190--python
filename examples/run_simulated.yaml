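# Full pipeline on a synthetic cohort with known admixture truth.
# Swap the `simulate` block for an `input` block (vcf / metadata /
# annotation paths) to run on real data.
simulate:
  n_sites: 20000
  n_marine: 40
  n_freshwater: 88
  alpha_marine: 0.35
  alpha_freshwater: 0.068
  pi_fixed: 0.05
  pi_ils: 0.10
  missing_rate: 0.01
dstat:
  block_size: 2000
scan:
  threshold: 0.5
output_dir: scratch/run_simulated
seed: 1
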