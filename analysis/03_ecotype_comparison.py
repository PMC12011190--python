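"""Marine vs freshwater comparison of the per-specimen D distributions.

Reads results/dstat_per_specimen.tsv (from 02_per_specimen_dstat.py) and
the cohort metadata, runs the two-sided rank-sum test, and writes the
single-row summary to results/ecotype_comparison.tsv.
"""

import argparse
from pathlib import Path

from introscan.dstat import read_dresults_tsv
from introscan.genotype_io import read_sample_metadata
from introscan.group_compare import compare_ecotypes

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()
    results = read_dresults_tsv(ROOT / "results" / "dstat_per_specimen.tsv")
    samples = read_sample_metadata(ROOT / "scratch" / "cohort" / "samples.tsv")
    cmp = compare_ecotypes(results, samples)
    out = ROOT / "results" / "ecotype_comparison.tsv"
    cmp.to_tsv(out)
    print(f"marine mean D = {cmp.mean_d_marine:.6f} (n = {cmp.n_marine}); "
          f"freshwater mean D = {cmp.mean_d_freshwater:.6f} (n = {cmp.n_freshwater})")
    print(f"rank-sum U = {cmp.u_statistic:.1f}, two-sided p = {cmp.p_value:.3e} "
          f"[{cmp.method}]")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
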