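"""Per-specimen ABBA-BABA D scan over the study-analog cohort.

Reads the cohort fixture written by 01_simulate_cohort.py, computes one D
statistic per focal specimen (P1 = the designated conspecific reference,
P3 = the donor reference, outgroup = the reference allele), and writes the
per-specimen table to results/dstat_per_specimen.tsv.
"""

import argparse
from pathlib import Path

import numpy as np

from introscan.dstat import per_specimen_scan, write_dresults_tsv
from introscan.genotype_io import read_sample_metadata, read_vcf

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--block-size", type=int, default=2000)
    args = ap.parse_args()

    fx = ROOT / "scratch" / "cohort"
    gm = read_vcf(fx / "sim.vcf")
    samples = read_sample_metadata(fx / "samples.tsv")
    focal = list(samples.marine_ids) + list(samples.freshwater_ids)
    print(f"{gm.n_sites} sites x {gm.n_samples} samples; scanning {len(focal)} specimens")

    results = per_specimen_scan(gm, samples, samples.p1_reference_id,
                                samples.p3_reference_id, focal,
                                block_size=args.block_size)
    out = ROOT / "results" / "dstat_per_specimen.tsv"
    out.parent.mkdir(exist_ok=True)
    write_dresults_tsv(results, out)

    for eco, ids in (("marine", samples.marine_ids), ("freshwater", samples.freshwater_ids)):
        ds = np.array([r.d for r in results if r.focal_id in ids])
        print(f"{eco}: n = {ds.size}, mean D = {ds.mean():.4f} "
              f"(range {ds.min():.4f} .. {ds.max():.4f})")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
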