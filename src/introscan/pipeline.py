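"""End-to-end orchestration of the introgression analysis.

The pipeline runs, in order: the per-specimen D scan, the marine vs
freshwater comparison, the re-selection of the least-introgressed
freshwater specimen as the locus-scan conspecific reference, the
donor-allele locus scan, and positional gene annotation.  It writes the
per-specimen TSV, the comparison TSV, the hits TSV, the distinct-gene list
and a versioned JSON run report; on failure, partial outputs are removed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

from . import __version__
from .config import RunConfig
from .dstat import per_specimen_scan, write_dresults_tsv
from .genotype_io import (
    GeneAnnotation,
    read_gene_intervals,
    read_sample_metadata,
    read_vcf,
)
from .group_compare import compare_ecotypes
from .locus_scan import (
    annotate_loci,
    call_introgressed_loci,
    filter_informative_loci,
    marine_alt_freq,
    select_p1_reference,
    write_gene_list,
    write_hits_tsv,
)
from .simulate import SimParams, write_fixture

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs have been removed."""


def _load_inputs(config: RunConfig, out_dir: Path, written: list[Path]):
    if config.simulate is not None:
        params = SimParams(seed=config.seed, **config.simulate.model_dump())
        fixture_dir = out_dir / "simulated"
        paths = write_fixture(params, fixture_dir)
        written.extend(paths.values())
        gm = read_vcf(paths["vcf"])
        samples = read_sample_metadata(paths["metadata"])
        annotation = read_gene_intervals(paths["bed"], format="bed")
        return gm, samples, annotation
    inp = config.input
    gm = read_vcf(inp.vcf)
    samples = read_sample_metadata(inp.metadata)
    annotation = (
        read_gene_intervals(inp.annotation, format=inp.annotation_format)
        if inp.annotation
        else GeneAnnotation(intervals=())
    )
    return gm, samples, annotation


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis chain and write all outputs.

    Returns the run report (also written as ``run_report.json``).
    Idempotent: identical config and seed give byte-identical TSV outputs.
    """
    t0 = time.time()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "load_inputs"
        gm, samples, annotation = _load_inputs(config, out_dir, written)

        stage = "per_specimen_dstat"
        p1_ref = samples.p1_reference_id
        p3_ref = samples.p3_reference_id
        if p1_ref is None or p3_ref is None:
            raise ValueError("metadata must designate one p1_reference and one p3_reference")
        focal_ids = [
            s
            for s in samples.ids_where(species="focal", role="none")
            if samples.ecotype_of(s) in ("marine", "freshwater")
        ]
        dresults = per_specimen_scan(
            gm,
            samples,
            p1_ref,
            p3_ref,
            focal_ids,
            block_size=config.dstat.block_size,
            hard_call=config.dstat.hard_call,
        )
        dstat_path = out_dir / "dstat_per_specimen.tsv"
        write_dresults_tsv(dresults, dstat_path)
        written.append(dstat_path)

        stage = "ecotype_comparison"
        comparison = compare_ecotypes(
            dresults,
            samples,
            alternative=config.compare.alternative,
            continuity=config.compare.continuity,
        )
        cmp_path = out_dir / "ecotype_comparison.tsv"
        comparison.to_tsv(cmp_path)
        written.append(cmp_path)

        stage = "p1_reference_selection"
        fresh_ids = [f for f in focal_ids if samples.ecotype_of(f) == "freshwater"]
        scan_p1 = select_p1_reference(dresults, fresh_ids)

        stage = "locus_scan"
        informative = filter_informative_loci(gm, scan_p1, p3_ref)
        marine_ids = [m for m in samples.marine_ids if m != scan_p1]
        freqs = marine_alt_freq(gm, informative, marine_ids, min_called=config.scan.min_called)
        hits = call_introgressed_loci(
            gm, informative, freqs, marine_ids, threshold=config.scan.threshold
        )

        stage = "annotation"
        hits, n_genes = annotate_loci(hits, annotation)
        hits_path = out_dir / "introgressed_loci.tsv"
        write_hits_tsv(hits, hits_path)
        written.append(hits_path)
        genes_path = out_dir / "introgressed_genes.txt"
        write_gene_list(hits, genes_path)
        written.append(genes_path)

        stage = "report"
        report = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "introscan_version": __version__,
            "config": config.model_dump(),
            "seed": config.seed,
            "counts": {
                "n_sites": gm.n_sites,
                "n_samples": gm.n_samples,
                "n_focal_specimens": len(focal_ids),
                "n_marine": comparison.n_marine,
                "n_freshwater": comparison.n_freshwater,
                "n_informative_sites": int(len(informative)),
                "n_hits": len(hits),
                "n_distinct_genes": n_genes,
            },
            "comparison": dataclasses.asdict(comparison),
            "selected_p1_reference": scan_p1,
            "wall_clock_sec": round(time.time() - t0, 3),
        }
        report_path = out_dir / "run_report.json"
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=1)
        return report
    except Exception as exc:
        logger.error("pipeline failed at stage '%s': %s", stage, exc)
        for p in written:
            try:
                Path(p).unlink(missing_ok=True)
            except OSError:
                pass
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
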