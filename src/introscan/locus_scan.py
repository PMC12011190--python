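"""Locus-level scan for introgressed sites.

A site is informative for the scan when the conspecific reference specimen
is homozygous for the reference allele (dosage 0) and the donor-species
reference specimen is homozygous for the alternative allele (dosage 2):
the alternative allele is then diagnostic of donor ancestry.  Among the
informative sites, those where the donor allele's frequency in the marine
ecotype strictly exceeds a threshold (default 0.5) are called introgressed
and annotated with overlapping genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dstat import DResult
from .genotype_io import MISSING, GeneAnnotation, GenotypeMatrix


@dataclass
class LocusHit:
    """A called introgressed site (1-based VCF coordinates)."""

    chrom: str
    pos: int
    alt_freq_marine: float
    n_called_marine: int
    n_alt_alleles_marine: int
    gene_ids: tuple[str, ...] = ()


def select_p1_reference(dresults: Sequence[DResult], candidate_ids: Sequence[str]) -> str:
    """The candidate specimen with minimal D (the least-introgressed genome).

    Ties are broken by lexicographically smallest sample id.  Candidates
    with NA D are ignored; if none remain, a ``ValueError`` is raised.
    """
    if not candidate_ids:
        raise ValueError("candidate_ids must be non-empty")
    by_id = {r.focal_id: r for r in dresults}
    usable = []
    for cid in candidate_ids:
        r = by_id.get(cid)
        if r is None:
            raise LookupError(f"candidate {cid!r} has no D result")
        if not r.is_na:
            usable.append((r.d, cid))
    if not usable:
        raise ValueError("all candidate specimens have NA D values")
    return min(usable)[1]


def filter_informative_loci(gm: GenotypeMatrix, p1_ref: str, p3_ref: str) -> np.ndarray:
    """Indices of sites with p1_ref dosage 0 and p3_ref dosage 2.

    Sites where either reference specimen is missing or heterozygous are
    excluded.
    """
    i1 = gm.column_index([p1_ref])[0]
    i3 = gm.column_index([p3_ref])[0]
    keep = (gm.dosages[:, i1] == 0) & (gm.dosages[:, i3] == 2)
    return np.flatnonzero(keep)


def marine_alt_freq(
    gm: GenotypeMatrix,
    sites: Sequence[int],
    marine_ids: Sequence[str],
    min_called: int = 1,
) -> np.ndarray:
    """Alternative-allele frequency in the marine ecotype at the given sites.

    Per site: (sum of non-missing marine dosages) / (2 x number of called
    marine samples).  Sites with fewer than ``min_called`` called marine
    samples get NaN; no imputation is performed.
    """
    if not len(marine_ids):
        raise ValueError("marine_ids must be non-empty")
    if min_called < 1:
        raise ValueError("min_called must be >= 1")
    sites = np.asarray(sites, dtype=np.intp)
    cols = gm.column_index(marine_ids)
    dos = gm.dosages[np.ix_(sites, cols)].astype(float)
    called = dos != MISSING
    n_called = called.sum(axis=1)
    total = np.where(called, dos, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called >= min_called, total / (2.0 * n_called), np.nan)
    return freq


def call_introgressed_loci(
    gm: GenotypeMatrix,
    sites: Sequence[int],
    freqs: Sequence[float],
    marine_ids: Sequence[str],
    threshold: float = 0.5,
) -> list[LocusHit]:
    """Call sites whose marine alternative-allele frequency strictly exceeds
    ``threshold``.

    NA frequencies are never called.  Hits are returned sorted by
    (chrom, pos) and carry the supporting marine call counts.
    """
    if not (0.0 <= threshold < 1.0):
        raise ValueError("threshold must be in [0, 1)")
    sites = np.asarray(sites, dtype=np.intp)
    freqs = np.asarray(freqs, dtype=float)
    if sites.shape != freqs.shape:
        raise ValueError("sites and freqs must have equal length")
    cols = gm.column_index(marine_ids)
    hits: list[LocusHit] = []
    for si, f in zip(sites, freqs):
        if math.isnan(f) or f <= threshold:
            continue
        dos = gm.dosages[si, cols]
        called = dos != MISSING
        hits.append(
            LocusHit(
                chrom=str(gm.chrom[si]),
                pos=int(gm.pos[si]),
                alt_freq_marine=float(f),
                n_called_marine=int(called.sum()),
                n_alt_alleles_marine=int(dos[called].sum()),
            )
        )
    hits.sort(key=lambda h: (h.chrom, h.pos))
    return hits


def annotate_loci(
    hits: Sequence[LocusHit], genes: GeneAnnotation
) -> tuple[list[LocusHit], int]:
    """Assign overlapping gene ids to each hit.

    A hit at 1-based position ``pos`` is assigned every gene whose 0-based
    half-open interval contains ``pos - 1``; hits with no overlap keep an
    empty gene list and are retained.  Returns the annotated hits and the
    number of distinct genes assigned over all hits.
    """
    annotated: list[LocusHit] = []
    all_genes: set[str] = set()
    for h in hits:
        gids = genes.genes_at(h.chrom, h.pos - 1)
        all_genes.update(gids)
        annotated.append(
            LocusHit(
                chrom=h.chrom,
                pos=h.pos,
                alt_freq_marine=h.alt_freq_marine,
                n_called_marine=h.n_called_marine,
                n_alt_alleles_marine=h.n_alt_alleles_marine,
                gene_ids=gids,
            )
        )
    return annotated, len(all_genes)


def write_hits_tsv(hits: Sequence[LocusHit], path) -> None:
    cols = ("chrom", "pos", "alt_freq_marine", "n_called_marine", "n_alt_alleles_marine", "gene_ids")
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        for h in hits:
            fh.write(
                f"{h.chrom}\t{h.pos}\t{h.alt_freq_marine:.10g}\t"
                f"{h.n_called_marine}\t{h.n_alt_alleles_marine}\t"
                f"{';'.join(h.gene_ids)}\n"
            )


def write_gene_list(hits: Sequence[LocusHit], path) -> int:
    """One distinct gene id per line, sorted; returns the count."""
    genes = sorted({g for h in hits for g in h.gene_ids})
    with open(path, "w") as fh:
        for g in genes:
            fh.write(g + "\n")
    return len(genes)
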