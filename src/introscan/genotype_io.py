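"""Genotype, sample-metadata and gene-annotation I/O.

The in-memory model is deliberately small: a :class:`GenotypeMatrix` of
diploid alternative-allele dosages (0/1/2, with a ``MISSING`` sentinel) for
biallelic SNPs, a :class:`SampleSet` carrying species/ecotype/role labels,
and a :class:`GeneAnnotation` of 0-based half-open gene intervals.  Phase is
ignored throughout: every downstream quantity (panel allele frequency,
homozygosity, D) depends on dosage only.

Coordinates are 1-based for sites (as in VCF) and 0-based half-open for
intervals; BED is taken as-is, GFF3 is converted on read.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for an uncalled (or half-called) diploid genotype.
MISSING: int = -1

_BASES = frozenset("ACGT")

ECOTYPES = ("marine", "freshwater", "NA")
SPECIES = ("focal", "donor")
ROLES = ("none", "p1_reference", "p3_reference", "outgroup_proxy")


class FormatError(ValueError):
    """A file violates its format contract (VCF/BED/GFF3/TSV)."""


class ValidationError(ValueError):
    """In-memory data violates a model invariant."""


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# GenotypeMatrix


@dataclass
class GenotypeMatrix:
    """Sites x samples table of diploid alternative-allele dosages.

    Attributes
    ----------
    chrom, pos : arrays of per-site chromosome label and 1-based position.
    ref, alt : single-base reference/alternative alleles per site.
    dosages : ``(n_sites, n_samples)`` int8 array with values in
        ``{0, 1, 2, MISSING}``.
    sample_ids : ordered unique sample identifiers (one per column).
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosages: np.ndarray
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            self.dosages = self.dosages.reshape(len(self.pos), -1)
        self.sample_ids = tuple(str(s) for s in self.sample_ids)
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        n_sites = len(self.pos)
        for name, arr in (("chrom", self.chrom), ("ref", self.ref), ("alt", self.alt)):
            if len(arr) != n_sites:
                raise ValidationError(f"{name} has {len(arr)} entries for {n_sites} sites")
        if self.dosages.shape != (n_sites, len(self.sample_ids)):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} != ({n_sites}, {len(self.sample_ids)})"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValidationError("dosages must be 0, 1, 2 or MISSING")
        for r, a in zip(self.ref, self.alt):
            if r == a or r not in _BASES or a not in _BASES:
                raise ValidationError(f"not a biallelic SNP: ref={r!r} alt={a!r}")
        if n_sites > 1:
            keys = list(zip(self.chrom, self.pos))
            if any(k2 <= k1 for k1, k2 in zip(keys, keys[1:])):
                raise ValidationError("sites must be sorted by (chrom, pos) without duplicates")

    # -- helpers -----------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column_index(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Column indices for the given sample ids (LookupError if absent)."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=np.intp)
        except KeyError as exc:
            raise LookupError(f"sample {exc.args[0]!r} not in genotype matrix") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.dosages, other.dosages)
        )


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path, allowed_samples: Sequence[str] | None = None) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are kept; multiallelic records and indels are
    dropped with a logged count.  Diploid GT fields are parsed to dosages;
    half-missing genotypes (one called allele) map to ``MISSING``.  Sites are
    sorted by (chrom, pos); duplicate sites are rejected.

    Parameters
    ----------
    path : str or Path
        Plain or gzip/bgzip-compressed VCF.
    allowed_samples : optional list of sample ids
        Restrict the matrix to these columns; a missing id raises
        ``LookupError``.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad files
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc

    if allowed_samples is not None:
        missing = set(allowed_samples) - set(vcf.samples)
        if missing:
            raise LookupError(f"samples not in VCF: {sorted(missing)}")
        vcf.set_samples(list(allowed_samples))
    samples = tuple(vcf.samples)

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[list[int]] = []
    n_dropped = 0
    try:
        for var in vcf:
            if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
                n_dropped += 1
                continue
            if var.REF not in _BASES or var.ALT[0] not in _BASES:
                n_dropped += 1
                continue
            row = []
            for gt in var.genotypes:
                alleles = gt[:-1]  # last element is the phased flag
                if len(alleles) != 2 or min(alleles) < 0:
                    row.append(MISSING)
                else:
                    row.append(int(alleles[0] > 0) + int(alleles[1] > 0))
            chroms.append(var.CHROM)
            poss.append(var.POS)
            refs.append(var.REF)
            alts.append(var.ALT[0])
            rows.append(row)
    except Exception as exc:
        raise FormatError(f"malformed VCF record in {path} near site {len(rows) + 1}: {exc}") from exc
    finally:
        vcf.close()

    if n_dropped:
        logger.info("read_vcf: dropped %d non-SNP/multiallelic records from %s", n_dropped, path)

    chrom = np.asarray(chroms, dtype=object)
    pos = np.asarray(poss, dtype=np.int64)
    order = np.lexsort((pos, chrom))
    keys = [(chroms[i], poss[i]) for i in order]
    if any(k1 == k2 for k1, k2 in zip(keys, keys[1:])):
        dup = next(k1 for k1, k2 in zip(keys, keys[1:]) if k1 == k2)
        raise FormatError(f"duplicate site {dup[0]}:{dup[1]} in {path}")
    dos = (
        np.asarray(rows, dtype=np.int8)[order]
        if rows
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    return GenotypeMatrix(
        chrom=chrom[order],
        pos=pos[order],
        ref=np.asarray(refs, dtype=object)[order],
        alt=np.asarray(alts, dtype=object)[order],
        dosages=dos,
        sample_ids=samples,
    )


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 (GT-only FORMAT) for a genotype matrix.

    Heterozygotes are written unphased in canonical order (``0/1``),
    ``MISSING`` as ``./.``.  A ``.gz`` suffix selects gzip compression.
    """
    seen: list[str] = []
    for c in gm.chrom:
        if c not in seen:
            seen.append(c)
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in seen:
            fh.write(f"##contig=<ID={c}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + list(gm.sample_ids)) + "\n")
        for i in range(gm.n_sites):
            gts = "\t".join(_GT_STRINGS[int(d)] for d in gm.dosages[i])
            fh.write(
                f"{gm.chrom[i]}\t{gm.pos[i]}\t.\t{gm.ref[i]}\t{gm.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# SampleSet


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    species: str
    ecotype: str = "NA"
    role: str = "none"


@dataclass
class SampleSet:
    """Sample ids with species, ecotype and reference-role labels."""

    records: tuple[SampleRecord, ...]

    def __post_init__(self) -> None:
        self.records = tuple(self.records)
        self.validate()

    def validate(self) -> None:
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample_id(s): {dup}")
        for r in self.records:
            if r.species not in SPECIES:
                raise ValidationError(f"unknown species {r.species!r} for {r.sample_id}")
            if r.ecotype not in ECOTYPES:
                raise ValidationError(f"unknown ecotype {r.ecotype!r} for {r.sample_id}")
            if r.role not in ROLES:
                raise ValidationError(f"unknown role {r.role!r} for {r.sample_id}")
            if r.ecotype != "NA" and r.species != "focal":
                raise ValidationError(
                    f"{r.sample_id}: ecotype labels apply to focal-species samples only"
                )
        for role in ("p1_reference", "p3_reference"):
            n = sum(r.role == role for r in self.records)
            if n > 1:
                raise ValidationError(f"at most one {role} sample allowed, found {n}")

    # -- accessors ---------------------------------------------------------
    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.sample_id for r in self.records)

    def ids_where(self, *, species=None, ecotype=None, role=None) -> tuple[str, ...]:
        out = []
        for r in self.records:
            if species is not None and r.species != species:
                continue
            if ecotype is not None and r.ecotype != ecotype:
                continue
            if role is not None and r.role != role:
                continue
            out.append(r.sample_id)
        return tuple(out)

    @property
    def marine_ids(self) -> tuple[str, ...]:
        return self.ids_where(ecotype="marine")

    @property
    def freshwater_ids(self) -> tuple[str, ...]:
        return self.ids_where(ecotype="freshwater")

    def _unique_role(self, role: str) -> str | None:
        ids = self.ids_where(role=role)
        return ids[0] if ids else None

    @property
    def p1_reference_id(self) -> str | None:
        return self._unique_role("p1_reference")

    @property
    def p3_reference_id(self) -> str | None:
        return self._unique_role("p3_reference")

    def ecotype_of(self, sample_id: str) -> str:
        for r in self.records:
            if r.sample_id == sample_id:
                return r.ecotype
        raise LookupError(f"sample {sample_id!r} not in SampleSet")

    def to_tsv(self, path) -> None:
        with _open_text(path, "wt") as fh:
            fh.write("sample_id\tspecies\tecotype\trole\n")
            for r in self.records:
                fh.write(f"{r.sample_id}\t{r.species}\t{r.ecotype}\t{r.role}\n")


def read_sample_metadata(path) -> SampleSet:
    """Read the sample-metadata TSV (sample_id, species, ecotype, role)."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "species", "ecotype", "role"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"metadata {path} lacks column(s) {missing}")
    records = [
        SampleRecord(
            sample_id=row.sample_id,
            species=row.species,
            ecotype=row.ecotype if row.ecotype not in ("", "na", ".") else "NA",
            role=row.role if row.role != "" else "none",
        )
        for row in df.itertuples()
    ]
    return SampleSet(records=tuple(records))


# ---------------------------------------------------------------------------
# Gene annotation


@dataclass
class GeneAnnotation:
    """Gene intervals, 0-based half-open, with positional overlap lookup.

    Strand is stored but never used in overlap tests: locus-to-gene
    assignment is purely positional.
    """

    intervals: tuple[tuple[str, int, int, str, str], ...]  # chrom, start, end, strand, gene_id

    def __post_init__(self) -> None:
        self.intervals = tuple(self.intervals)
        for chrom, start, end, strand, gene_id in self.intervals:
            if start < 0 or start >= end:
                raise FormatError(f"bad interval {chrom}:{start}-{end} for {gene_id!r}")
            if not gene_id:
                raise FormatError(f"empty gene_id at {chrom}:{start}-{end}")
        self._trees = None

    def _build_trees(self):
        from intervaltree import IntervalTree

        trees: dict[str, "IntervalTree"] = {}
        for chrom, start, end, _strand, gene_id in self.intervals:
            trees.setdefault(chrom, IntervalTree()).addi(start, end, gene_id)
        return trees

    def genes_at(self, chrom: str, pos0: int) -> tuple[str, ...]:
        """Gene ids whose half-open interval contains 0-based position pos0."""
        if self._trees is None:
            self._trees = self._build_trees()
        tree = self._trees.get(chrom)
        if tree is None:
            return ()
        return tuple(sorted({iv.data for iv in tree.at(pos0)}))

    def __len__(self) -> int:
        return len(self.intervals)


def _read_bed(path) -> list[tuple[str, int, int, str, str]]:
    out = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: BED4+ required (chrom, start, end, name)")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            out.append((chrom, start, end, strand, name))
    return out


def _read_gff3(path) -> list[tuple[str, int, int, str, str]]:
    import gffutils

    with _open_text(path) as fh:
        text = fh.read()
    try:
        db = gffutils.create_db(
            text, dbfn=":memory:", from_string=True, merge_strategy="create_unique", keep_order=True
        )
    except Exception as exc:
        raise FormatError(f"cannot parse GFF3 {path}: {exc}") from exc
    out = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", feat.attributes.get("gene_id", [""]))[0]
        # GFF3 is 1-based closed; convert to 0-based half-open
        out.append((feat.seqid, feat.start - 1, feat.end, feat.strand or ".", gene_id))
    return out


def read_gene_intervals(path, format: str = "bed") -> GeneAnnotation:
    """Read gene intervals from BED (0-based half-open) or GFF3 (1-based closed).

    GFF3 parsing keeps ``gene`` features only; the gene id is taken from the
    ``ID`` (fallback ``gene_id``) attribute.  Both formats yield the same
    internal 0-based half-open convention.
    """
    if format == "bed":
        intervals = _read_bed(path)
    elif format == "gff3":
        intervals = _read_gff3(path)
    else:
        raise ValueError(f"unknown annotation format {format!r} (expected 'bed' or 'gff3')")
    return GeneAnnotation(intervals=tuple(intervals))
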