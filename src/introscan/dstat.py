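"""Patterson's D (ABBA-BABA) from genotype dosages, with block-jackknife SE.

The four-taxon configuration follows the usual (((P1,P2),P3),O) topology:
P1 is a non-introgressed conspecific reference panel, P2 the focal
specimen(s) under test, P3 the donor species, and the outgroup O polarizes
alleles.  Because the study design maps all reads against the outgroup
species' reference genome, the default polarization takes the outgroup
allele to be the reference base at every site (derived = alternative
allele, p4 = 0); a sample-based outgroup panel is supported for generality.

The estimator is the frequency-weighted (population allele frequency) form:
per site, with derived-allele frequencies p1, p2, p3, p4,

    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    D    = (sum abba - sum baba) / (sum abba + sum baba)

Uncertainty comes from a weighted delete-one-block jackknife over
contiguous genomic blocks of sites, which is robust to linkage between
nearby sites.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, SampleSet

logger = logging.getLogger(__name__)

DEFAULT_BLOCK_SIZE = 5000


@dataclass
class PanelConfig:
    """Sample panels for one four-taxon test.

    ``outgroup_mode`` is ``"reference_allele"`` (p4 = 0 everywhere; the
    alternative allele is derived relative to the outgroup-species
    reference) or ``"sample_ids"`` (p4 from the ``outgroup_samples`` panel).
    """

    p1_samples: tuple[str, ...]
    p2_samples: tuple[str, ...]
    p3_samples: tuple[str, ...]
    outgroup_mode: str = "reference_allele"
    outgroup_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.p1_samples = tuple(self.p1_samples)
        self.p2_samples = tuple(self.p2_samples)
        self.p3_samples = tuple(self.p3_samples)
        self.outgroup_samples = tuple(self.outgroup_samples)
        if not (self.p1_samples and self.p2_samples and self.p3_samples):
            raise ValueError("P1, P2 and P3 panels must all be non-empty")
        if self.outgroup_mode not in ("reference_allele", "sample_ids"):
            raise ValueError(f"unknown outgroup_mode {self.outgroup_mode!r}")
        if self.outgroup_mode == "sample_ids" and not self.outgroup_samples:
            raise ValueError("outgroup_mode='sample_ids' requires outgroup_samples")
        panels = [self.p1_samples, self.p2_samples, self.p3_samples, self.outgroup_samples]
        all_ids = [s for panel in panels for s in panel]
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("the four panels must be pairwise disjoint")


@dataclass
class SiteWeights:
    """Per-usable-site ABBA/BABA weights, ordered by genome position."""

    site_index: np.ndarray  # indices into the GenotypeMatrix
    abba: np.ndarray
    baba: np.ndarray

    def __post_init__(self) -> None:
        self.site_index = np.asarray(self.site_index, dtype=np.intp)
        self.abba = np.asarray(self.abba, dtype=float)
        self.baba = np.asarray(self.baba, dtype=float)
        if not (len(self.site_index) == len(self.abba) == len(self.baba)):
            raise ValueError("site_index, abba and baba must have equal length")


@dataclass
class DResult:
    """One four-taxon D test for a focal specimen (or panel)."""

    focal_id: str
    d: float
    sum_abba: float
    sum_baba: float
    n_sites_used: int
    jackknife_se: float
    z_score: float
    n_blocks: int
    status: str = "ok"

    @property
    def is_na(self) -> bool:
        return not math.isfinite(self.d)


def site_pattern_weights(p1, p2, p3, p4):
    """ABBA and BABA weights from derived-allele frequencies (vectorized).

    Returns ``(abba, baba)`` with
    ``abba = (1-p1) p2 p3 (1-p4)`` and ``baba = p1 (1-p2) p3 (1-p4)``.
    BBAA-type (species tree) sites get weight (0, 0) and contribute nothing.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    for name, p in (("p1", p1), ("p2", p2), ("p3", p3), ("p4", p4)):
        if np.any((p < 0) | (p > 1)):
            raise ValueError(f"{name} frequency outside [0, 1]")
    abba = (1.0 - p1) * p2 * p3 * (1.0 - p4)
    baba = p1 * (1.0 - p2) * p3 * (1.0 - p4)
    return abba, baba


def _panel_freq(gm: GenotypeMatrix, sample_ids: Sequence[str]) -> np.ndarray:
    """Derived-allele frequency per site: mean dosage / 2 over called samples.

    Sites where every sample in the panel is missing get NaN.
    """
    cols = gm.column_index(sample_ids)
    dos = gm.dosages[:, cols].astype(float)
    called = dos != MISSING
    n_called = called.sum(axis=1)
    total = np.where(called, dos, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, total / (2.0 * n_called), np.nan)
    return freq


def _hard_call(freq: np.ndarray) -> np.ndarray:
    """Round panel frequencies to 0/1; exact 0.5 becomes NaN (site dropped)."""
    out = np.where(freq > 0.5, 1.0, np.where(freq < 0.5, 0.0, np.nan))
    return np.where(np.isnan(freq), np.nan, out)


def site_weights(
    gm: GenotypeMatrix, panels: PanelConfig, hard_call: bool = False
) -> SiteWeights:
    """Per-site ABBA/BABA weights for usable sites, in genomic order.

    A site is usable when every required panel has at least one called
    sample (and, with ``hard_call``, no panel frequency is exactly 0.5).
    """
    p1 = _panel_freq(gm, panels.p1_samples)
    p2 = _panel_freq(gm, panels.p2_samples)
    p3 = _panel_freq(gm, panels.p3_samples)
    if panels.outgroup_mode == "reference_allele":
        p4 = np.zeros(gm.n_sites)
    else:
        p4 = _panel_freq(gm, panels.outgroup_samples)
    if hard_call:
        p1, p2, p3, p4 = (_hard_call(p) for p in (p1, p2, p3, p4))
    usable = ~(np.isnan(p1) | np.isnan(p2) | np.isnan(p3) | np.isnan(p4))
    idx = np.flatnonzero(usable)
    abba, baba = site_pattern_weights(p1[idx], p2[idx], p3[idx], p4[idx])
    return SiteWeights(site_index=idx, abba=abba, baba=baba)


def _d_from_sums(sum_abba: float, sum_baba: float) -> float:
    denom = sum_abba + sum_baba
    return (sum_abba - sum_baba) / denom if denom > 0 else float("nan")


def block_jackknife(
    weights: SiteWeights, block_size: int = DEFAULT_BLOCK_SIZE
) -> tuple[float, float, int]:
    """Weighted delete-one-block jackknife SE and Z for D.

    Usable sites (already in genomic order) are partitioned into contiguous
    blocks of ``block_size`` sites (last block possibly shorter).  The
    delete-m jackknife of Busing et al. weights blocks by their site counts,
    so an uneven final block does not bias the variance.  Returns
    ``(se, z, n_blocks)``; fewer than two blocks yields ``(nan, nan, g)``
    with a logged warning.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    n = len(weights.abba)
    g = math.ceil(n / block_size) if n else 0
    A = float(weights.abba.sum())
    B = float(weights.baba.sum())
    d_hat = _d_from_sums(A, B)
    if g < 2 or not math.isfinite(d_hat):
        if g < 2:
            logger.warning("block_jackknife: %d block(s) only; SE undefined", g)
        return float("nan"), float("nan"), g

    edges = np.arange(0, n + block_size, block_size)[: g + 1]
    edges[-1] = n
    cum_a = np.concatenate(([0.0], np.cumsum(weights.abba)))
    cum_b = np.concatenate(([0.0], np.cumsum(weights.baba)))
    block_a = cum_a[edges[1:]] - cum_a[edges[:-1]]
    block_b = cum_b[edges[1:]] - cum_b[edges[:-1]]
    m = (edges[1:] - edges[:-1]).astype(float)

    denom_j = (A - block_a) + (B - block_b)
    if np.any(denom_j <= 0):
        logger.warning("block_jackknife: a delete-one-block D is undefined; SE set to NA")
        return float("nan"), float("nan"), g
    theta_j = ((A - block_a) - (B - block_b)) / denom_j

    h = n / m
    theta_dot = g * d_hat - float(((1.0 - m / n) * theta_j).sum())
    resid = h * d_hat - (h - 1.0) * theta_j - theta_dot
    var = float((resid**2 / (h - 1.0)).sum()) / g
    se = math.sqrt(max(var, 0.0))
    z = d_hat / se if se > 0 else float("nan")
    return se, z, g


def compute_d(
    gm: GenotypeMatrix,
    panels: PanelConfig,
    block_size: int = DEFAULT_BLOCK_SIZE,
    hard_call: bool = False,
    focal_id: str | None = None,
) -> DResult:
    """Compute D with block-jackknife SE for one panel configuration.

    Per site, panel derived-allele frequencies are mean dosage / 2 over
    non-missing samples; sites where any required panel is entirely missing
    are skipped.  ``sum_abba + sum_baba == 0`` yields D = NaN with status
    ``"no_informative_sites"`` rather than an exception.
    """
    weights = site_weights(gm, panels, hard_call=hard_call)
    sum_abba = float(weights.abba.sum())
    sum_baba = float(weights.baba.sum())
    d = _d_from_sums(sum_abba, sum_baba)
    label = focal_id if focal_id is not None else "+".join(panels.p2_samples)
    if not math.isfinite(d):
        return DResult(
            focal_id=label,
            d=float("nan"),
            sum_abba=sum_abba,
            sum_baba=sum_baba,
            n_sites_used=len(weights.abba),
            jackknife_se=float("nan"),
            z_score=float("nan"),
            n_blocks=0,
            status="no_informative_sites",
        )
    se, z, n_blocks = block_jackknife(weights, block_size)
    return DResult(
        focal_id=label,
        d=d,
        sum_abba=sum_abba,
        sum_baba=sum_baba,
        n_sites_used=len(weights.abba),
        jackknife_se=se,
        z_score=z,
        n_blocks=n_blocks,
    )


def per_specimen_scan(
    gm: GenotypeMatrix,
    samples: SampleSet,
    p1_ref: str,
    p3_ref: str,
    focal_ids: Sequence[str],
    block_size: int = DEFAULT_BLOCK_SIZE,
    hard_call: bool = False,
) -> list[DResult]:
    """One D test per focal specimen: P2 = {focal}, P1 = {p1_ref}, P3 = {p3_ref}.

    Uses reference-allele outgroup polarization throughout.  Per-specimen
    failures are captured in the result's ``status`` field; the scan
    continues over the remaining specimens.  Output order matches
    ``focal_ids``.
    """
    if p1_ref in focal_ids or p3_ref in focal_ids:
        raise ValueError("focal_ids must be disjoint from the P1/P3 reference specimens")
    results: list[DResult] = []
    for fid in focal_ids:
        try:
            panels = PanelConfig(
                p1_samples=(p1_ref,), p2_samples=(fid,), p3_samples=(p3_ref,)
            )
            results.append(
                compute_d(gm, panels, block_size=block_size, hard_call=hard_call, focal_id=fid)
            )
        except (LookupError, ValueError) as exc:
            logger.warning("per_specimen_scan: %s failed: %s", fid, exc)
            results.append(
                DResult(
                    focal_id=fid,
                    d=float("nan"),
                    sum_abba=float("nan"),
                    sum_baba=float("nan"),
                    n_sites_used=0,
                    jackknife_se=float("nan"),
                    z_score=float("nan"),
                    n_blocks=0,
                    status=f"error: {exc}",
                )
            )
    return results


# ---------------------------------------------------------------------------
# TSV serialization of per-specimen results

_DRESULT_COLUMNS = (
    "focal_id",
    "d",
    "sum_abba",
    "sum_baba",
    "n_sites_used",
    "jackknife_se",
    "z_score",
    "n_blocks",
    "status",
)


def write_dresults_tsv(results: Sequence[DResult], path) -> None:
    """Per-specimen TSV with a '#'-prefixed header and deterministic columns."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_DRESULT_COLUMNS) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    [
                        r.focal_id,
                        f"{r.d:.10g}",
                        f"{r.sum_abba:.10g}",
                        f"{r.sum_baba:.10g}",
                        str(r.n_sites_used),
                        f"{r.jackknife_se:.10g}",
                        f"{r.z_score:.10g}",
                        str(r.n_blocks),
                        r.status,
                    ]
                )
                + "\n"
            )


def read_dresults_tsv(path) -> list[DResult]:
    results = []
    with open(path) as fh:
        header = fh.readline().lstrip("#").rstrip("\n").split("\t")
        if tuple(header) != _DRESULT_COLUMNS:
            raise ValueError(f"unexpected per-specimen TSV header in {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            results.append(
                DResult(
                    focal_id=f[0],
                    d=float(f[1]),
                    sum_abba=float(f[2]),
                    sum_baba=float(f[3]),
                    n_sites_used=int(f[4]),
                    jackknife_se=float(f[5]),
                    z_score=float(f[6]),
                    n_blocks=int(f[7]),
                    status=f[8],
                )
            )
    return results
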