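"""Marine vs freshwater comparison of per-specimen D values.

The two ecotype groups are independent samples, so the "Wilcoxon test" of
the study design is the two-sample rank-sum (Mann-Whitney U) test.  Small
tie-free problems use exact enumeration of the U distribution; everything
else uses the normal approximation with midrank tie correction and an
optional continuity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .dstat import DResult
from .genotype_io import SampleSet

logger = logging.getLogger(__name__)

_ALTERNATIVES = {"two_sided": "two-sided", "greater": "greater", "less": "less"}

#: Largest group size for which the exact null distribution is enumerated.
EXACT_MAX_N = 8


@dataclass
class EcotypeComparison:
    """Group means and rank-sum test for marine vs freshwater D values."""

    n_marine: int
    n_freshwater: int
    mean_d_marine: float
    mean_d_freshwater: float
    u_statistic: float
    p_value: float
    method: str  # "exact" or "normal_approx"

    def to_tsv(self, path) -> None:
        cols = (
            "n_marine",
            "n_freshwater",
            "mean_d_marine",
            "mean_d_freshwater",
            "u_statistic",
            "p_value",
            "method",
        )
        with open(path, "w") as fh:
            fh.write("#" + "\t".join(cols) + "\n")
            fh.write(
                f"{self.n_marine}\t{self.n_freshwater}\t"
                f"{self.mean_d_marine:.10g}\t{self.mean_d_freshwater:.10g}\t"
                f"{self.u_statistic:.10g}\t{self.p_value:.10g}\t{self.method}\n"
            )


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two_sided",
    continuity: bool = True,
) -> tuple[float, float, str]:
    """Mann-Whitney U rank-sum test of two independent samples.

    Returns ``(u, p, method)`` where ``u`` is the U statistic of ``x`` and
    ``method`` records the path taken: ``"exact"`` (complete enumeration,
    used when both groups have at most :data:`EXACT_MAX_N` values and there
    are no ties) or ``"normal_approx"`` (tie-corrected normal approximation,
    continuity-corrected by default).

    NA values must be excluded by the caller.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires non-empty samples")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("NA values must be excluded before rank_sum_test")
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")

    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size

    if np.ptp(combined) == 0:
        # Both groups identical in value: no evidence of any shift.
        return x.size * y.size / 2.0, 1.0, "normal_approx"

    if max(x.size, y.size) <= EXACT_MAX_N and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative=_ALTERNATIVES[alternative], method="exact")
        return float(res.statistic), float(res.pvalue), "exact"

    res = stats.mannwhitneyu(
        x,
        y,
        alternative=_ALTERNATIVES[alternative],
        method="asymptotic",
        use_continuity=continuity,
    )
    return float(res.statistic), min(float(res.pvalue), 1.0), "normal_approx"


def compare_ecotypes(
    dresults: Sequence[DResult],
    samples: SampleSet,
    alternative: str = "two_sided",
    continuity: bool = True,
) -> EcotypeComparison:
    """Compare per-specimen D between the marine and freshwater ecotypes.

    NA D values (no informative sites, or failed specimens) are dropped with
    a logged count.  Each group must retain at least two usable values.
    """
    groups: dict[str, list[float]] = {"marine": [], "freshwater": []}
    n_dropped = 0
    for r in dresults:
        eco = samples.ecotype_of(r.focal_id)
        if eco not in groups:
            continue
        if r.is_na:
            n_dropped += 1
            continue
        groups[eco].append(r.d)
    if n_dropped:
        logger.info("compare_ecotypes: dropped %d specimen(s) with NA D", n_dropped)
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(
                f"ecotype group '{name}' has {len(vals)} usable D value(s); need >= 2"
            )
    marine = np.array(groups["marine"])
    fresh = np.array(groups["freshwater"])
    u, p, method = rank_sum_test(marine, fresh, alternative=alternative, continuity=continuity)
    return EcotypeComparison(
        n_marine=marine.size,
        n_freshwater=fresh.size,
        mean_d_marine=float(marine.mean()),
        mean_d_freshwater=float(fresh.mean()),
        u_statistic=u,
        p_value=p,
        method=method,
    )
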