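"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately scalar/loop-based and shares no code with
the package's vectorized paths.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

from introscan.genotype_io import MISSING, GenotypeMatrix


def scalar_panel_freq(gm: GenotypeMatrix, site: int, sample_ids) -> float | None:
    total = 0
    n_called = 0
    for s in sample_ids:
        d = int(gm.dosages[site, gm.sample_ids.index(s)])
        if d != MISSING:
            total += d
            n_called += 1
    if n_called == 0:
        return None
    return total / (2.0 * n_called)


def scalar_d(gm: GenotypeMatrix, p1_ids, p2_ids, p3_ids, outgroup_ids=None):
    """Per-site scalar D: returns (d, sum_abba, sum_baba, n_sites_used).

    ``outgroup_ids=None`` means reference-allele polarization (p4 = 0).
    """
    sum_abba = 0.0
    sum_baba = 0.0
    n_used = 0
    for i in range(gm.n_sites):
        p1 = scalar_panel_freq(gm, i, p1_ids)
        p2 = scalar_panel_freq(gm, i, p2_ids)
        p3 = scalar_panel_freq(gm, i, p3_ids)
        if outgroup_ids is None:
            p4 = 0.0
        else:
            p4 = scalar_panel_freq(gm, i, outgroup_ids)
        if p1 is None or p2 is None or p3 is None or p4 is None:
            continue
        sum_abba += (1 - p1) * p2 * p3 * (1 - p4)
        sum_baba += p1 * (1 - p2) * p3 * (1 - p4)
        n_used += 1
    denom = sum_abba + sum_baba
    d = (sum_abba - sum_baba) / denom if denom > 0 else float("nan")
    return d, sum_abba, sum_baba, n_used


def _u_statistic(x, y) -> float:
    """Mann-Whitney U of x (count of (x_i, y_j) pairs with x_i > y_j; ties 0.5)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def enumerated_ranksum(x, y, alternative="two_sided"):
    """Exact rank-sum p by complete enumeration of label assignments.

    Valid for tie-free data.  Returns (u_observed, p).
    """
    x = list(x)
    y = list(y)
    n, m = len(x), len(y)
    pooled = x + y
    u_obs = _u_statistic(x, y)
    total = comb(n + m, n)
    n_le = 0
    n_ge = 0
    for idx in combinations(range(n + m), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n + m) if i not in set(idx)]
        u = _u_statistic(xs, ys)
        if u <= u_obs + 1e-12:
            n_le += 1
        if u >= u_obs - 1e-12:
            n_ge += 1
    if alternative == "greater":
        p = n_ge / total
    elif alternative == "less":
        p = n_le / total
    else:
        p = min(1.0, 2.0 * min(n_le, n_ge) / total)
    return u_obs, p


def scalar_informative_sites(gm: GenotypeMatrix, p1_ref: str, p3_ref: str) -> list[int]:
    i1 = gm.sample_ids.index(p1_ref)
    i3 = gm.sample_ids.index(p3_ref)
    out = []
    for i in range(gm.n_sites):
        if int(gm.dosages[i, i1]) == 0 and int(gm.dosages[i, i3]) == 2:
            out.append(i)
    return out
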