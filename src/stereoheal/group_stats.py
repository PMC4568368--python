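"""Group-level reporting and nonparametric inference.

The statistical unit is the animal: fields are pooled within animals upstream
and never enter tests directly. Comparisons use the Kruskal-Wallis omnibus
test across all groups and pairwise Mann-Whitney U tests, exact by full
enumeration of group assignments when the combined sample is small (the exact
path uses midranks and therefore handles ties), with the tie-corrected normal
approximation otherwise. No multiple-testing correction is applied by
default (each pairwise test at α = 0.05); a Holm adjustment is available.

Percent differences between group means are computed at full precision; the
printed-style formatter truncates (not rounds) to two decimals, which is the
convention that reproduces published two-decimal percentages from their
underlying one-decimal means.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import StereologyEstimates

__all__ = [
    "GroupSummary",
    "ComparisonReport",
    "percent_difference",
    "truncate_decimals",
    "mann_whitney",
    "mann_whitney_exact",
    "compare_groups",
    "table1_report",
]


@dataclass(frozen=True)
class GroupSummary:
    group: str
    quantity: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class ComparisonReport:
    quantity: str
    group_a: str
    group_b: str
    percent_difference: float
    test: str
    statistic: float
    p_value: float


def percent_difference(mean_a: float, mean_b: float) -> float:
    """``100 · (mean_a − mean_b) / mean_b`` — how much a exceeds baseline b."""
    if not mean_b > 0:
        raise ValueError(f"baseline mean must be positive, got {mean_b}")
    return 100.0 * (mean_a - mean_b) / mean_b


def truncate_decimals(x: float, decimals: int = 2) -> float:
    """Truncate toward zero at the given number of decimals."""
    factor = 10.0 ** decimals
    return math.trunc(x * factor) / factor


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for sample x via midranks (ties get half credit)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def mann_whitney_exact(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Exact Mann-Whitney U test by enumeration of all group assignments.

    Enumerates every way of choosing which pooled observations belong to the
    first sample (C(n1+n2, n1) assignments), computing U with midranks, so the
    null distribution is exact even under ties. Two-sided p doubles the
    smaller tail (capped at 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    if math.comb(n1 + n2, n1) > 5_000_000:
        raise ValueError("sample too large for exact enumeration")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    offset = n1 * (n1 + 1) / 2.0
    u_obs = float(ranks[:n1].sum() - offset)
    us = np.array([ranks[list(c)].sum() - offset
                   for c in itertools.combinations(range(n1 + n2), n1)])
    eps = 1e-9
    p_less = np.mean(us <= u_obs + eps)
    p_greater = np.mean(us >= u_obs - eps)
    if alternative == "less":
        p = p_less
    elif alternative == "greater":
        p = p_greater
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_less, p_greater))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return u_obs, float(p)


def mann_whitney(x, y, alternative: str = "two-sided",
                 exact_max_n: int = 12) -> tuple[float, float]:
    """Mann-Whitney U: exact enumeration when n1+n2 ≤ exact_max_n, otherwise
    the tie-corrected normal approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) + len(y) <= exact_max_n:
        return mann_whitney_exact(x, y, alternative)
    res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H and p; all-identical data give H = 0, p = 1."""
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def compare_groups(values_by_group: dict[str, list[float]],
                   quantity: str = "",
                   alternative: str = "two-sided",
                   exact_max_n: int = 12,
                   holm: bool = False) -> dict:
    """Omnibus and pairwise nonparametric comparison of ≥ 2 groups.

    Returns ``{"kruskal": (H, p), "pairwise": [ComparisonReport, ...]}``.
    Pairwise percent differences take the second group of each pair as the
    baseline. With ``holm=True`` the pairwise p-values are Holm-adjusted.
    """
    if len(values_by_group) < 2:
        raise ValueError("need at least two groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    for g, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has n < 2")
    h, p_omni = kruskal_wallis(list(arrays.values()))
    reports = []
    for ga, gb in itertools.combinations(arrays, 2):
        u, p = mann_whitney(arrays[ga], arrays[gb], alternative, exact_max_n)
        mean_b = float(arrays[gb].mean())
        # undefined (not an error) when the baseline group mean is not positive
        pct = (percent_difference(float(arrays[ga].mean()), mean_b)
               if mean_b > 0 else float("nan"))
        reports.append(ComparisonReport(
            quantity=quantity, group_a=ga, group_b=gb, percent_difference=pct,
            test="mann-whitney", statistic=u, p_value=p))
    if holm:
        order = np.argsort([r.p_value for r in reports])
        m = len(reports)
        adjusted = [None] * m
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * reports[idx].p_value)
            adjusted[idx] = min(1.0, running)
        reports = [ComparisonReport(r.quantity, r.group_a, r.group_b,
                                    r.percent_difference, r.test, r.statistic, adj)
                   for r, adj in zip(reports, adjusted)]
    return {"kruskal": (h, p_omni), "pairwise": reports}


_QUANTITIES = {
    "nv_fibroblast": ("Fibroblast Nv (x10^3/mm^3)", 1),
    "vv_collagen": ("Collagen Vv (%)", 1),
    "vv_hair": ("Hair Vv (%)", 1),
    "vv_vessel": ("Vessel Vv (%)", 1),
    "lv_vessel": ("Vessel Lv (mm/mm^3)", 1),
    "vessel_diameter_mean": ("Vessel diameter (um)", 1),
}


def table1_report(estimates: list[StereologyEstimates],
                  group_order: list[str] | None = None,
                  reference_groups: tuple[str, ...] = ("control", "gel base"),
                  alpha: float = 0.05) -> dict:
    """Summary grid of mean (SD) per group × quantity with significance stars.

    A cell is starred when its group differs from *every* reference group at
    the given level by pairwise Mann-Whitney. Returns ``raw`` (tidy means/SDs),
    ``formatted`` (strings at one-decimal precision), and ``comparisons``
    (tidy pairwise test results including percent differences).
    """
    if not estimates:
        raise ValueError("no estimates supplied")
    df = pd.DataFrame([vars(e) for e in estimates])
    if df["group"].isna().any():
        raise ValueError("every animal needs a group label")
    groups = group_order or list(dict.fromkeys(df["group"]))
    single_group = len(groups) < 2

    raw_rows, fmt_rows, comp_rows = [], [], []
    for qty, (label, nd) in _QUANTITIES.items():
        values_by_group = {
            g: df.loc[df["group"] == g, qty].dropna().to_numpy() for g in groups
        }
        values_by_group = {g: v for g, v in values_by_group.items() if len(v)}
        starred: dict[str, bool] = {g: False for g in groups}
        if not single_group and all(len(v) >= 2 for v in values_by_group.values()) \
                and len(values_by_group) >= 2:
            res = compare_groups({g: list(v) for g, v in values_by_group.items()},
                                 quantity=qty)
            h, p_omni = res["kruskal"]
            comp_rows.append({"quantity": qty, "group_a": "all", "group_b": "all",
                              "pct_diff": np.nan, "test": "kruskal-wallis",
                              "statistic": h, "p_value": p_omni})
            pair_p = {}
            for r in res["pairwise"]:
                comp_rows.append({"quantity": qty, "group_a": r.group_a,
                                  "group_b": r.group_b, "pct_diff": r.percent_difference,
                                  "test": r.test, "statistic": r.statistic,
                                  "p_value": r.p_value})
                pair_p[frozenset((r.group_a, r.group_b))] = r.p_value
            refs = [g for g in reference_groups if g in values_by_group]
            for g in groups:
                if g in refs or g not in values_by_group or not refs:
                    continue
                ps = [pair_p.get(frozenset((g, r)), 1.0) for r in refs]
                starred[g] = all(p < alpha for p in ps)
        fmt_row = {"quantity": label}
        for g in groups:
            v = values_by_group.get(g)
            if v is None or len(v) == 0:
                warnings.warn(f"no values for {qty} in group {g!r}; blank cell")
                fmt_row[g] = ""
                continue
            mean = float(np.mean(v))
            sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
            raw_rows.append({"quantity": qty, "group": g, "n": len(v),
                             "mean": mean, "sd": sd})
            star = "*" if starred.get(g) else ""
            fmt_row[g] = f"{mean:.{nd}f} ({sd:.{nd}f}){star}"
        fmt_rows.append(fmt_row)

    return {
        "raw": pd.DataFrame(raw_rows),
        "formatted": pd.DataFrame(fmt_rows).set_index("quantity"),
        "comparisons": pd.DataFrame(comp_rows),
    }
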