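"""Surface-expression (reporter kinetics) and adhesion-frequency quantification."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "PlateKinetics",
    "AdhesionSeries",
    "kinetic_slope",
    "surface_total_ratio",
    "adhesion_frequency",
    "compare_conditions",
    "significance_stars",
]


@dataclass
class PlateKinetics:
    """Timed absorbance readings for one well."""

    well_id: str
    construct: str
    compartment: str  # "surface" | "total"
    t_min: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.t_min.shape != self.absorbance.shape:
            raise ValueError("time and absorbance must have equal length")
        if len(self.t_min) < 3:
            raise ValueError("need at least 3 readings per well")
        if np.any(np.diff(self.t_min) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.compartment not in ("surface", "total"):
            raise ValueError(f"unknown compartment {self.compartment!r}")


@dataclass(frozen=True)
class AdhesionSeries:
    """Contact outcomes for one bead-cell pair."""

    pair_id: str
    condition: str
    n_contacts: int
    n_adhesions: int

    def __post_init__(self) -> None:
        if self.n_contacts < 1:
            raise ValueError("n_contacts must be >= 1")
        if not (0 <= self.n_adhesions <= self.n_contacts):
            raise ValueError("n_adhesions must lie in [0, n_contacts]")


def kinetic_slope(well: PlateKinetics) -> tuple[float, float]:
    """OLS slope (AU/min) and its standard error for one well."""
    res = stats.linregress(well.t_min, well.absorbance)
    return float(res.slope), float(res.stderr)


def surface_total_ratio(
    surface_slopes,
    total_slopes,
    wt_surface_slopes,
    wt_total_slopes,
) -> dict[str, float]:
    """Surface/total slope ratio and total expression, both as % of wild type.

    Uncertainty is propagated from replicate-well spread by the delta
    method (sum of squared relative SEMs).
    """
    s = np.asarray(surface_slopes, dtype=float)
    t = np.asarray(total_slopes, dtype=float)
    ws = np.asarray(wt_surface_slopes, dtype=float)
    wt = np.asarray(wt_total_slopes, dtype=float)
    for name, arr in (("total", t), ("wt_total", wt)):
        if np.mean(arr) <= 0:
            raise ValueError(f"mean {name} slope must be positive")
    if np.mean(ws) <= 0:
        raise ValueError("mean wt surface slope must be positive")

    def rel_sem(arr):
        if len(arr) < 2:
            return 0.0
        return float(np.std(arr, ddof=1) / math.sqrt(len(arr)) / abs(np.mean(arr)))

    ratio = (np.mean(s) / np.mean(t)) / (np.mean(ws) / np.mean(wt)) * 100.0
    total = np.mean(t) / np.mean(wt) * 100.0
    ratio_sem = ratio * math.sqrt(sum(rel_sem(a) ** 2 for a in (s, t, ws, wt)))
    total_sem = total * math.sqrt(rel_sem(t) ** 2 + rel_sem(wt) ** 2)
    return {
        "ratio_pct_wt": float(ratio),
        "ratio_sem": ratio_sem,
        "total_pct_wt": float(total),
        "total_sem": total_sem,
        "n_surface": len(s),
        "n_total": len(t),
    }


def adhesion_frequency(series: AdhesionSeries) -> dict[str, float]:
    """Adhesion frequency Pa with a Wilson 95% binomial interval."""
    pa = series.n_adhesions / series.n_contacts
    lo, hi = proportion_confint(series.n_adhesions, series.n_contacts, alpha=0.05, method="wilson")
    return {"pa": float(pa), "ci_low": float(lo), "ci_high": float(hi),
            "n_contacts": series.n_contacts}


def significance_stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_conditions(values_by_condition: dict[str, np.ndarray]) -> pd.DataFrame:
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    Returns one row per condition pair with the Tukey statistic,
    adjusted p, and the star tier used in the figure convention.
    """
    if len(values_by_condition) < 2:
        raise ValueError("need at least two conditions")
    names = sorted(values_by_condition)
    arrays = [np.asarray(values_by_condition[n], dtype=float) for n in names]
    for name, arr in zip(names, arrays):
        if len(arr) < 2:
            raise ValueError(f"condition {name!r} has fewer than 2 observations")
    f_stat, f_p = stats.f_oneway(*arrays)
    tukey = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p = float(tukey.pvalue[i, j])
            rows.append(
                {
                    "condition_a": names[i],
                    "condition_b": names[j],
                    "statistic": float(tukey.statistic[i, j]),
                    "p_adj": p,
                    "stars": significance_stars(p),
                    "significant": p < 0.05,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["anova_F"] = float(f_stat)
    out.attrs["anova_p"] = float(f_p)
    return out
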