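"""Voltage-clamp quantification: difference currents, Hill fits, potency stats.

Concentration-response data are fit in log10-concentration space with two
logistic forms:

* activation:  Response(%) = 100 / (1 + (EC50/[agonist])^nH)
* inhibition:  Response(%) = (100 - minimum) / (1 + ([conc]/IC50)^nH) + minimum,
  with ``minimum`` constrained to be positive.

Midpoints are optimized and reported as log10 molar, matching the
logEC50/logIC50 statistics used for group comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DoseResponseSeries",
    "HillFit",
    "PotencyRatio",
    "difference_current",
    "percent_max_effect",
    "normalize_percent_response",
    "hill_activation",
    "hill_inhibition",
    "fit_hill_activation",
    "fit_hill_inhibition",
    "fit_per_cell",
    "potency_ratio",
    "compare_log_potency",
    "summarize_constructs",
]

MULTISTART_SEED = 20230711


@dataclass
class DoseResponseSeries:
    """Pooled concentration-response observations for one construct/compound."""

    cell_ids: list[str]
    concentrations: np.ndarray  # molar, one per observation
    responses: np.ndarray  # percent of maximal response
    construct: str = ""
    compound: str = ""
    holding_mv: float = -40.0

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must have equal length")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")

    @property
    def n_cells(self) -> int:
        return len(set(self.cell_ids))


@dataclass
class HillFit:
    kind: str  # "activation" | "inhibition"
    log10_midpoint: float
    ci95: tuple[float, float]  # on log10 midpoint
    nH: float
    minimum: float | None
    n_cells: int
    rss: float
    midpoint_in_range: bool
    compound: str = ""
    construct: str = ""
    censored: str | None = None  # e.g. "> 10000 uM", excluded from ratios

    @property
    def midpoint(self) -> float:
        """Midpoint in molar."""
        return 10.0 ** self.log10_midpoint


@dataclass(frozen=True)
class PotencyRatio:
    reference: str
    variant: str
    ratio: float
    direction: str

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("potency ratio must be positive")


def difference_current(i_na: float, i_nmdg: float) -> float:
    """Constitutive Na⁺ influx magnitude: I_NMDG − I_Na.

    Positive for an inward (negative) resting Na⁺ current; a negative
    return value means the NMDG⁺ current was more negative than the Na⁺
    current (flagged by the caller as anomalous).
    """
    return i_nmdg - i_na


def percent_max_effect(i_baseline: float, i_drug: float, i_nmdg: float) -> float:
    """Drug effect as a percent of the full Na⁺→NMDG⁺ difference current.

    100% = complete block to the NMDG⁺ floor; negative = potentiation.
    """
    denom = i_baseline - i_nmdg
    if denom == 0:
        raise ValueError("baseline equals NMDG current; percent effect undefined")
    return 100.0 * (i_baseline - i_drug) / denom


def normalize_percent_response(currents, i_baseline: float, i_nmdg: float) -> np.ndarray:
    """Residual constitutive current as percent of the difference current."""
    denom = i_baseline - i_nmdg
    if denom == 0:
        raise ValueError("baseline equals NMDG current; normalization undefined")
    return 100.0 * (np.asarray(currents, dtype=float) - i_nmdg) / denom


def hill_activation(conc, log10_ec50: float, nh: float) -> np.ndarray:
    conc = np.asarray(conc, dtype=float)
    return 100.0 / (1.0 + 10.0 ** ((log10_ec50 - np.log10(conc)) * nh))


def hill_inhibition(conc, log10_ic50: float, nh: float, minimum: float) -> np.ndarray:
    conc = np.asarray(conc, dtype=float)
    return (100.0 - minimum) / (1.0 + 10.0 ** ((np.log10(conc) - log10_ic50) * nh)) + minimum


def _multistart_fit(model, logc, resp, p0_list, bounds):
    best = None
    for p0 in p0_list:
        try:
            popt, pcov = optimize.curve_fit(
                model, logc, resp, p0=p0, bounds=bounds, maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((model(logc, *popt) - resp) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        raise RuntimeError("Hill fit failed to converge from every start")
    return best


def _ci_from_cov(pcov, idx, value, dof):
    se = math.sqrt(max(pcov[idx, idx], 0.0))
    if not math.isfinite(se) or dof < 1:
        return (float("-inf"), float("inf"))
    tcrit = stats.t.ppf(0.975, dof)
    return (value - tcrit * se, value + tcrit * se)


def fit_hill_activation(series: DoseResponseSeries) -> HillFit:
    """Least-squares activation (EC50) fit on the log10-concentration axis.

    Three starts span the tested concentration range; the best
    residual-sum-of-squares solution wins.  The 95% CI comes from the
    curvature (covariance) approximation at the optimum.
    """
    conc = series.concentrations
    if len(np.unique(conc)) < 4:
        raise ValueError("activation fit needs >= 4 distinct concentrations")
    logc = np.log10(conc)

    def model(lc, log_ec50, nh):
        return 100.0 / (1.0 + 10.0 ** ((log_ec50 - lc) * nh))

    lo, hi = logc.min(), logc.max()
    starts = [(lo, 1.0), ((lo + hi) / 2, 1.0), (hi, 1.0)]
    bounds = ([lo - 6.0, 0.05], [hi + 6.0, 10.0])
    popt, pcov, rss = _multistart_fit(model, logc, series.responses, starts, bounds)
    dof = len(logc) - 2
    ci = _ci_from_cov(pcov, 0, popt[0], dof)
    return HillFit(
        kind="activation",
        log10_midpoint=float(popt[0]),
        ci95=ci,
        nH=float(popt[1]),
        minimum=None,
        n_cells=series.n_cells,
        rss=rss,
        midpoint_in_range=bool(lo <= popt[0] <= hi),
        compound=series.compound,
        construct=series.construct,
    )


def fit_hill_inhibition(series: DoseResponseSeries, min_floor: float = 1e-6) -> HillFit:
    """Inhibition (IC50) fit with a residual plateau constrained positive."""
    conc = series.concentrations
    if len(np.unique(conc)) < 5:
        raise ValueError("inhibition fit needs >= 5 distinct concentrations")
    logc = np.log10(conc)

    def model(lc, log_ic50, nh, minimum):
        return (100.0 - minimum) / (1.0 + 10.0 ** ((lc - log_ic50) * nh)) + minimum

    lo, hi = logc.min(), logc.max()
    starts = [(lo, 1.0, 5.0), ((lo + hi) / 2, 1.0, 5.0), (hi, 1.0, 5.0)]
    bounds = ([lo - 6.0, 0.05, min_floor], [hi + 6.0, 10.0, 100.0])
    popt, pcov, rss = _multistart_fit(model, logc, series.responses, starts, bounds)
    dof = len(logc) - 3
    ci = _ci_from_cov(pcov, 0, popt[0], dof)
    return HillFit(
        kind="inhibition",
        log10_midpoint=float(popt[0]),
        ci95=ci,
        nH=float(popt[1]),
        minimum=float(popt[2]),
        n_cells=series.n_cells,
        rss=rss,
        midpoint_in_range=bool(lo <= popt[0] <= hi),
        compound=series.compound,
        construct=series.construct,
    )


def fit_per_cell(series: DoseResponseSeries, kind: str = "activation") -> list[HillFit]:
    """Fit each cell separately; feeds per-cell log-midpoint statistics."""
    fits = []
    cells = sorted(set(series.cell_ids))
    ids = np.asarray(series.cell_ids)
    fitter = fit_hill_activation if kind == "activation" else fit_hill_inhibition
    for cell in cells:
        mask = ids == cell
        sub = DoseResponseSeries(
            cell_ids=[cell] * int(mask.sum()),
            concentrations=series.concentrations[mask],
            responses=series.responses[mask],
            construct=series.construct,
            compound=series.compound,
        )
        fits.append(fitter(sub))
    return fits


def potency_ratio(fit_ref: HillFit, fit_var: HillFit) -> PotencyRatio:
    """Fold shift midpoint(reference)/midpoint(variant).

    Censored midpoints (e.g. "> 10 mM") are excluded from ratio
    arithmetic and raise.
    """
    if fit_ref.compound != fit_var.compound:
        raise ValueError(
            f"compound mismatch: {fit_ref.compound!r} vs {fit_var.compound!r}"
        )
    if fit_ref.kind != fit_var.kind:
        raise ValueError(f"fit kind mismatch: {fit_ref.kind} vs {fit_var.kind}")
    if fit_ref.censored or fit_var.censored:
        raise ValueError("censored potency cannot enter ratio arithmetic")
    ratio = fit_ref.midpoint / fit_var.midpoint
    if ratio > 1:
        direction = "variant more potent"
    elif ratio < 1:
        direction = "variant less potent"
    else:
        direction = "equal"
    return PotencyRatio(
        reference=fit_ref.construct, variant=fit_var.construct, ratio=ratio,
        direction=direction,
    )


def compare_log_potency(
    groups: dict[str, np.ndarray],
    control: str,
    mode: str = "dunnett",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Many-to-one comparison of per-cell log midpoints against a control.

    ``mode="dunnett"``: one-way ANOVA then Dunnett's test.
    ``mode="welch-bonferroni"``: pairwise Welch t with Bonferroni p.
    """
    if control not in groups:
        raise ValueError(f"control group {control!r} absent")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {name: np.asarray(vals, dtype=float) for name, vals in groups.items()}
    for name, vals in arrays.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 cells")
    others = [name for name in arrays if name != control]

    f_stat, f_p = stats.f_oneway(*arrays.values())
    rows = []
    if mode == "dunnett":
        res = stats.dunnett(*[arrays[n] for n in others], control=arrays[control])
        for name, statv, p in zip(others, res.statistic, res.pvalue):
            rows.append(
                {"comparison": f"{name} vs {control}", "statistic": float(statv),
                 "p_adj": float(p), "significant": bool(p < alpha)}
            )
    elif mode == "welch-bonferroni":
        m = len(others)
        for name in others:
            t, p = stats.ttest_ind(arrays[name], arrays[control], equal_var=False)
            rows.append(
                {"comparison": f"{name} vs {control}", "statistic": float(t),
                 "p_adj": float(min(p * m, 1.0)), "significant": bool(min(p * m, 1.0) < alpha)}
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = pd.DataFrame(rows)
    out.attrs["anova_F"] = float(f_stat)
    out.attrs["anova_p"] = float(f_p)
    out.attrs["mode"] = mode
    return out


def summarize_constructs(values: pd.DataFrame, measure_col: str = "value") -> pd.DataFrame:
    """Per-construct mean ± SEM and n over per-cell measurements.

    Expects columns ``construct`` and ``measure_col``.  SEM is NaN for a
    single cell (flagged by ``sem_defined``).
    """
    if "construct" not in values.columns:
        raise ValueError("summary input needs a 'construct' column")
    rows = []
    for construct, sub in values.groupby("construct", sort=True):
        vals = sub[measure_col].to_numpy(dtype=float)
        if len(vals) == 0:
            continue
        mean = float(np.mean(vals))
        sem = float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else float("nan")
        rows.append(
            {"construct": construct, "mean": mean, "sem": sem, "n": len(vals),
             "sem_defined": len(vals) > 1}
        )
    return pd.DataFrame(rows, columns=["construct", "mean", "sem", "n", "sem_defined"])
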