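"""Four-parameter logistic dose-response fitting and IC50 reporting.

Fits R(c) = bottom + (top − bottom) / (1 + (c / IC50)^hill) to viability
plates by unweighted least squares, with the IC50 parameterized on the
log10 scale for stability on short (8-point) dilution designs.  The 95%
confidence interval on IC50 comes from the parameter covariance (t-based
on the residual degrees of freedom).  When no IC50 is identifiable within
the tested range — the fitted midpoint exceeds the highest concentration,
or the fit fails while viability stays above 50% — the result is flagged
right-censored and the IC50 is reported as "≥ max concentration".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthetic import four_pl

__all__ = [
    "FourPLFit",
    "SeriesError",
    "fivefold_series",
    "fit_4pl",
    "ic50_table",
    "normalize_responses",
]


class SeriesError(ValueError):
    """Dilution-series endpoints are not related by an integer power of 5."""


@dataclass
class FourPLFit:
    """Fitted 4PL parameter set for one plate."""

    top: float
    bottom: float
    hill: float
    ic50: float
    ic50_ci95: tuple[float, float]
    converged: bool
    censored: str  # "none" | "right"
    max_concentration: float
    cell_line: str = ""
    compound: str = ""

    @property
    def ic50_display(self) -> str:
        if self.censored == "right":
            return f">= {self.max_concentration:g}"
        return f"{self.ic50:g}"


def fivefold_series(start: float, end: float) -> list[float]:
    """Serial fivefold dilution series from ``start`` to ``end`` (µM).

    ``end`` must equal ``start * 5**k`` for an integer k >= 0 (relative
    tolerance 1e-9); e.g. (0.0032, 250) gives the standard 8-point design.
    """
    if start <= 0 or end < start:
        raise SeriesError("need 0 < start <= end")
    k = math.log(end / start) / math.log(5.0)
    k_int = round(k)
    if abs(end - start * 5.0**k_int) > 1e-9 * end:
        raise SeriesError(
            f"end={end} is not start*5^k for integer k (start={start})"
        )
    return [start * 5.0**i for i in range(k_int + 1)]


def normalize_responses(
    plate: pd.DataFrame, control_mean: float, column: str = "response_pct"
) -> pd.DataFrame:
    """Rescale raw absorbances so the untreated-control mean reads 100%."""
    if control_mean <= 0:
        raise ValueError("control_mean must be > 0")
    out = plate.copy()
    out[column] = 100.0 * out[column] / control_mean
    return out


def _initial_guess(conc: np.ndarray, resp: np.ndarray) -> tuple[float, float, float, float]:
    """top/bottom from extreme mean responses; IC50 near the midpoint response."""
    means = pd.Series(resp).groupby(pd.Series(conc)).mean()
    top = float(means.max())
    bottom = float(means.min())
    midpoint = 0.5 * (top + bottom)
    ic50_guess = float(means.index[np.argmin(np.abs(means.values - midpoint))])
    return top, bottom, 1.0, ic50_guess


def fit_4pl(plate: pd.DataFrame) -> FourPLFit:
    """Fit a four-parameter logistic curve to a viability plate.

    The plate must contain ``concentration_uM`` and ``response_pct``
    columns with at least 4 distinct positive concentrations.  Bounds:
    hill in [0.1, 10], IC50 in [min_conc/100, max_conc*100] (fitted as
    log10 IC50).
    """
    conc = np.asarray(plate["concentration_uM"], dtype=float)
    resp = np.asarray(plate["response_pct"], dtype=float)
    if not np.all(np.isfinite(resp)):
        raise ValueError("responses must be finite")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0")
    distinct = np.unique(conc)
    if len(distinct) < 4:
        raise ValueError(f"need >= 4 distinct concentrations, got {len(distinct)}")
    cmax = float(distinct.max())
    cmin = float(distinct.min())
    resp_at_max = float(resp[conc == cmax].mean())

    def model(c, top, bottom, hill, log_ic50):
        return four_pl(c, top, bottom, hill, 10.0**log_ic50)

    top0, bottom0, hill0, ic50_0 = _initial_guess(conc, resp)
    span = max(top0 - bottom0, 1.0)
    p0 = [top0, bottom0, hill0, math.log10(ic50_0)]
    bounds = (
        [bottom0 - 5 * span, bottom0 - 5 * span, 0.1, math.log10(cmin / 100.0)],
        [top0 + 5 * span, top0 + 5 * span, 10.0, math.log10(cmax * 100.0)],
    )

    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(
                model, conc, resp, p0=p0, bounds=bounds, maxfev=20000
            )
        perr = np.sqrt(np.diag(pcov))
        if not np.all(np.isfinite(perr)):
            converged = False
    except (RuntimeError, ValueError):
        converged = False
        popt = np.asarray(p0, dtype=float)
        perr = np.full(4, np.inf)

    top, bottom, hill, log_ic50 = (float(v) for v in popt)
    ic50 = 10.0**log_ic50
    dof = max(len(resp) - 4, 1)
    tcrit = float(stats.t.ppf(0.975, dof))
    if np.isfinite(perr[3]):
        ci = (10.0 ** (log_ic50 - tcrit * perr[3]), 10.0 ** (log_ic50 + tcrit * perr[3]))
    else:
        ci = (float("nan"), float("nan"))

    censored = "none"
    fitted_at_max = float(four_pl(cmax, top, bottom, hill, ic50))
    if (
        (converged and ic50 > cmax)
        or (converged and fitted_at_max > 50.0)
        or (not converged and resp_at_max > 50.0)
    ):
        # no half-maximal concentration identifiable within the tested range
        censored = "right"

    meta = {}
    for key in ("cell_line", "compound"):
        if key in plate.columns:
            meta[key] = str(plate[key].iloc[0])
    return FourPLFit(
        top=top,
        bottom=bottom,
        hill=hill,
        ic50=ic50,
        ic50_ci95=ci,
        converged=converged,
        censored=censored,
        max_concentration=cmax,
        **meta,
    )


def ic50_table(fits: dict[str, FourPLFit]) -> pd.DataFrame:
    """Summary table of IC50 fits, ascending by IC50 with censored fits last."""
    if not fits:
        raise ValueError("need at least one fit")
    rows = []
    for name, fit in fits.items():
        rows.append(
            {
                "cell_line": name,
                "compound": fit.compound,
                "top": fit.top,
                "bottom": fit.bottom,
                "hill": fit.hill,
                "ic50_uM": fit.ic50,
                "ic50_display": fit.ic50_display,
                "ci_lo": fit.ic50_ci95[0],
                "ci_hi": fit.ic50_ci95[1],
                "converged": fit.converged,
                "censored": fit.censored,
            }
        )
    table = pd.DataFrame(rows)
    table["_cens"] = (table["censored"] == "right").astype(int)
    table = table.sort_values(["_cens", "ic50_uM"], kind="mergesort").drop(columns="_cens")
    return table.reset_index(drop=True)
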