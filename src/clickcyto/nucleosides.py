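"""Nucleoside and nucleotide quantification from chromatography tables.

Converts integrated HPLC peak areas into relative molar amounts through
extinction coefficients (A = ε·c·l, so area/ε is proportional to molar
amount within a run — path length and injection volume cancel in ratios),
computes EdU:dT content ratios of enzymatically digested DNA, applies the
EdC detection-limit rule (about one EdC per thousand dT), and summarizes
nucleotide pools as percentage shares with phosphorylation-state ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PeakRecord",
    "DetectionFlag",
    "EPSILON_260",
    "EPSILON_EDU_289",
    "relative_molar_amount",
    "edu_dt_ratio",
    "edc_detection_flag",
    "pool_shares",
    "phosphorylation_ratio",
    "simplify_ratio",
]

# Standard 260-nm molar extinction coefficients (l·mol^-1·cm^-1) of the
# natural 2'-deoxynucleosides; overridable per record.
EPSILON_260 = {"dT": 8700.0, "dC": 7400.0, "dA": 15400.0, "dG": 11700.0}
# EdU is quantified at 289 nm where natural nucleosides barely absorb.
EPSILON_EDU_289 = 12000.0

# Dephosphorylation/deamination products of EdCTP tracked in pool runs.
EDCTP_METABOLITES = ["EdCDP", "EdCMP", "EdC", "EdU", "EdUMP"]


@dataclass
class PeakRecord:
    """One integrated chromatographic peak."""

    species: str
    area: float
    epsilon: float
    retention_min: float = float("nan")
    wavelength_nm: float = 260.0

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("peak area must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("extinction coefficient must be > 0")


@dataclass
class DetectionFlag:
    """Outcome of the EdC detection-limit test."""

    detected: bool
    ratio: float  # EdC:dT molar ratio
    limit: float  # detection threshold on the ratio
    bound: float | None  # upper bound on the EdC amount when not detected


def relative_molar_amount(peak: PeakRecord) -> float:
    """Relative molar amount of a species: peak area / extinction coefficient."""
    return peak.area / peak.epsilon


def _find_peak(peaks: list[PeakRecord], species: str) -> PeakRecord:
    for p in peaks:
        if p.species == species:
            return p
    raise KeyError(f"no {species} peak in the table")


def edu_dt_ratio(peaks: list[PeakRecord]) -> float:
    """Molar EdU:dT ratio of a digested-DNA peak table.

    EdU is read at 289 nm, dT at 260 nm; each is converted to a relative
    molar amount through its own extinction coefficient before the ratio
    is formed.
    """
    edu = _find_peak(peaks, "EdU")
    dt = _find_peak(peaks, "dT")
    dt_amount = relative_molar_amount(dt)
    if dt_amount == 0:
        raise ZeroDivisionError("dT amount is 0; ratio undefined")
    return relative_molar_amount(edu) / dt_amount


def edc_detection_flag(
    edc_amount: float, dt_amount: float, limit: float = 1e-3
) -> DetectionFlag:
    """Apply the EdC detection-limit rule against the dT amount.

    EdC counts as detected when its molar amount reaches ``limit`` times
    the dT amount (default: one EdC per thousand dT).  When not detected,
    the reported bound is the largest EdC amount still compatible with
    non-detection, ``limit * dt_amount``.
    """
    if dt_amount <= 0:
        raise ValueError("dt_amount must be > 0")
    ratio = edc_amount / dt_amount
    detected = ratio >= limit
    return DetectionFlag(
        detected=detected,
        ratio=ratio,
        limit=limit,
        bound=None if detected else limit * dt_amount,
    )


def pool_shares(pool: pd.DataFrame, monitored: list[str] | None = None) -> dict[str, float]:
    """Percentage share of each monitored species in a concentration pool.

    ``pool`` needs ``species`` and ``concentration`` columns (optionally
    ``detected``; non-detected species contribute 0).  Shares are
    normalized over the ``monitored`` list (default: every species in the
    table) and sum to 100.
    """
    table = pool.set_index("species")
    if monitored is None:
        monitored = list(table.index)
    missing = [s for s in monitored if s not in table.index]
    if missing:
        raise KeyError(f"monitored species absent from pool: {missing}")
    conc = table.loc[monitored, "concentration"].astype(float).copy()
    if "detected" in table.columns:
        conc[~table.loc[monitored, "detected"].astype(bool)] = 0.0
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    total = conc.sum()
    if total <= 0:
        raise ValueError("pool has no positive concentrations among monitored species")
    return {s: float(100.0 * c / total) for s, c in conc.items()}


def simplify_ratio(a: float, b: float, max_denominator: int = 20, tol: float = 0.02) -> str | None:
    """Small-integer form "p : q" of a/b, or None if no close pair exists.

    A pair is accepted when |p/q − a/b| / (a/b) < ``tol`` with q up to
    ``max_denominator`` (so 30:70 reports as "3 : 7").
    """
    if b <= 0 or a < 0:
        return None
    target = a / b
    for q in range(1, max_denominator + 1):
        p = round(target * q)
        if p == 0:
            continue
        g = math.gcd(p, q)
        p, q_r = p // g, q // g
        if abs(p / q_r - target) / target < tol:
            return f"{p} : {q_r}"
    return None


def phosphorylation_ratio(
    shares: dict[str, float],
    numerator: str,
    denominator: list[str],
) -> tuple[float, str | None]:
    """Share ratio of one species to the summed shares of a species group.

    Returns the quotient and, when both sides round to small integers,
    a simplified "p : q" string (e.g. EdCTP vs its dephosphorylated
    products, 30 vs 70 → "3 : 7").
    """
    if numerator not in shares:
        raise KeyError(f"numerator {numerator!r} not in shares")
    missing = [s for s in denominator if s not in shares]
    if missing:
        raise KeyError(f"denominator species not in shares: {missing}")
    denom = sum(shares[s] for s in denominator)
    if denom <= 0:
        raise ZeroDivisionError("denominator shares sum to 0")
    num = shares[numerator]
    return num / denom, simplify_ratio(num, denom)
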