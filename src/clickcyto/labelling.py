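"""The trimmed labelled-fraction statistic for click-labelling cytometry.

Given a per-nucleus intensity table, this module implements the sample
quantification used throughout the package:

1.  Estimate the labelled fraction F — the proportion of nuclei whose
    click signal places them in the labelled mode of the (typically
    bimodal) intensity histogram.
2.  Compute the trimmed specific signal: with a trim margin δ (default
    0.1), the mean signal of the (F−δ)·N brightest nuclei minus the mean
    of the (1−δ−F)·N dimmest.  Trimming excludes the ambiguous middle of
    the histogram, so the statistic is robust to the exact location of
    the labelled/unlabelled boundary, and the top-minus-bottom difference
    cancels any common additive background.
3.  Subtract the same statistic evaluated on an untreated control sample
    (background correction).
4.  Summarize condition pairs as per-experiment ratios with mean ± s.e.m.,
    and normalize condition panels to a reference condition (= 100%).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

__all__ = [
    "LabellingParams",
    "LabellingResult",
    "RatioResult",
    "MarginError",
    "estimate_labelled_fraction",
    "trimmed_specific_signal",
    "background_correct",
    "condition_ratio",
    "normalize_to_reference",
]


class MarginError(ValueError):
    """Labelled fraction outside the admissible [δ, 1−δ] trim window."""


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass
class LabellingParams:
    """Tuning knobs of the labelling statistic.

    ``trim_margin`` is the δ of the (F−δ)/(1−δ−F) trim (default 0.1);
    ``fraction_method`` selects how the labelled/unlabelled separation
    threshold is found on the signal histogram; ``out_of_range_policy``
    controls what happens when F falls outside [δ, 1−δ].
    """

    trim_margin: float = 0.1
    fraction_method: str = "otsu_log"  # otsu_log | gmm2 | valley
    out_of_range_policy: str = "error"  # error | clamp
    histogram_bins: int = 256

    def __post_init__(self) -> None:
        if not 0.0 < self.trim_margin < 0.5:
            raise ValueError("trim_margin must lie in (0, 0.5)")
        if self.histogram_bins < 16:
            raise ValueError("histogram_bins must be >= 16")
        if self.fraction_method not in ("otsu_log", "gmm2", "valley"):
            raise ValueError("unknown fraction_method")
        if self.out_of_range_policy not in ("error", "clamp"):
            raise ValueError("unknown out_of_range_policy")


@dataclass
class LabellingResult:
    """Trimmed-statistic summary of one sample."""

    F: float
    n_top: int
    n_bottom: int
    mean_top: float
    mean_bottom: float
    specific_signal: float
    corrected_signal: float | None = None
    sample_id: str = ""
    condition: str = ""
    n_nuclei: int = 0


@dataclass
class RatioResult:
    """Mean ± s.e.m. of per-experiment condition ratios."""

    mean_ratio: float
    sem: float
    n_experiments: int
    per_experiment_ratios: list = field(default_factory=list)


def _signal_vector(table: pd.DataFrame) -> np.ndarray:
    if len(table) == 0:
        raise ValueError("intensity table is empty")
    signal = np.asarray(table["signal_mean"], dtype=float)
    if np.any(signal < 0):
        raise ValueError("signal_mean must be >= 0")
    return signal


def _otsu_log_threshold(signal: np.ndarray, bins: int) -> float:
    """Otsu threshold on log10(signal+1), returned on the linear scale."""
    log_sig = np.log10(signal + 1.0)
    if np.ptp(log_sig) == 0:
        return float(signal[0])
    return 10.0 ** threshold_otsu(log_sig, nbins=bins) - 1.0


def _gmm2_threshold(signal: np.ndarray, bins: int) -> float:
    """Two-component Gaussian mixture on log10 signal; boundary between means.

    Falls back to the Otsu threshold (with a warning) when the mixture is
    degenerate — components collapsed onto each other or one component
    nearly empty.
    """
    from sklearn.mixture import GaussianMixture

    log_sig = np.log10(signal + 1.0).reshape(-1, 1)
    gm = GaussianMixture(n_components=2, random_state=0, n_init=3).fit(log_sig)
    means = np.sort(gm.means_.ravel())
    weights = gm.weights_
    # Ashman's D < 2: components too overlapped to mark genuine bimodality
    ashman_d = (means[1] - means[0]) / math.sqrt(float(gm.covariances_.sum()))
    if ashman_d < 2.0 or weights.min() < 0.02:
        warnings.warn(
            "degenerate 2-component mixture; falling back to otsu_log", stacklevel=3
        )
        return _otsu_log_threshold(signal, bins)
    # decision boundary: point between the two means where posteriors cross
    grid = np.linspace(means[0], means[1], 512).reshape(-1, 1)
    post = gm.predict_proba(grid)
    hi = int(np.argmax(gm.means_.ravel()))
    crossing = grid[np.argmin(np.abs(post[:, hi] - 0.5)), 0]
    return 10.0**crossing - 1.0


def _valley_threshold(signal: np.ndarray, bins: int) -> float:
    """Minimum of the smoothed log-signal histogram between the two modes."""
    log_sig = np.log10(signal + 1.0)
    hist, edges = np.histogram(log_sig, bins=bins)
    kernel = np.ones(5) / 5.0
    smooth = np.convolve(hist, kernel, mode="same")
    lo_mode = int(np.argmax(smooth[: bins // 2]))
    hi_mode = bins // 2 + int(np.argmax(smooth[bins // 2 :]))
    if hi_mode <= lo_mode + 1:
        return _otsu_log_threshold(signal, bins)
    valley = lo_mode + int(np.argmin(smooth[lo_mode : hi_mode + 1]))
    centre = 0.5 * (edges[valley] + edges[valley + 1])
    return 10.0**centre - 1.0


def estimate_labelled_fraction(
    table: pd.DataFrame, params: LabellingParams | None = None
) -> float:
    """Estimate the labelled fraction F from the nuclear-signal histogram.

    F is the proportion of nuclei whose mean signal exceeds the separation
    threshold between the unlabelled and labelled modes.
    """
    params = params or LabellingParams()
    signal = _signal_vector(table)
    if params.fraction_method == "otsu_log":
        thresh = _otsu_log_threshold(signal, params.histogram_bins)
    elif params.fraction_method == "gmm2":
        thresh = _gmm2_threshold(signal, params.histogram_bins)
    else:
        thresh = _valley_threshold(signal, params.histogram_bins)
    return float(np.mean(signal > thresh))


def trimmed_specific_signal(
    table: pd.DataFrame,
    F: float,
    params: LabellingParams | None = None,
) -> LabellingResult:
    """Compute the trimmed specific signal for a sample with labelled fraction F.

    Nuclei are sorted by descending signal (ties broken by nucleus_id);
    ``mean_top`` averages the first round((F−δ)·N) of them, ``mean_bottom``
    the last round((1−δ−F)·N), and the specific signal is their difference.
    """
    params = params or LabellingParams()
    delta = params.trim_margin
    signal = _signal_vector(table)
    n = len(signal)
    if n < 10:
        raise ValueError(f"need at least 10 nuclei, got {n}")

    clamped = False
    if not delta <= F <= 1.0 - delta:
        if params.out_of_range_policy == "error":
            raise MarginError(
                f"labelled fraction F={F:.4f} outside the admissible window "
                f"[{delta}, {1 - delta}] set by trim margin delta={delta}"
            )
        warnings.warn(
            f"F={F:.4f} clamped into [{delta}, {1 - delta}]", stacklevel=2
        )
        F = min(max(F, delta), 1.0 - delta)
        clamped = True

    n_top = _round_half_away((F - delta) * n)
    n_bottom = _round_half_away((1.0 - delta - F) * n)
    if clamped:
        # clamping onto a window edge must still leave both slices usable
        n_top = max(n_top, 1)
        n_bottom = max(n_bottom, 1)
    if n_top == 0 or n_bottom == 0:
        raise ValueError(
            f"empty trim slice (n_top={n_top}, n_bottom={n_bottom}); "
            f"F={F} too close to the margin for N={n}"
        )

    order = np.lexsort((np.asarray(table["nucleus_id"]), -signal))
    ranked = signal[order]
    mean_top = float(ranked[:n_top].mean())
    mean_bottom = float(ranked[n - n_bottom :].mean())
    return LabellingResult(
        F=F,
        n_top=n_top,
        n_bottom=n_bottom,
        mean_top=mean_top,
        mean_bottom=mean_bottom,
        specific_signal=mean_top - mean_bottom,
        sample_id=str(table["sample_id"].iloc[0]) if "sample_id" in table else "",
        condition=str(table["condition"].iloc[0]) if "condition" in table else "",
        n_nuclei=n,
    )


def background_correct(
    treated: LabellingResult,
    control_table: pd.DataFrame,
    F_treated: float | None = None,
    params: LabellingParams | None = None,
    control_statistic: str = "trimmed",
) -> LabellingResult:
    """Subtract the untreated-control signal from a treated sample's statistic.

    By default the identical trimmed statistic is evaluated on the control
    table using the treated sample's F, keeping the estimator form constant
    across samples; ``control_statistic="mean"`` subtracts the plain control
    mean instead.
    """
    if F_treated is None:
        F_treated = treated.F
    if control_statistic == "trimmed":
        control = trimmed_specific_signal(control_table, F_treated, params)
        control_value = control.specific_signal
    elif control_statistic == "mean":
        control_value = float(_signal_vector(control_table).mean())
    else:
        raise ValueError("control_statistic must be 'trimmed' or 'mean'")
    corrected = treated.specific_signal - control_value
    return LabellingResult(
        F=treated.F,
        n_top=treated.n_top,
        n_bottom=treated.n_bottom,
        mean_top=treated.mean_top,
        mean_bottom=treated.mean_bottom,
        specific_signal=treated.specific_signal,
        corrected_signal=corrected,
        sample_id=treated.sample_id,
        condition=treated.condition,
        n_nuclei=treated.n_nuclei,
    )


def condition_ratio(pairs: list[tuple[float, float]]) -> RatioResult:
    """Mean ± s.e.m. of per-experiment ratios a/b across experiments.

    The s.e.m. uses the sample standard deviation over experiments; a
    single experiment reports s.e.m. = 0.
    """
    if len(pairs) < 1:
        raise ValueError("need at least one experiment")
    ratios = []
    for i, (a, b) in enumerate(pairs, start=1):
        if b == 0:
            raise ZeroDivisionError(f"experiment {i}: denominator signal is 0")
        ratios.append(a / b)
    ratios_arr = np.asarray(ratios, dtype=float)
    n = len(ratios_arr)
    sem = float(ratios_arr.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return RatioResult(
        mean_ratio=float(ratios_arr.mean()),
        sem=sem,
        n_experiments=n,
        per_experiment_ratios=ratios,
    )


def normalize_to_reference(values: dict, reference) -> dict:
    """Express each condition's signal as % of a reference condition (=100%)."""
    if reference not in values:
        raise KeyError(f"reference condition {reference!r} not in values")
    ref = values[reference]
    if ref == 0:
        raise ZeroDivisionError("reference condition has zero signal")
    out = {k: 100.0 * v / ref for k, v in values.items()}
    out[reference] = 100.0
    return out
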