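"""Seeded synthetic-data generators with known ground truth.

Every downstream stage of the pipeline (segmentation, labelled-fraction
estimation, dose-response fitting, pool-share arithmetic) can be exercised
against inputs whose generating parameters are known exactly:

* two-channel nucleus images (DAPI + click-signal) with a ground-truth
  label map,
* per-nucleus intensity tables with a hidden labelled/unlabelled flag,
* MTT-style viability plates drawn from a four-parameter logistic curve,
* nucleoside/nucleotide pool tables with prescribed percentage shares.

All generators are deterministic for a given configuration and seed.  Each
operation derives its own independent random sub-stream from the top-level
seed, so adding one output never shifts the draws of another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "SceneConfig",
    "SyntheticScene",
    "PlateConfig",
    "CapacityError",
    "generate_intensity_table",
    "generate_image_pair",
    "generate_viability_plate",
    "generate_pool_table",
    "write_image_pair",
]

# Fixed per-operation stream tags: rng(seed, tag) is independent across tags.
_STREAM_TABLE = 1
_STREAM_IMAGE = 2
_STREAM_PLATE = 3
_STREAM_POOL = 4


class CapacityError(RuntimeError):
    """Raised when the requested nuclei cannot be placed without overlap."""

    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"could only place {achieved} of {requested} non-overlapping "
            f"nuclei; enlarge the image or reduce n_nuclei/radii"
        )


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Independent per-operation stream derived from one top-level seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def _round_half_away(x: float) -> int:
    """round() with half-away-from-zero ties (Excel-style), for counts."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass
class SceneConfig:
    """Parameters of one synthetic sample (image pair or intensity table).

    The intensity model is a two-component mixture over nuclei: a fraction
    ``labelled_fraction`` of nuclei carry a right-skewed (lognormal) click
    signal with median ``labelled_signal_median`` and log-scale spread
    ``labelled_signal_sigma_log``; the remainder sit at
    ``unlabelled_signal_mean`` plus Gaussian measurement noise.  A common
    additive background is applied to both populations.  Defaults describe a
    well-labelled sample of 10,000 nuclei, the per-sample count used in the
    image-cytometry protocol this package implements.
    """

    image_width: int = 1024
    image_height: int = 1024
    n_nuclei: int = 10_000
    labelled_fraction: float = 0.75
    nucleus_radius_min: float = 8.0
    nucleus_radius_max: float = 12.0
    dapi_mean: float = 8000.0
    labelled_signal_median: float = 2000.0
    labelled_signal_sigma_log: float = 0.5
    unlabelled_signal_mean: float = 50.0
    background_mean: float = 0.0
    noise_sd: float = 10.0
    seed: int = 0
    exact_count: bool = True  # exact-count labelled assignment (vs Bernoulli)
    sample_id: str = "synthetic"
    condition: str = "treated"
    replicate: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.labelled_fraction <= 1.0:
            raise ValueError("labelled_fraction must lie in [0, 1]")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if self.nucleus_radius_min > self.nucleus_radius_max:
            raise ValueError("nucleus_radius_min must be <= nucleus_radius_max")
        for name in (
            "dapi_mean",
            "labelled_signal_median",
            "unlabelled_signal_mean",
            "background_mean",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SyntheticScene:
    """Ground truth for a generated image pair."""

    centroids: np.ndarray  # (n, 2) array of (x, y) pixel coordinates
    radii: np.ndarray  # (n,)
    is_labelled: np.ndarray  # (n,) bool
    true_signal_mean: np.ndarray  # (n,) intensity units
    label_image: np.ndarray  # int32, 0 = background, k = nucleus k

    @property
    def n_nuclei(self) -> int:
        return len(self.radii)


@dataclass
class PlateConfig:
    """Generating parameters for a synthetic viability plate.

    ``top``/``bottom`` are asymptotic viabilities (% of untreated control),
    ``hill`` the slope, ``ic50`` the midpoint concentration in µM.
    Defaults reproduce an 8-point fivefold dilution series (0.0032–250 µM)
    read in quadruplicate with 5% absorbance noise.
    """

    top: float = 100.0
    bottom: float = 0.0
    hill: float = 1.0
    ic50: float = 0.8
    concentrations: tuple = (0.0032, 0.016, 0.08, 0.4, 2.0, 10.0, 50.0, 250.0)
    replicates: int = 4
    noise_sd: float = 5.0
    seed: int = 0
    cell_line: str = "synthetic"
    compound: str = "EdC"

    def __post_init__(self) -> None:
        if self.top <= self.bottom:
            raise ValueError("top must exceed bottom")
        if self.ic50 <= 0:
            raise ValueError("ic50 must be > 0")
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.size == 0 or np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be positive and strictly increasing")


def _draw_labels(rng: np.random.Generator, n: int, fraction: float, exact: bool) -> np.ndarray:
    """Hidden labelled/unlabelled assignment (exact-count by default)."""
    if exact:
        n_lab = _round_half_away(fraction * n)
        flags = np.zeros(n, dtype=bool)
        flags[rng.permutation(n)[:n_lab]] = True
        return flags
    return rng.random(n) < fraction


def _draw_signals(rng: np.random.Generator, cfg: SceneConfig, labelled: np.ndarray) -> np.ndarray:
    """Per-nucleus true mean click signal for the mixture model.

    Labelled nuclei: lognormal with median m and shape sigma, i.e.
    exp(N(ln m, sigma)); unlabelled nuclei: constant mean plus Gaussian
    noise.  Both get the common additive background; negatives clip to 0.
    """
    n = len(labelled)
    signal = np.empty(n, dtype=float)
    n_lab = int(labelled.sum())
    if cfg.labelled_signal_sigma_log > 0:
        lab = rng.lognormal(
            mean=math.log(cfg.labelled_signal_median) if cfg.labelled_signal_median > 0 else -np.inf,
            sigma=cfg.labelled_signal_sigma_log,
            size=n_lab,
        )
    else:
        lab = np.full(n_lab, cfg.labelled_signal_median)
    signal[labelled] = lab
    unl = np.full(n - n_lab, cfg.unlabelled_signal_mean)
    if cfg.noise_sd > 0:
        unl = unl + rng.normal(0.0, cfg.noise_sd, size=n - n_lab)
    signal[~labelled] = unl
    return np.clip(signal + cfg.background_mean, 0.0, None)


def generate_intensity_table(config: SceneConfig) -> pd.DataFrame:
    """Generate a per-nucleus intensity table directly (skipping imaging).

    Returns a DataFrame with the standard intensity-table schema
    (``sample_id, condition, replicate, nucleus_id, x, y, area_px,
    dapi_mean, signal_mean``) plus a ``truth_labelled`` ground-truth column.
    Exactly ``round(labelled_fraction * n_nuclei)`` rows are labelled when
    ``exact_count`` is on.
    """
    if config.n_nuclei == 0:
        raise ValueError("n_nuclei must be >= 1 to generate an intensity table")
    rng = _rng(config.seed, _STREAM_TABLE)
    n = config.n_nuclei
    labelled = _draw_labels(rng, n, config.labelled_fraction, config.exact_count)
    signal = _draw_signals(rng, config, labelled)

    radii = rng.uniform(config.nucleus_radius_min, config.nucleus_radius_max, size=n)
    dapi = config.dapi_mean + (
        rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else 0.0
    )
    return pd.DataFrame(
        {
            "sample_id": config.sample_id,
            "condition": config.condition,
            "replicate": config.replicate,
            "nucleus_id": np.arange(1, n + 1),
            "x": rng.uniform(0, config.image_width, size=n),
            "y": rng.uniform(0, config.image_height, size=n),
            "area_px": np.round(np.pi * radii**2).astype(int),
            "dapi_mean": np.clip(dapi, 0.0, None),
            "signal_mean": signal,
            "truth_labelled": labelled,
        }
    )


def _place_disks(
    rng: np.random.Generator,
    cfg: SceneConfig,
    max_tries_per_nucleus: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping disk centres (gap >= 2 px)."""
    centroids = np.empty((cfg.n_nuclei, 2), dtype=float)
    radii = rng.uniform(cfg.nucleus_radius_min, cfg.nucleus_radius_max, size=cfg.n_nuclei)
    placed = 0
    budget = max_tries_per_nucleus * max(cfg.n_nuclei, 1)
    while placed < cfg.n_nuclei and budget > 0:
        budget -= 1
        r = radii[placed]
        x = rng.uniform(r, cfg.image_width - r)
        y = rng.uniform(r, cfg.image_height - r)
        if placed:
            d = np.hypot(centroids[:placed, 0] - x, centroids[:placed, 1] - y)
            if np.any(d <= radii[:placed] + r + 2.0):
                continue
        centroids[placed] = (x, y)
        placed += 1
    if placed < cfg.n_nuclei:
        raise CapacityError(cfg.n_nuclei, placed)
    return centroids, radii


def generate_image_pair(
    config: SceneConfig,
) -> tuple[np.ndarray, np.ndarray, SyntheticScene]:
    """Render a (DAPI, click-signal) image pair plus its ground truth.

    Nuclei are non-overlapping disks.  The DAPI channel carries
    ``dapi_mean`` inside every disk; the signal channel carries each
    nucleus's true mean signal from the mixture model.  Pixel noise is
    additive Gaussian with sd ``noise_sd``.  Images are float arrays
    clipped to the 16-bit range [0, 65535]; use :func:`write_image_pair`
    to quantize to TIFF.
    """
    shape = (config.image_height, config.image_width)
    rng = _rng(config.seed, _STREAM_IMAGE)
    if config.n_nuclei == 0:
        blank = np.zeros(shape, dtype=float)
        scene = SyntheticScene(
            centroids=np.empty((0, 2)),
            radii=np.empty(0),
            is_labelled=np.empty(0, dtype=bool),
            true_signal_mean=np.empty(0),
            label_image=np.zeros(shape, dtype=np.int32),
        )
        return blank + config.background_mean, blank + config.background_mean, scene

    centroids, radii = _place_disks(rng, config)
    labelled = _draw_labels(rng, config.n_nuclei, config.labelled_fraction, config.exact_count)
    true_signal = _draw_signals(rng, config, labelled)

    label_image = np.zeros(shape, dtype=np.int32)
    dapi = np.full(shape, float(config.background_mean))
    signal = np.full(shape, float(config.background_mean))
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for k in range(config.n_nuclei):
        x, y = centroids[k]
        r = radii[k]
        # rasterize only the bounding box of the disk
        y0, y1 = int(max(0, y - r - 1)), int(min(shape[0], y + r + 2))
        x0, x1 = int(max(0, x - r - 1)), int(min(shape[1], x + r + 2))
        mask = (yy[y0:y1, x0:x1] - y) ** 2 + (xx[y0:y1, x0:x1] - x) ** 2 <= r**2
        label_image[y0:y1, x0:x1][mask] = k + 1
        dapi[y0:y1, x0:x1][mask] = config.dapi_mean
        signal[y0:y1, x0:x1][mask] = true_signal[k]

    if config.noise_sd > 0:
        dapi = dapi + rng.normal(0.0, config.noise_sd, size=shape)
        signal = signal + rng.normal(0.0, config.noise_sd, size=shape)
    dapi = np.clip(dapi, 0.0, 65535.0)
    signal = np.clip(signal, 0.0, 65535.0)

    scene = SyntheticScene(
        centroids=centroids,
        radii=radii,
        is_labelled=labelled,
        true_signal_mean=true_signal,
        label_image=label_image,
    )
    return dapi, signal, scene


def write_image_pair(dapi: np.ndarray, signal: np.ndarray, sample: str, out_dir) -> tuple[str, str]:
    """Write `<sample>_dapi.tif` / `<sample>_signal.tif` as 16-bit TIFFs."""
    import os

    paths = []
    for channel, img in (("dapi", dapi), ("signal", signal)):
        path = os.path.join(str(out_dir), f"{sample}_{channel}.tif")
        tifffile.imwrite(path, np.round(np.clip(img, 0, 65535)).astype(np.uint16))
        paths.append(path)
    return tuple(paths)


def four_pl(conc, top: float, bottom: float, hill: float, ic50: float):
    """Four-parameter logistic: R(c) = bottom + (top-bottom)/(1+(c/ic50)^hill)."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (conc / ic50) ** hill)


def generate_viability_plate(config: PlateConfig) -> pd.DataFrame:
    """Simulate an MTT-style plate from a 4PL curve.

    One row per (concentration, replicate) with a viability response (% of
    untreated control) drawn as 4PL(c) + N(0, noise_sd).
    """
    rng = _rng(config.seed, _STREAM_PLATE)
    conc = np.asarray(config.concentrations, dtype=float)
    rows = []
    for c in conc:
        expected = float(four_pl(c, config.top, config.bottom, config.hill, config.ic50))
        for rep in range(1, config.replicates + 1):
            resp = expected + (rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0)
            rows.append((config.cell_line, config.compound, c, rep, resp))
    return pd.DataFrame(
        rows, columns=["cell_line", "compound", "concentration_uM", "replicate", "response_pct"]
    )


def generate_pool_table(
    shares: dict,
    total: float = 100.0,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a species-concentration pool table from percentage shares.

    Concentrations are proportional to ``shares`` scaled so they sum to
    ``total``, with multiplicative lognormal noise of coefficient of
    variation ``noise_cv`` (mean preserved).  Zero-share species come out
    as non-detected.
    """
    if not shares or all(v == 0 for v in shares.values()):
        raise ValueError("shares must contain at least one positive entry")
    if any(v < 0 for v in shares.values()):
        raise ValueError("shares must be >= 0")
    rng = _rng(seed, _STREAM_POOL)
    species = list(shares)
    weights = np.array([shares[s] for s in species], dtype=float)
    conc = total * weights / weights.sum()
    if noise_cv > 0:
        sigma = math.sqrt(math.log1p(noise_cv**2))
        conc = conc * rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=len(conc))
    return pd.DataFrame(
        {"species": species, "concentration": conc, "detected": conc > 0}
    )
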