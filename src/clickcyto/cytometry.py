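"""Nucleus segmentation and per-nucleus intensity measurement.

Segments nuclei from the DAPI channel (Otsu or fixed threshold, optional
distance-transform watershed for touching nuclei, area and border filters)
and measures the mean DAPI and click-signal intensity over each nuclear
mask, producing the per-nucleus intensity table consumed by the labelling
statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops_table
from skimage.segmentation import clear_border, watershed

__all__ = [
    "SegmentationParams",
    "segment_nuclei",
    "measure_nuclei",
    "intensity_table_from_images",
    "read_intensity_table",
    "write_intensity_table",
]

INTENSITY_COLUMNS = [
    "sample_id",
    "condition",
    "replicate",
    "nucleus_id",
    "x",
    "y",
    "area_px",
    "dapi_mean",
    "signal_mean",
]


@dataclass
class SegmentationParams:
    """Settings for DAPI-based nucleus segmentation.

    ``threshold_method`` is either ``"otsu"`` (256-bin histogram of the raw
    DAPI image) or ``"fixed"`` (use ``fixed_threshold``).  Objects outside
    [``min_area``, ``max_area``] pixels are dropped; ``exclude_border``
    removes objects touching the image edge; ``split_touching`` applies a
    distance-transform watershed seeded at local maxima separated by at
    least ``min_peak_separation`` pixels.
    """

    threshold_method: str = "otsu"
    fixed_threshold: float = 0.0
    min_area: int = 50
    max_area: int = 5000
    exclude_border: bool = False
    split_touching: bool = False
    min_peak_separation: int = 8

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.min_area >= self.max_area:
            raise ValueError("min_area must be < max_area")
        if self.fixed_threshold < 0:
            raise ValueError("fixed_threshold must be >= 0")


def segment_nuclei(dapi_image: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Segment nuclei from a DAPI image into an integer label map.

    Returns an int32 array of the same shape with background 0 and nuclei
    numbered 1..k.  A constant (flat) image yields zero objects with a
    warning rather than an error.
    """
    params = params or SegmentationParams()
    img = np.asarray(dapi_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("dapi_image must be 2-D")
    if np.any(img < 0):
        raise ValueError("dapi_image must be nonnegative")

    if params.threshold_method == "otsu":
        if np.ptp(img) == 0:
            warnings.warn("flat DAPI image: no nuclei found", stacklevel=2)
            return np.zeros(img.shape, dtype=np.int32)
        thresh = threshold_otsu(img, nbins=256)
    else:
        thresh = params.fixed_threshold
    binary = img > thresh
    if not binary.any():
        warnings.warn("no pixels above threshold: no nuclei found", stacklevel=2)
        return np.zeros(img.shape, dtype=np.int32)

    if params.split_touching:
        distance = ndi.distance_transform_edt(binary)
        peaks = peak_local_max(
            distance,
            min_distance=params.min_peak_separation,
            labels=sk_label(binary),
            exclude_border=False,
        )
        markers = np.zeros(img.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = watershed(-distance, markers, mask=binary)
    else:
        labels = sk_label(binary)

    if params.exclude_border:
        labels = clear_border(labels)

    # area filter, then relabel compactly 1..k
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[(counts >= params.min_area) & (counts <= params.max_area)]
    lut = np.zeros(labels.max() + 1, dtype=np.int32)
    lut[keep] = np.arange(1, len(keep) + 1)
    return lut[labels]


def measure_nuclei(
    label_map: np.ndarray,
    signal_image: np.ndarray,
    dapi_image: np.ndarray,
    metadata: dict | None = None,
) -> pd.DataFrame:
    """Measure per-nucleus mean intensities over each label mask.

    One row per label with centroid (x = column, y = row, 0-based),
    pixel area and the arithmetic mean of the signal and DAPI pixels
    under the mask.
    """
    label_map = np.asarray(label_map)
    if label_map.shape != np.shape(signal_image) or label_map.shape != np.shape(dapi_image):
        raise ValueError("label_map, signal_image and dapi_image must share shape")
    metadata = metadata or {}

    if label_map.max() == 0:
        table = pd.DataFrame(columns=INTENSITY_COLUMNS)
    else:
        props = regionprops_table(
            label_map,
            intensity_image=np.stack(
                [np.asarray(signal_image, float), np.asarray(dapi_image, float)], axis=-1
            ),
            properties=("label", "centroid", "area", "intensity_mean"),
        )
        table = pd.DataFrame(
            {
                "nucleus_id": props["label"],
                "x": props["centroid-1"],
                "y": props["centroid-0"],
                "area_px": props["area"].astype(int),
                "signal_mean": props["intensity_mean-0"],
                "dapi_mean": props["intensity_mean-1"],
            }
        )
    table.insert(0, "sample_id", metadata.get("sample_id", ""))
    table.insert(1, "condition", metadata.get("condition", ""))
    table.insert(2, "replicate", metadata.get("replicate", 1))
    table.attrs["n_nuclei"] = len(table)
    table.attrs.update(metadata)
    return table[INTENSITY_COLUMNS]


def intensity_table_from_images(
    dapi_image: np.ndarray,
    signal_image: np.ndarray,
    params: SegmentationParams | None = None,
    metadata: dict | None = None,
) -> pd.DataFrame:
    """Convenience pipeline: segment the DAPI channel, then measure."""
    labels = segment_nuclei(dapi_image, params)
    return measure_nuclei(labels, signal_image, dapi_image, metadata)


def write_intensity_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.6g")


def read_intensity_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in INTENSITY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"intensity table missing columns: {missing}")
    return table
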