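"""Astrocyte co-label classification from the second imaging channel.

Astrocytes are identified by a static red-dye channel (sulforhodamine-B
style staining): the channel is thresholded into a foreground mask and an
ROI counts as co-labeled when at least ``min_overlap`` of its pixels fall
inside the mask.  Combining the co-label flags with the recruitment calls
gives per-ring astrocyte recruitment and co-label fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu


@dataclass
class ColabelResult:
    """Per-slice co-label summary.

    ``fraction_colabeled_of_reference`` is the co-labeled fraction of all
    ROIs (the reference cell population); ``fraction_colabeled_of_recruited``
    restricts to recruited ROIs.  ``srb_cells_per_ring`` counts recruited
    AND co-labeled cells per 50-um ring, so each entry is bounded by the
    recruited count in that ring.
    """

    overlap_fraction: dict[int, float] = field(default_factory=dict)
    colabeled: dict[int, bool] = field(default_factory=dict)
    fraction_colabeled_of_reference: float = float("nan")
    fraction_colabeled_of_recruited: float = float("nan")
    srb_cells_per_ring: list[int] = field(default_factory=list)
    srb_mean_amplitude: float = float("nan")


def colabel_mask(channel2: np.ndarray, method: str = "otsu") -> np.ndarray:
    """Foreground mask of the co-label channel.

    Default is Otsu's global threshold, which is invariant to rescaling the
    intensities by any positive constant.  A constant image has no
    foreground: an empty mask is returned with a warning.
    """
    img = np.asarray(channel2, dtype=float)
    if img.min() == img.max():
        warnings.warn("constant co-label channel: empty mask", stacklevel=2)
        return np.zeros(img.shape, dtype=bool)
    if method != "otsu":
        raise ValueError(f"unknown thresholding method {method!r}")
    return img > threshold_otsu(img)


def overlap_fraction(roi_mask: np.ndarray, mask: np.ndarray) -> float:
    """|roi AND mask| / |roi|; raises on an empty ROI."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    n = int(roi_mask.sum())
    if n == 0:
        raise ValueError("empty ROI has no overlap fraction")
    return float(np.logical_and(roi_mask, mask).sum()) / n


def classify_colabel(roi_mask: np.ndarray, mask: np.ndarray,
                     min_overlap: float = 0.5) -> bool:
    """Co-labeled iff the ROI's overlap fraction reaches ``min_overlap``."""
    return overlap_fraction(roi_mask, mask) >= min_overlap


def astrocyte_recruitment(calls: pd.DataFrame) -> ColabelResult:
    """Per-ring co-labeled recruitment from an annotated calls table.

    ``calls`` must carry columns ``roi_id, recruited, ring_index,
    peak_amplitude, colabeled, overlap_fraction``.  Returns counts of
    recruited-and-co-labeled cells per ring, the mean peak amplitude over
    that subset, and the slice-level co-label fractions.
    """
    res = ColabelResult()
    res.overlap_fraction = dict(zip(calls["roi_id"], calls["overlap_fraction"]))
    res.colabeled = dict(zip(calls["roi_id"], calls["colabeled"].astype(bool)))
    n_ref = len(calls)
    if n_ref:
        res.fraction_colabeled_of_reference = float(calls["colabeled"].mean())
    rec = calls[calls["recruited"].astype(bool)]
    if len(rec):
        res.fraction_colabeled_of_recruited = float(rec["colabeled"].mean())
        n_rings = int(rec["ring_index"].max()) + 1
        counts = [0] * n_rings
        srb = rec[rec["colabeled"].astype(bool)]
        for k, c in srb.groupby("ring_index").size().items():
            counts[int(k)] = int(c)
        res.srb_cells_per_ring = counts
        if len(srb):
            res.srb_mean_amplitude = float(srb["peak_amplitude"].mean())
    return res
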