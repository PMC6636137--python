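"""Image-based particle counting and its calibration.

A sheet photo is binarized at an intensity cutoff (THRESHOLD, 1..100,
mapped linearly onto 0..255; specimens are dark on a light background) and
the number of 8-connected foreground components with area >= SIZE pixels is
the specimen-count estimate.  Touching specimens merge into one component —
the method does not declump, and the calibration absorbs that bias.

Calibration exhaustively scans all 100 x 100 (THRESHOLD, SIZE) pairs over
an image set with known true counts, computing the mean and SD of the
consistency score (estimate/truth x 100) per pair; the best pair has mean
consistency inside the window [97.5, 102.5] with minimal SD (ties: smaller
|mean - 100|, then smaller threshold, then smaller size).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label as _label

from .bootstrap import StatResult, pearson_r
from .render import SheetImage

__all__ = [
    "CountingParams",
    "CalibrationGrid",
    "binarize",
    "count_particles",
    "estimate_count",
    "calibrate",
    "replicate_consistency",
]

PARAM_RANGE = range(1, 101)


@dataclass(frozen=True)
class CountingParams:
    """THRESHOLD (intensity cutoff rank) and SIZE (min component area, px)."""

    threshold: int
    min_size: int

    def __post_init__(self):
        if not 1 <= self.threshold <= 100:
            raise ValueError("threshold must be in 1..100")
        if not 1 <= self.min_size <= 100:
            raise ValueError("min_size must be in 1..100")


def _as_gray(image) -> np.ndarray:
    arr = image.pixels if isinstance(image, SheetImage) else np.asarray(image)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        # ITU-R 601 luminance for RGB inputs
        arr = (
            0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2]
        ).astype(np.uint8)
    if arr.ndim != 2:
        raise ValueError("image must be 2-D grayscale (or RGB convertible)")
    return arr


def threshold_cut(threshold: int) -> int:
    """8-bit intensity cutoff for a 1..100 THRESHOLD value."""
    if not 1 <= threshold <= 100:
        raise ValueError("threshold must be in 1..100")
    return int(round(threshold * 255 / 100))


def binarize(image, threshold: int) -> np.ndarray:
    """Foreground mask: pixels strictly darker than the mapped cutoff.

    The strict inequality keeps pure paper white (255) out of the
    foreground even at THRESHOLD = 100.  This is the single place to change
    for a different thresholding convention.
    """
    arr = _as_gray(image)
    return arr < threshold_cut(threshold)


def _component_areas(mask: np.ndarray, connectivity: int = 2) -> np.ndarray:
    labels = _label(mask, connectivity=connectivity)
    if labels.max() == 0:
        return np.empty(0, dtype=int)
    return np.bincount(labels.ravel())[1:]


def count_particles(mask: np.ndarray, min_size: int, connectivity: int = 2) -> int:
    """Number of connected foreground components with area >= min_size."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    areas = _component_areas(np.asarray(mask, dtype=bool), connectivity)
    return int((areas >= min_size).sum())


def estimate_count(image, params: CountingParams, connectivity: int = 2) -> int:
    """Binarize then count: the full specimen-count estimate."""
    return count_particles(binarize(image, params.threshold), params.min_size, connectivity)


def _counts_all_sizes(image, connectivity: int = 2) -> np.ndarray:
    """(100, 100) array of counts for every (threshold, size) pair.

    One labelling per threshold; counts for all SIZE values follow from the
    sorted component areas.  Equivalent to calling estimate_count 10 000
    times (the brute-force path), just not quadratically slow.
    """
    arr = _as_gray(image)
    counts = np.zeros((100, 100), dtype=int)
    sizes = np.arange(1, 101)
    for ti, t in enumerate(PARAM_RANGE):
        areas = np.sort(_component_areas(arr < threshold_cut(t), connectivity))
        counts[ti] = areas.size - np.searchsorted(areas, sizes, side="left")
    return counts


@dataclass
class CalibrationGrid:
    """Mean/SD consistency for every (THRESHOLD, SIZE) pair, plus the best."""

    mean_c: np.ndarray  # (100, 100), thresholds x sizes
    sd_c: np.ndarray
    best: CountingParams | None
    window: tuple[float, float] = (97.5, 102.5)
    n_images: int = 0

    def lookup(self, params: CountingParams) -> tuple[float, float]:
        return (
            float(self.mean_c[params.threshold - 1, params.min_size - 1]),
            float(self.sd_c[params.threshold - 1, params.min_size - 1]),
        )

    def to_frame(self) -> pd.DataFrame:
        t, s = np.meshgrid(np.arange(1, 101), np.arange(1, 101), indexing="ij")
        return pd.DataFrame(
            {
                "threshold": t.ravel(),
                "min_size": s.ravel(),
                "mean_c": self.mean_c.ravel(),
                "sd_c": self.sd_c.ravel(),
            }
        )


def find_best(
    mean_c: np.ndarray, sd_c: np.ndarray, window: tuple[float, float] = (97.5, 102.5)
) -> CountingParams | None:
    """In-window pair with minimal SD (ties: |mean-100|, threshold, size)."""
    lo, hi = window
    in_window = (mean_c >= lo) & (mean_c <= hi)
    if not in_window.any():
        return None
    ti, si = np.nonzero(in_window)
    order = np.lexsort((si, ti, np.abs(mean_c[ti, si] - 100.0), sd_c[ti, si]))
    t, s = ti[order[0]], si[order[0]]
    return CountingParams(threshold=int(t) + 1, min_size=int(s) + 1)


def calibrate(
    images: list[SheetImage],
    window: tuple[float, float] = (97.5, 102.5),
    connectivity: int = 2,
) -> CalibrationGrid:
    """Exhaustive 100 x 100 grid search for the best counting parameters.

    Images with truth_count == 0 are excluded with a warning (their
    consistency is undefined); at least 2 usable images are required.
    The SD is the sample SD (ddof=1) across images.
    """
    usable = []
    for im in images:
        if im.truth_count <= 0:
            warnings.warn(
                f"image {im.sample_id!r} rep {im.replicate_id} has truth_count 0; excluded"
            )
            continue
        usable.append(im)
    if len(usable) < 2:
        raise ValueError("calibration needs at least 2 images with truth_count > 0")

    cons = np.stack(
        [100.0 * _counts_all_sizes(im, connectivity) / im.truth_count for im in usable]
    )
    mean_c = cons.mean(axis=0)
    sd_c = cons.std(axis=0, ddof=1)
    best = find_best(mean_c, sd_c, window)
    return CalibrationGrid(
        mean_c=mean_c, sd_c=sd_c, best=best, window=window, n_images=len(usable)
    )


def replicate_consistency(
    replicate_sets: list[list[SheetImage]],
    params: CountingParams,
    expected_replicates: int = 3,
    connectivity: int = 2,
) -> tuple[pd.DataFrame, StatResult | None]:
    """Reproducibility over re-photographed (rearranged) replicates.

    ``replicate_sets`` holds one list of replicate images per sample (all
    sharing a truth_count).  Returns the per-sample SD of the replicate
    estimates and, when >= 3 samples are usable, the pooled Pearson
    correlation of estimates vs truth over all images.
    """
    rows, est_all, truth_all = [], [], []
    for reps in replicate_sets:
        if len(reps) < expected_replicates:
            warnings.warn(
                f"sample {reps[0].sample_id if reps else '?'}: "
                f"{len(reps)} < {expected_replicates} replicates; skipped"
            )
            continue
        truths = {im.truth_count for im in reps}
        if len(truths) != 1:
            raise ValueError("replicates of one sample must share truth_count")
        ests = [estimate_count(im, params, connectivity) for im in reps]
        rows.append(
            {
                "sample_id": reps[0].sample_id,
                "truth_count": reps[0].truth_count,
                "mean_estimate": float(np.mean(ests)),
                "sd_estimate": float(np.std(ests, ddof=1)),
            }
        )
        est_all.extend(ests)
        truth_all.extend([im.truth_count for im in reps])

    table = pd.DataFrame(rows)
    r = None
    if len(rows) >= 3:
        try:
            r = pearson_r(est_all, truth_all)
        except ValueError:
            r = None
    return table, r
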