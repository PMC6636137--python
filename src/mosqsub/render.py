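"""Synthetic sheet photographs.

Renders a gridded sample as a grayscale photo: dark elliptical blobs
(specimens) on a light paper background with additive pixel noise.  The
renderer keeps ground-truth annotations (count and blob centres) so the
image-based particle counter can be evaluated against an exact oracle.

What this emulates: overhead photos of the sorting sheet, re-taken three
times with the specimens rearranged in between.  What it does not emulate:
species-specific morphology (wings/legs), colour, lighting gradients or
lens distortion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import ellipse as _draw_ellipse

from . import geometry
from ._rng import stream
from .synthetic import GriddedSample

__all__ = ["RenderParams", "SheetImage", "render_sheet_image"]


@dataclass(frozen=True)
class RenderParams:
    """Rendering knobs.

    scale_px_per_mm
        Pixel pitch; 2.0 gives a 420 x 594 px image of the A4 sheet.
    bg_level / fg_level
        Background (paper) and specimen-core 8-bit intensities; the
        background must be strictly lighter.
    blob_len_mm / blob_width_mm
        Mean major/minor diameters of the specimen ellipse (a resting
        mosquito body is a few mm long).
    size_cv
        Lognormal CV of a per-specimen size factor applied to both axes.
    noise_sd
        SD of additive Gaussian pixel noise (0 disables).
    allow_overlap
        If False, blob centres are re-placed by rejection sampling so no
        two ellipses can touch (disjoint ground truth), ignoring the
        sample's stored positions.
    min_gap_mm
        Minimum clearance between blob envelopes when overlap is disabled.
    """

    scale_px_per_mm: float = 2.0
    bg_level: int = 235
    fg_level: int = 45
    blob_len_mm: float = 3.2
    blob_width_mm: float = 1.4
    size_cv: float = 0.2
    noise_sd: float = 6.0
    allow_overlap: bool = True
    min_gap_mm: float = 0.8

    def __post_init__(self):
        if not 0 <= self.fg_level < self.bg_level <= 255:
            raise ValueError("need 0 <= fg_level < bg_level <= 255")
        if self.scale_px_per_mm <= 0:
            raise ValueError("scale must be > 0")

    @property
    def mean_blob_area_px(self) -> float:
        a = self.blob_len_mm * self.scale_px_per_mm / 2.0
        b = self.blob_width_mm * self.scale_px_per_mm / 2.0
        return float(np.pi * a * b)


@dataclass
class SheetImage:
    """8-bit grayscale sheet photo with ground truth."""

    pixels: np.ndarray
    scale_px_per_mm: float
    truth_count: int
    truth_positions: np.ndarray  # (n, 2) of (x_px, y_px)
    replicate_id: int = 1
    sample_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale array")
        if self.truth_count != len(self.truth_positions):
            raise ValueError("truth_count must equal number of truth positions")


def _draw_positions_uniform(n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(
        [0.0, 0.0], [geometry.SHEET_WIDTH_MM, geometry.SHEET_HEIGHT_MM], size=(n, 2)
    )


def _place_disjoint(
    radii_mm: np.ndarray, gap_mm: float, rng: np.random.Generator, max_tries: int = 5000
) -> np.ndarray:
    """Rejection-sample centres so blob envelopes (discs) cannot touch."""
    n = len(radii_mm)
    centres = np.empty((n, 2))
    order = np.argsort(-radii_mm)  # place big blobs first
    placed = 0
    for i in order:
        r = radii_mm[i]
        lo = np.array([r, r])
        hi = np.array([geometry.SHEET_WIDTH_MM - r, geometry.SHEET_HEIGHT_MM - r])
        for _ in range(max_tries):
            c = rng.uniform(lo, hi)
            if placed == 0:
                break
            d = np.hypot(*(centres[order[:placed]] - c).T)
            if np.all(d >= radii_mm[order[:placed]] + r + gap_mm):
                break
        else:
            raise RuntimeError(
                f"could not place {n} non-overlapping blobs on the sheet"
            )
        centres[i] = c
        placed += 1
    return centres


def render_sheet_image(
    gridded: GriddedSample,
    render: RenderParams | None = None,
    replicate_id: int = 1,
    seed: int = 0,
) -> SheetImage:
    """Render one photo replicate of a gridded sample.

    Replicate 1 uses the sample's stored specimen positions; replicates > 1
    redraw positions uniformly over the sheet (the physical rearrangement
    between photos), keeping ``truth_count`` unchanged.  Deterministic given
    (seed, replicate_id).
    """
    render = render or RenderParams()
    if render.mean_blob_area_px < 4.0:
        raise ValueError(
            f"mean blob area {render.mean_blob_area_px:.2f} px < 4 px: "
            "unresolvable rendering; increase scale_px_per_mm"
        )
    rng = stream(seed, "render", replicate_id)

    n = gridded.total
    scale = render.scale_px_per_mm
    shape = (
        int(round(geometry.SHEET_HEIGHT_MM * scale)),
        int(round(geometry.SHEET_WIDTH_MM * scale)),
    )

    size_factor = (
        np.exp(rng.normal(-render.size_cv**2 / 2, render.size_cv, size=n))
        if (n and render.size_cv > 0)
        else np.ones(n)
    )
    major_mm = render.blob_len_mm * size_factor / 2.0  # semi-axes
    minor_mm = render.blob_width_mm * size_factor / 2.0
    angles = rng.uniform(0.0, np.pi, size=n)

    if n == 0:
        centres_mm = np.empty((0, 2))
    elif not render.allow_overlap:
        centres_mm = _place_disjoint(major_mm, render.min_gap_mm, rng)
    elif replicate_id == 1 and gridded.positions is not None:
        pos = gridded.positions.sort_values("specimen_id")
        centres_mm = pos[["x_mm", "y_mm"]].to_numpy(dtype=float)
    else:
        centres_mm = _draw_positions_uniform(n, rng)

    img = np.full(shape, float(render.bg_level))
    for i in range(n):
        cx, cy = centres_mm[i] * scale
        rr, cc = _draw_ellipse(
            cy,
            cx,
            max(major_mm[i] * scale, 1.0),
            max(minor_mm[i] * scale, 1.0),
            shape=shape,
            rotation=angles[i],
        )
        img[rr, cc] = render.fg_level

    if render.noise_sd > 0:
        img += rng.normal(0.0, render.noise_sd, size=shape)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)

    return SheetImage(
        pixels=pixels,
        scale_px_per_mm=scale,
        truth_count=n,
        truth_positions=centres_mm * scale,
        replicate_id=replicate_id,
        sample_id=gridded.sample_id,
    )
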