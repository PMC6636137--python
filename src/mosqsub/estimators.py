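"""The five subsampling estimators.

Cell-based methods (area, volume, fresh weight, dry weight) extrapolate
from a set of selected grid cells:

* area:   est_total = mean specimen count over selected cells x n_cells
* volume / weight: est_total = sub_count x total_measure / sub_measure

The fixed-n method picks a fixed number of specimens (simple random
sampling without replacement, or nearest-to-random-point selection on the
sheet) and estimates composition, not abundance.  The adjacent-cell design
replaces random cell subsets with one contiguous block of whole rows.

Cell ids in the public API are 1-based (1..25, matching the printed sheet);
internally everything is 0-based.  The most abundant species is identified
on the FULL sample, never per subsample.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .synthetic import GriddedSample, SpeciesComposition

__all__ = [
    "UndefinedEstimateError",
    "EstimateResult",
    "estimate_by_area",
    "estimate_by_fraction",
    "estimate_cellbased",
    "select_fixed_n",
    "adjacent_cells",
    "ADJACENT_FRACTIONS",
]

CELL_METHODS = ("area", "volume", "weight_fresh", "weight_dry")
ADJACENT_FRACTIONS = (0.2, 0.4, 0.6, 0.8)


class UndefinedEstimateError(ValueError):
    """Raised when a fraction-based estimate has no measurable denominator."""


@dataclass(frozen=True)
class EstimateResult:
    """One subsample's estimates for a single sample."""

    method: str
    est_total: float
    est_mas_count: float
    est_mas_proportion: float
    detected_species: int
    cells_used: tuple[int, ...] | None = None  # 1-based
    n_used: int | None = None


def _cells_to_idx(cells, n_cells: int) -> np.ndarray:
    cells = sorted(set(int(c) for c in cells))
    if not cells:
        raise ValueError("cells must be non-empty")
    if cells[0] < 1 or cells[-1] > n_cells:
        raise ValueError(f"cell ids must be in 1..{n_cells}, got {cells}")
    return np.array(cells, dtype=int) - 1


def _species_stats(gridded: GriddedSample, idx: np.ndarray):
    """Subsample species table, detection count and dominant-species share."""
    sub_by_species = gridded.cell_counts[idx].sum(axis=0)
    sub_total = int(sub_by_species.sum())
    detected = int((sub_by_species > 0).sum())
    mas_j = gridded.most_abundant_index()
    mas_sub = int(sub_by_species[mas_j])
    proportion = mas_sub / sub_total if sub_total > 0 else 0.0
    return sub_total, mas_sub, detected, proportion


def estimate_by_area(gridded: GriddedSample, cells) -> EstimateResult:
    """Area method: mean count per selected cell, scaled to all cells."""
    idx = _cells_to_idx(cells, gridded.n_cells)
    k = len(idx)
    sub_total, mas_sub, detected, proportion = _species_stats(gridded, idx)
    factor = gridded.n_cells / k
    return EstimateResult(
        method="area",
        est_total=sub_total * factor,
        est_mas_count=mas_sub * factor,
        est_mas_proportion=proportion,
        detected_species=detected,
        cells_used=tuple(int(c) + 1 for c in idx),
    )


def estimate_by_fraction(sub_count: int, sub_measure: float, total_measure: float) -> float:
    """Scale a subsample count by the inverse of its measured fraction."""
    if sub_count < 0:
        raise ValueError("sub_count must be >= 0")
    if total_measure <= 0:
        raise UndefinedEstimateError("total measure must be > 0")
    if sub_measure <= 0:
        raise UndefinedEstimateError(
            "empty subsample has no measurable volume/weight"
        )
    if sub_measure > total_measure + 1e-9:
        raise ValueError("sub_measure exceeds total_measure")
    return sub_count * total_measure / sub_measure


def estimate_cellbased(
    gridded: GriddedSample, cells, measure: str
) -> EstimateResult:
    """Volume / fresh-weight / dry-weight extrapolation from selected cells.

    Species detection and the dominant-species proportion are identical to
    the area method on the same cells — the physical subsample is the same;
    only the extrapolation of totals differs.
    """
    if measure not in ("volume", "weight_fresh", "weight_dry"):
        raise ValueError(f"unknown measure {measure!r}")
    idx = _cells_to_idx(cells, gridded.n_cells)
    values = gridded.measure(measure)
    total_measure = float(values.sum())
    sub_measure = float(values[idx].sum())
    sub_total, mas_sub, detected, proportion = _species_stats(gridded, idx)
    est_total = estimate_by_fraction(sub_total, sub_measure, total_measure)
    est_mas = mas_sub * total_measure / sub_measure
    return EstimateResult(
        method=measure,
        est_total=est_total,
        est_mas_count=est_mas,
        est_mas_proportion=proportion,
        detected_species=detected,
        cells_used=tuple(int(c) + 1 for c in idx),
    )


# ---------------------------------------------------------------------------
# fixed-n selection


def _specimen_arrays(source):
    """(species labels per specimen, positions or None), ordered by specimen id."""
    if isinstance(source, SpeciesComposition):
        labels = np.repeat(
            np.array(source.species, dtype=object),
            [source.counts[sp] for sp in source.species],
        )
        return labels, None
    if isinstance(source, GriddedSample):
        if source.positions is None:
            labels = np.repeat(
                np.array(source.species, dtype=object),
                [source.composition.counts[sp] for sp in source.species],
            )
            return labels, None
        pos = source.positions.sort_values("specimen_id")
        return (
            pos["species"].to_numpy(dtype=object),
            pos[["x_mm", "y_mm"]].to_numpy(dtype=float),
        )
    raise TypeError("source must be a SpeciesComposition or GriddedSample")


def select_fixed_n(
    source,
    n: int,
    mode: str = "srswor",
    points: np.ndarray | None = None,
    seed: int = 0,
) -> dict[str, int]:
    """Select n specimens and return their species -> count table.

    srswor
        Simple random sampling without replacement among all specimens.
    nearest_point
        For each of n sheet points (in index order) take the nearest
        still-available specimen (Euclidean distance, ties broken by lowest
        specimen id); every point yields a distinct specimen.
    """
    labels, coords = _specimen_arrays(source)
    total = len(labels)
    if not 1 <= n <= total:
        raise ValueError(f"n must be in 1..{total}, got {n}")

    if mode == "srswor":
        rng = np.random.default_rng(seed)
        chosen = rng.choice(total, size=n, replace=False)
    elif mode == "nearest_point":
        if coords is None:
            raise ValueError("nearest_point mode requires specimen positions")
        if points is None or len(points) != n:
            raise ValueError("nearest_point mode requires exactly n points")
        available = np.ones(total, dtype=bool)
        chosen = np.empty(n, dtype=int)
        for i, pt in enumerate(np.asarray(points, dtype=float)):
            d = np.hypot(coords[:, 0] - pt[0], coords[:, 1] - pt[1])
            d[~available] = np.inf
            pick = int(np.argmin(d))  # argmin -> lowest index on ties
            chosen[i] = pick
            available[pick] = False
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return dict(Counter(labels[chosen]))


def adjacent_cells(fraction: float) -> frozenset[int]:
    """The fixed contiguous block for a proportional single-step subsample.

    Convention: whole rows from the top of the sheet — 20% is the top row
    {1..5}, 40% the top two rows {1..10}, and so on.  Deterministic.
    """
    for f in ADJACENT_FRACTIONS:
        if abs(fraction - f) < 1e-9:
            n_rows = round(f * 5)
            return frozenset(range(1, 5 * n_rows + 1))
    raise ValueError(
        f"fraction must be one of {ADJACENT_FRACTIONS}, got {fraction}"
    )
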