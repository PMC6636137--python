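"""Bootstrap evaluation of the subsampling estimators.

For each sample and each subsample size k (1..25 cells), B random k-subsets
of cells are drawn (uniformly, without replacement within a draw), the
chosen estimator is applied, and each estimate is expressed as a
consistency score:

    consistency = 100 x estimated / actual

so 100 means perfect estimation.  Per (sample, k) the bootstrap mean and
95% percentile confidence interval are computed, then averaged across
samples with equal weight.  The error rate is the mean absolute deviation
of the consistency from 100 (the CI half-width is reported alongside).

Three consistency tracks are evaluated for every draw: the total specimen
count, the count of the sample's most abundant species (identified on the
full sample), and the number of detected species.  Species consistency can
never exceed 100 — a subsample cannot invent species.

The drawn subsets depend only on (seed, sample index, k), never on the
estimator, so area/volume/weight curves from the same seed see identical
subsets and differ only through the extrapolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import stream
from .estimators import ADJACENT_FRACTIONS, adjacent_cells, select_fixed_n
from .synthetic import GriddedSample

__all__ = [
    "consistency",
    "error_rate",
    "BootstrapCurve",
    "bootstrap_curve",
    "evaluate_adjacent",
    "FixedNResult",
    "evaluate_fixed_n",
    "StatResult",
    "pearson_r",
    "paired_t",
    "UndefinedStatisticError",
]

_TRACKS = ("total", "mas", "species")


class UndefinedStatisticError(ValueError):
    """Raised when a statistic's denominator (a variance) is zero."""


def consistency(estimate: float, actual: float) -> float:
    """100 x estimated / actual; 100 = perfect estimation."""
    if actual <= 0:
        raise ValueError("actual must be > 0")
    if estimate < 0:
        raise ValueError("estimate must be >= 0")
    return 100.0 * estimate / actual


def error_rate(consistencies) -> float:
    """Mean absolute deviation of consistency scores from 100 (percent)."""
    c = np.asarray(list(consistencies), dtype=float)
    if c.size == 0:
        raise ValueError("empty consistency list")
    return float(np.abs(c - 100.0).mean())


# ---------------------------------------------------------------------------
# bootstrap curves


def _draw_subsets(rng: np.random.Generator, B: int, n_cells: int, k: int) -> np.ndarray:
    """B uniform k-subsets of {0..n_cells-1}, one subset per row, sorted."""
    idx = np.argsort(rng.random((B, n_cells)), axis=1)[:, :k]
    return np.sort(idx, axis=1)


def _consistencies_for_draws(
    gridded: GriddedSample, idx: np.ndarray, method: str
) -> dict[str, np.ndarray]:
    """Consistency scores (total/mas/species) for a batch of cell subsets."""
    k = idx.shape[1]
    n_cells = gridded.n_cells
    actual_total = gridded.total
    mas_j = gridded.most_abundant_index()
    actual_mas = int(gridded.cell_counts[:, mas_j].sum())
    actual_species = len(gridded.species)

    by_sp = gridded.cell_counts[idx].sum(axis=1)  # (B, S)
    sub_tot = by_sp.sum(axis=1).astype(float)
    mas_sub = by_sp[:, mas_j].astype(float)
    detected = (by_sp > 0).sum(axis=1).astype(float)

    if method == "area":
        factor = np.full(len(idx), n_cells / k)
    else:
        values = gridded.measure(method)
        total_measure = float(values.sum())
        if total_measure <= 0:
            raise ValueError(
                f"sample {gridded.sample_id!r}: total {method} measure is 0"
            )
        sub_measure = values[idx].sum(axis=1)
        # empty subsample: no measurable fraction; estimate 0, replicate kept
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = np.where(sub_measure > 0, total_measure / sub_measure, 0.0)

    c_total = 100.0 * sub_tot * factor / actual_total
    c_mas = 100.0 * mas_sub * factor / actual_mas
    c_species = 100.0 * detected / actual_species
    return {"total": c_total, "mas": c_mas, "species": c_species}


def _summarize_track(c: np.ndarray) -> dict[str, float]:
    lo, hi = np.percentile(c, [2.5, 97.5])
    return {
        "mean_c": float(c.mean()),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "error": float(np.abs(c - 100.0).mean()),
    }


@dataclass
class BootstrapCurve:
    """Per-k consistency summary, averaged over samples."""

    method: str
    B: int
    seed: int
    table: pd.DataFrame  # one row per k
    per_sample: pd.DataFrame = field(repr=False, default=None)

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "method", self.method)
        out["B"] = self.B
        out["seed"] = self.seed
        out.to_csv(path, index=False)


def bootstrap_curve(
    samples: list[GriddedSample],
    method: str = "area",
    B: int = 1000,
    ks=None,
    seed: int = 0,
) -> BootstrapCurve:
    """Bootstrap consistency curve for one estimator over many samples.

    Parameters
    ----------
    samples
        Gridded samples; cell-measure methods require biometrics.
    method
        "area", "volume", "weight_fresh" or "weight_dry".
    B
        Bootstrap replicates per (sample, k); the study design uses 1000.
    ks
        Iterable of subsample sizes; default 1..n_cells.
    """
    if not samples:
        raise ValueError("need at least one sample")
    if B < 1:
        raise ValueError("B must be >= 1")
    n_cells = samples[0].n_cells
    if any(s.n_cells != n_cells for s in samples):
        raise ValueError("all samples must share the cell universe")
    ks = list(ks) if ks is not None else list(range(1, n_cells + 1))
    if any(not 1 <= k <= n_cells for k in ks):
        raise ValueError(f"ks must be within 1..{n_cells}")

    rows = []
    for si, sample in enumerate(samples):
        for k in ks:
            rng = stream(seed, "subsets", si, k)
            idx = _draw_subsets(rng, B, n_cells, k)
            tracks = _consistencies_for_draws(sample, idx, method)
            row = {"sample_id": sample.sample_id, "k": k}
            for name, c in tracks.items():
                for stat, value in _summarize_track(c).items():
                    row[f"{stat}_{name}"] = value
            rows.append(row)
    per_sample = pd.DataFrame(rows)

    # equal-weight average of per-sample bootstrap summaries
    table = per_sample.drop(columns="sample_id").groupby("k", as_index=False).mean()
    for name in _TRACKS:
        table[f"ci_halfwidth_{name}"] = (
            table[f"ci_high_{name}"] - table[f"ci_low_{name}"]
        ) / 2.0
    return BootstrapCurve(method=method, B=B, seed=seed, table=table, per_sample=per_sample)


# ---------------------------------------------------------------------------
# adjacent-cell design


def evaluate_adjacent(
    samples: list[GriddedSample],
    method: str = "area",
    fractions=ADJACENT_FRACTIONS,
) -> pd.DataFrame:
    """Single-step contiguous-block subsampling at 20/40/60/80% of cells.

    One deterministic block per fraction (no resampling); consistencies are
    computed per sample and summarised as mean and SD across samples
    (population SD, so a single sample gives SD 0 by convention).
    """
    if not samples:
        raise ValueError("need at least one sample")
    rows = []
    for fraction in fractions:
        cells = sorted(adjacent_cells(fraction))
        per_sample = {name: [] for name in _TRACKS}
        for sample in samples:
            idx = np.array(cells, dtype=int).reshape(1, -1) - 1
            tracks = _consistencies_for_draws(sample, idx, method)
            for name in _TRACKS:
                per_sample[name].append(float(tracks[name][0]))
        row = {"fraction": fraction, "n_cells": len(cells)}
        for name in _TRACKS:
            arr = np.array(per_sample[name])
            row[f"mean_c_{name}"] = float(arr.mean())
            row[f"sd_c_{name}"] = float(arr.std(ddof=0))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixed-n random specimens


@dataclass
class FixedNResult:
    """Fixed-n evaluation: species detection and dominant-species share."""

    n: int
    per_sample: pd.DataFrame
    missed_species_mean: float
    missed_species_sd: float
    r_species: "StatResult | None"
    r_proportion: "StatResult | None"


def evaluate_fixed_n(
    samples: list[GriddedSample],
    n: int = 200,
    replicates: int = 1,
    seed: int = 0,
    mode: str = "srswor",
    points_seed: int | None = None,
) -> FixedNResult:
    """Evaluate selection of a fixed number of random specimens per sample.

    Per sample, ``replicates`` independent selections of min(n, total)
    specimens are drawn and averaged; samples smaller than n are fully
    sorted and flagged.  Reports the percentage of actual species detected
    (and missed), the estimated vs actual proportion of the most abundant
    species, and Pearson correlations of detected species counts and of the
    proportions against the actual values (requires >= 3 samples).
    """
    if not samples:
        raise ValueError("need at least one sample")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")

    rows = []
    for si, sample in enumerate(samples):
        comp = sample.composition
        actual_species = comp.n_species
        mas = comp.most_abundant()
        actual_prop = comp.counts[mas] / comp.total
        n_eff = min(n, comp.total)
        det, props = [], []
        for rep in range(replicates):
            rng_seed = int(stream(seed, "fixed_n", si, rep).integers(0, 2**31))
            if mode == "nearest_point":
                pts_seed = int(
                    stream(points_seed if points_seed is not None else seed,
                           "points", si, rep).integers(0, 2**31)
                )
                from .geometry import place_points

                pts = place_points(n_eff, pts_seed)
                sel = select_fixed_n(sample, n_eff, mode=mode, points=pts, seed=rng_seed)
            else:
                sel = select_fixed_n(comp, n_eff, mode=mode, seed=rng_seed)
            det.append(len(sel))
            sub_total = sum(sel.values())
            props.append(sel.get(mas, 0) / sub_total if sub_total else 0.0)
        detected = float(np.mean(det))
        est_prop = float(np.mean(props))
        rows.append(
            {
                "sample_id": comp.sample_id,
                "total": comp.total,
                "n_selected": n_eff,
                "fully_sorted": n_eff == comp.total,
                "actual_species": actual_species,
                "detected_species": detected,
                "detected_pct": 100.0 * detected / actual_species,
                "missed_pct": 100.0 * (1.0 - detected / actual_species),
                "actual_mas_proportion": actual_prop,
                "est_mas_proportion": est_prop,
            }
        )
    per_sample = pd.DataFrame(rows)

    r_species = r_proportion = None
    if len(samples) >= 3:
        try:
            r_species = pearson_r(
                per_sample["detected_species"], per_sample["actual_species"]
            )
        except UndefinedStatisticError:
            pass
        try:
            r_proportion = pearson_r(
                per_sample["est_mas_proportion"], per_sample["actual_mas_proportion"]
            )
        except UndefinedStatisticError:
            pass

    return FixedNResult(
        n=n,
        per_sample=per_sample,
        missed_species_mean=float(per_sample["missed_pct"].mean()),
        missed_species_sd=float(per_sample["missed_pct"].std(ddof=0)),
        r_species=r_species,
        r_proportion=r_proportion,
    )


# ---------------------------------------------------------------------------
# classical statistics


@dataclass(frozen=True)
class StatResult:
    statistic_name: str
    estimate: float
    p_value: float
    df: int | None = None


def pearson_r(x, y) -> StatResult:
    """Product-moment correlation with a two-sided t-transform p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    return StatResult("pearson_r", float(res.statistic), float(res.pvalue), df=len(x) - 2)


def paired_t(a, b) -> StatResult:
    """Paired-samples t-test of a vs b: t = mean(d) / (sd(d)/sqrt(n))."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise UndefinedStatisticError("zero-variance differences: t undefined")
    res = stats.ttest_rel(a, b)
    if not math.isfinite(res.statistic):
        raise UndefinedStatisticError("t statistic undefined")
    return StatResult("paired_t", float(res.statistic), float(res.pvalue), df=len(a) - 1)
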