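"""Synthetic mosquito trap samples.

Generates virtual samples with the statistical structure of large CO2-trap
catches: a handful of species with one strongly dominant taxon, hundreds to
thousands of specimens spread (possibly unevenly) over the 25-cell sorting
sheet, and per-cell biometric measurements (settled volume, fresh and dry
weight) with realistic reading noise.

The spatial model is a Dirichlet-multinomial: per-cell weights are drawn
from a symmetric Dirichlet with concentration ``theta`` per cell (optionally
down-weighted on the 16 peripheral cells), and every species' count is then
allocated multinomially over cells given those shared weights.  ``theta``
controls clustering: small theta gives strongly clustered sheets,
theta -> infinity recovers the uniform multinomial.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import geometry
from ._rng import stream

__all__ = [
    "SpeciesComposition",
    "ClusteringModel",
    "BiometricModel",
    "SpeciesBiometrics",
    "GriddedSample",
    "generate_composition",
    "allocate_to_grid",
    "assign_biometrics",
]


# ---------------------------------------------------------------------------
# species composition


@dataclass(frozen=True)
class SpeciesComposition:
    """Ground-truth species -> specimen-count table for one sample."""

    sample_id: str
    counts: dict[str, int]

    def __post_init__(self):
        # an empty mapping is the degenerate empty sample; every listed
        # species must be present with at least one specimen
        for sp, c in self.counts.items():
            if int(c) != c or c < 1:
                raise ValueError(f"count for {sp!r} must be an integer >= 1, got {c}")

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def n_species(self) -> int:
        return len(self.counts)

    @property
    def species(self) -> list[str]:
        return sorted(self.counts)

    def most_abundant(self) -> str:
        """The single most abundant species; ties broken by lexicographic label."""
        if not self.counts:
            raise ValueError("empty composition has no most abundant species")
        top = max(self.counts.values())
        return min(sp for sp, c in self.counts.items() if c == top)


def generate_composition(
    n_species: int,
    total: int,
    dominance: float = 0.6,
    seed: int = 0,
    *,
    sample_id: str = "sample",
    ratio: float = 0.5,
    jitter_sd: float = 0.3,
    labels: list[str] | None = None,
) -> SpeciesComposition:
    """Draw a skewed species composition with one dominant species.

    The dominant species receives round(dominance * total) specimens (clamped
    so every other species can keep at least one).  The remainder is split
    over the other species by a geometric rank-abundance series with ratio
    ``ratio``, log-normally jittered (sd ``jitter_sd``) per species, floored
    at one specimen each, with largest-remainder rounding.

    Parameters
    ----------
    n_species
        Number of species present (each with count >= 1).
    total
        Total number of specimens; must be >= n_species.
    dominance
        Target share of the top species, in (0, 1).
    seed
        Seed for the rank-abundance jitter; the allocation is deterministic
        given the seed.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if total < n_species:
        raise ValueError(f"total ({total}) must be >= n_species ({n_species})")
    if not 0.0 < dominance < 1.0:
        raise ValueError(f"dominance must be in (0, 1), got {dominance}")

    if labels is None:
        labels = [f"sp{i + 1:02d}" for i in range(n_species)]
    elif len(labels) != n_species:
        raise ValueError("labels length must equal n_species")

    if n_species == 1:
        return SpeciesComposition(sample_id, {labels[0]: total})

    m = n_species - 1
    dominant = int(round(dominance * total))
    dominant = max(1, min(dominant, total - m))

    rest = total - dominant  # >= m by the clamp above
    counts = np.ones(m, dtype=int)
    extra = rest - m
    if extra > 0:
        rng = stream(seed, "composition")
        w = ratio ** np.arange(m)
        if jitter_sd > 0:
            w = w * np.exp(rng.normal(0.0, jitter_sd, size=m))
        target = extra * w / w.sum()
        base = np.floor(target).astype(int)
        counts += base
        leftover = extra - int(base.sum())
        order = np.argsort(-(target - base), kind="stable")
        counts[order[:leftover]] += 1

    table = {labels[0]: dominant}
    for lab, c in zip(labels[1:], counts):
        table[lab] = int(c)
    return SpeciesComposition(sample_id, table)


# ---------------------------------------------------------------------------
# spatial allocation


@dataclass(frozen=True)
class ClusteringModel:
    """Dirichlet-multinomial clustering of specimens over grid cells.

    theta
        Per-cell Dirichlet concentration (> 0).  theta -> infinity gives the
        uniform multinomial; small theta gives clustered sheets.  The field
        value is unknown; the default 5 is a documented calibration knob.
    edge_bias
        Multiplicative concentration weight (0 < w <= 1) on the 16 peripheral
        cells, emulating the tendency of specimens to end up away from the
        sheet edge.  1 disables the effect.
    """

    theta: float = 5.0
    edge_bias: float = 1.0

    def __post_init__(self):
        if not self.theta > 0:
            raise ValueError("theta must be > 0")
        if not 0.0 < self.edge_bias <= 1.0:
            raise ValueError("edge_bias must be in (0, 1]")

    def cell_concentrations(self, n_cells: int = geometry.N_CELLS) -> np.ndarray:
        alpha = np.full(n_cells, self.theta, dtype=float)
        if n_cells == geometry.N_CELLS:
            alpha[geometry.peripheral_cells()] *= self.edge_bias
        return alpha


@dataclass
class GriddedSample:
    """A sample distributed over grid cells, with optional biometrics.

    ``cell_counts`` is an (n_cells, n_species) integer matrix whose column
    order follows ``species``; normally n_cells == 25, but toy universes with
    fewer cells are allowed for enumeration oracles.  Per-cell measures are
    filled by :func:`assign_biometrics`.  ``positions`` is a DataFrame with
    columns specimen_id, species, x_mm, y_mm, cell (0-based).
    """

    composition: SpeciesComposition
    species: list[str]
    cell_counts: np.ndarray
    cell_volume_ul: np.ndarray | None = None
    cell_wet_mg: np.ndarray | None = None
    cell_dry_mg: np.ndarray | None = None
    positions: pd.DataFrame | None = None

    def __post_init__(self):
        self.cell_counts = np.asarray(self.cell_counts, dtype=int)
        if self.cell_counts.ndim != 2 or self.cell_counts.shape[1] != len(self.species):
            raise ValueError("cell_counts must be (n_cells, n_species)")
        if np.any(self.cell_counts < 0):
            raise ValueError("negative cell counts")

    # -- derived views ------------------------------------------------------

    @property
    def sample_id(self) -> str:
        return self.composition.sample_id

    @property
    def n_cells(self) -> int:
        return self.cell_counts.shape[0]

    @property
    def cell_totals(self) -> np.ndarray:
        return self.cell_counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.cell_counts.sum())

    def most_abundant_index(self) -> int:
        """Column index of the most abundant species of the FULL sample."""
        label = self.composition.most_abundant()
        return self.species.index(label)

    def measure(self, name: str) -> np.ndarray:
        arr = {
            "volume": self.cell_volume_ul,
            "weight_fresh": self.cell_wet_mg,
            "weight_dry": self.cell_dry_mg,
        }.get(name)
        if arr is None:
            raise ValueError(
                f"sample {self.sample_id!r} has no {name!r} measure; "
                "run assign_biometrics first"
            )
        return arr

    def validate(self) -> None:
        """Check conservation, weight ordering and position geometry."""
        col = {sp: self.cell_counts[:, j].sum() for j, sp in enumerate(self.species)}
        for sp, c in self.composition.counts.items():
            if col.get(sp, 0) != c:
                raise ValueError(f"column sum for {sp!r} != composition count")
        if self.cell_wet_mg is not None and self.cell_dry_mg is not None:
            if np.any(self.cell_dry_mg > self.cell_wet_mg + 1e-9):
                raise ValueError("dry weight exceeds wet weight")
        if self.positions is not None and self.n_cells == geometry.N_CELLS:
            x = self.positions["x_mm"].to_numpy()
            y = self.positions["y_mm"].to_numpy()
            cells = geometry.cell_of(x, y)
            if np.any(cells != self.positions["cell"].to_numpy()):
                raise ValueError("position/cell mismatch")

    @classmethod
    def from_counts(
        cls, cell_counts, species: list[str] | None = None, sample_id: str = "toy"
    ) -> "GriddedSample":
        """Build a (possibly toy) sample directly from a count matrix."""
        cell_counts = np.atleast_2d(np.asarray(cell_counts, dtype=int))
        if cell_counts.shape[0] == 1:
            cell_counts = cell_counts.T  # a vector means one species
        if species is None:
            species = [f"sp{j + 1:02d}" for j in range(cell_counts.shape[1])]
        counts = {
            sp: int(cell_counts[:, j].sum())
            for j, sp in enumerate(species)
            if cell_counts[:, j].sum() > 0
        }
        comp = SpeciesComposition(sample_id, counts)
        return cls(comp, list(species), cell_counts)


def allocate_to_grid(
    composition: SpeciesComposition,
    clustering: ClusteringModel,
    seed: int,
    *,
    with_positions: bool = True,
) -> GriddedSample:
    """Distribute a composition over the 25 grid cells.

    Per-cell weights are one Dirichlet draw shared by all species (the
    clustering is physical, not taxonomic); each species' count is then
    multinomial over cells.  Column sums are preserved exactly.  Each
    specimen is placed uniformly at random inside its cell.
    """
    rng = stream(seed, "allocate")
    alpha = clustering.cell_concentrations()
    p = rng.dirichlet(alpha)

    species = composition.species
    n_cells = geometry.N_CELLS
    cell_counts = np.zeros((n_cells, len(species)), dtype=int)
    for j, sp in enumerate(species):
        cell_counts[:, j] = rng.multinomial(composition.counts[sp], p)

    positions = None
    if with_positions:
        rows = []
        specimen_id = 0
        for cell in range(n_cells):
            x0, y0, x1, y1 = geometry.cell_rect(cell)
            for j, sp in enumerate(species):
                c = int(cell_counts[cell, j])
                if c == 0:
                    continue
                xs = rng.uniform(x0, x1, size=c)
                ys = rng.uniform(y0, y1, size=c)
                for x, y in zip(xs, ys):
                    rows.append((specimen_id, sp, x, y, cell))
                    specimen_id += 1
        positions = pd.DataFrame(
            rows, columns=["specimen_id", "species", "x_mm", "y_mm", "cell"]
        )

    return GriddedSample(composition, species, cell_counts, positions=positions)


# ---------------------------------------------------------------------------
# biometrics


@dataclass(frozen=True)
class SpeciesBiometrics:
    """Per-specimen fresh mass (mg) and settled volume (ul) distribution."""

    wet_mg_mean: float = 2.0
    wet_mg_cv: float = 0.35
    vol_ul_mean: float = 8.0
    vol_ul_cv: float = 0.35

    def __post_init__(self):
        if self.wet_mg_mean <= 0 or self.vol_ul_mean <= 0:
            raise ValueError("means must be > 0")
        if self.wet_mg_cv < 0 or self.vol_ul_cv < 0:
            raise ValueError("CVs must be >= 0")


@dataclass(frozen=True)
class BiometricModel:
    """Measurement model for per-cell tubes.

    Per-specimen wet mass and volume are lognormal with species-specific
    mean/CV (``overrides`` maps species label -> SpeciesBiometrics; others
    use ``default``).  Per-cell fresh weight is the specimen-mass sum rounded
    to ``balance_precision`` mg.  Per-cell dry weight is fresh x (1 - f),
    where f is a per-cell (per-tube) water-loss fraction drawn from a
    Normal(water_loss_mean, water_loss_sd) truncated to [0, 0.95].  Per-cell
    volume is the specimen-volume sum rounded UP to the tube graduation
    (meniscus-style scale reading); ``volume_graduation`` None selects
    100 ul (2 ml tube) or 500 ul (15 ml tube) by the raw subsample volume.
    """

    default: SpeciesBiometrics = field(default_factory=SpeciesBiometrics)
    overrides: dict[str, SpeciesBiometrics] = field(default_factory=dict)
    water_loss_mean: float = 0.273
    water_loss_sd: float = 0.178
    water_loss_bounds: tuple[float, float] = (0.0, 0.95)
    volume_graduation: float | None = None
    small_tube_capacity_ul: float = 2000.0
    balance_precision: float = 0.1

    def __post_init__(self):
        if not 0.0 < self.water_loss_mean < 1.0:
            raise ValueError("water_loss_mean must be in (0, 1)")
        if self.water_loss_sd < 0:
            raise ValueError("water_loss_sd must be >= 0")
        if self.balance_precision < 0:
            raise ValueError("balance_precision must be >= 0")
        if self.volume_graduation is not None and self.volume_graduation < 0:
            raise ValueError("volume_graduation must be >= 0")

    def for_species(self, label: str) -> SpeciesBiometrics:
        return self.overrides.get(label, self.default)

    def truncated_water_loss_moments(self) -> tuple[float, float]:
        """Mean and SD of the truncated water-loss distribution."""
        lo, hi = self.water_loss_bounds
        if self.water_loss_sd == 0:
            return self.water_loss_mean, 0.0
        a = (lo - self.water_loss_mean) / self.water_loss_sd
        b = (hi - self.water_loss_mean) / self.water_loss_sd
        mean, var = stats.truncnorm.stats(
            a, b, loc=self.water_loss_mean, scale=self.water_loss_sd, moments="mv"
        )
        return float(mean), float(np.sqrt(var))


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _round_to(x: np.ndarray, precision: float) -> np.ndarray:
    if precision <= 0:
        return x
    return np.round(x / precision) * precision


def assign_biometrics(
    gridded: GriddedSample, model: BiometricModel, seed: int
) -> GriddedSample:
    """Fill per-cell volume, fresh weight and dry weight.

    Empty cells read 0 for all measures (no specimens, no reading).
    Deterministic given the seed.  Returns a new GriddedSample.
    """
    rng = stream(seed, "biometrics")
    n_cells = gridded.n_cells
    raw_wet = np.zeros(n_cells)
    raw_vol = np.zeros(n_cells)

    for j, sp in enumerate(gridded.species):
        bio = model.for_species(sp)
        mu_m, sd_m = _lognormal_params(bio.wet_mg_mean, bio.wet_mg_cv)
        mu_v, sd_v = _lognormal_params(bio.vol_ul_mean, bio.vol_ul_cv)
        for cell in range(n_cells):
            c = int(gridded.cell_counts[cell, j])
            if c == 0:
                continue
            if sd_m > 0:
                raw_wet[cell] += rng.lognormal(mu_m, sd_m, size=c).sum()
            else:
                raw_wet[cell] += c * bio.wet_mg_mean
            if sd_v > 0:
                raw_vol[cell] += rng.lognormal(mu_v, sd_v, size=c).sum()
            else:
                raw_vol[cell] += c * bio.vol_ul_mean

    occupied = gridded.cell_totals > 0

    # per-tube water loss fraction, truncated normal
    lo, hi = model.water_loss_bounds
    if model.water_loss_sd > 0:
        a = (lo - model.water_loss_mean) / model.water_loss_sd
        b = (hi - model.water_loss_mean) / model.water_loss_sd
        f = stats.truncnorm.rvs(
            a,
            b,
            loc=model.water_loss_mean,
            scale=model.water_loss_sd,
            size=n_cells,
            random_state=rng,
        )
    else:
        f = np.full(n_cells, model.water_loss_mean)

    wet = _round_to(raw_wet, model.balance_precision)
    dry = _round_to(raw_wet * (1.0 - f), model.balance_precision)
    dry = np.minimum(dry, wet)

    if model.volume_graduation is not None:
        grad = np.full(n_cells, float(model.volume_graduation))
    else:
        grad = np.where(raw_vol <= model.small_tube_capacity_ul, 100.0, 500.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        vol = np.where(grad > 0, np.ceil(raw_vol / grad) * grad, raw_vol)

    wet[~occupied] = 0.0
    dry[~occupied] = 0.0
    vol[~occupied] = 0.0

    return dataclasses.replace(
        gridded, cell_volume_ul=vol, cell_wet_mg=wet, cell_dry_mg=dry
    )
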