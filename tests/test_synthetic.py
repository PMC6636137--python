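"""Unit and property tests for the synthetic-sample generator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import mosqsub as m
from mosqsub.geometry import (
    CELL_HEIGHT_MM,
    CELL_WIDTH_MM,
    N_CELLS,
    SHEET_HEIGHT_MM,
    SHEET_WIDTH_MM,
    cell_of,
    peripheral_cells,
    place_points,
)

# ---------------------------------------------------------------------------
# composition


class TestGenerateComposition:
    def test_single_species_degenerate(self):
        comp = m.generate_composition(1, 500, dominance=0.5, seed=0)
        assert comp.counts == {"sp01": 500}

    def test_dominant_share(self):
        comp = m.generate_composition(8, 1632, dominance=0.5, seed=1)
        assert comp.total == 1632
        assert comp.n_species == 8
        assert all(c >= 1 for c in comp.counts.values())
        # the top species holds round(0.5 * 1632) = 816 specimens
        assert max(comp.counts.values()) == 816
        assert comp.counts[comp.most_abundant()] == 816

    def test_floor_at_one_rule(self):
        # brute force: 0.995 * 200 rounds to 199, the other species keeps 1
        comp = m.generate_composition(2, 200, dominance=0.995, seed=0)
        assert sorted(comp.counts.values()) == [1, 199]

    @pytest.mark.parametrize(
        "n_species,total,dominance",
        [(5, 4, 0.5), (2, 100, 0.0), (2, 100, 1.0), (0, 10, 0.5)],
    )
    def test_invalid_arguments(self, n_species, total, dominance):
        with pytest.raises(ValueError):
            m.generate_composition(n_species, total, dominance=dominance, seed=0)

    @given(
        n_species=st.integers(1, 12),
        total=st.integers(12, 5000),
        dominance=st.floats(0.05, 0.95),
        seed=st.integers(0, 2**20),
    )
    @settings(max_examples=60, derandomize=True)
    def test_invariants(self, n_species, total, dominance, seed):
        comp = m.generate_composition(n_species, total, dominance, seed)
        assert comp.total == total
        assert comp.n_species == n_species
        assert min(comp.counts.values()) >= 1
        again = m.generate_composition(n_species, total, dominance, seed)
        assert again.counts == comp.counts

    def test_tie_break_is_lexicographic(self):
        comp = m.SpeciesComposition("s", {"b_sp": 5, "a_sp": 5, "c_sp": 1})
        assert comp.most_abundant() == "a_sp"


# ---------------------------------------------------------------------------
# grid allocation


class TestAllocateToGrid:
    @given(seed=st.integers(0, 2**20), theta=st.floats(0.5, 50.0))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_conservation(self, seed, theta):
        comp = m.generate_composition(6, 900, dominance=0.6, seed=1)
        g = m.allocate_to_grid(comp, m.ClusteringModel(theta=theta), seed=seed)
        assert g.total == 900
        for j, sp in enumerate(g.species):
            assert g.cell_counts[:, j].sum() == comp.counts[sp]

    def test_positions_match_cells(self):
        comp = m.generate_composition(4, 300, dominance=0.5, seed=2)
        g = m.allocate_to_grid(comp, m.ClusteringModel(theta=3.0, edge_bias=0.6), seed=7)
        pos = g.positions
        assert len(pos) == 300
        assert pos["x_mm"].between(0, SHEET_WIDTH_MM).all()
        assert pos["y_mm"].between(0, SHEET_HEIGHT_MM).all()
        cells = cell_of(pos["x_mm"].to_numpy(), pos["y_mm"].to_numpy())
        assert (cells == pos["cell"].to_numpy()).all()
        g.validate()

    def test_uniform_limit_chi_square(self):
        """theta -> infinity is indistinguishable from a uniform multinomial."""
        comp = m.generate_composition(1, 25_000, dominance=0.5, seed=0)
        model = m.ClusteringModel(theta=1e6, edge_bias=1.0)
        rejections = 0
        for seed in range(100):
            g = m.allocate_to_grid(comp, model, seed=seed, with_positions=False)
            stat, p = stats.chisquare(g.cell_totals)
            rejections += p < 0.01
        # expect about 1 rejection in 100 at alpha = 0.01
        assert rejections <= 6

    def test_edge_bias_depletes_periphery(self):
        comp = m.generate_composition(1, 20_000, dominance=0.5, seed=0)
        model = m.ClusteringModel(theta=50.0, edge_bias=0.5)
        per = peripheral_cells()
        inner = np.setdiff1d(np.arange(N_CELLS), per)
        per_mean = inner_mean = 0.0
        for seed in range(30):
            g = m.allocate_to_grid(comp, model, seed=seed, with_positions=False)
            per_mean += g.cell_totals[per].mean()
            inner_mean += g.cell_totals[inner].mean()
        assert per_mean < inner_mean


# ---------------------------------------------------------------------------
# biometrics


def _single_species_grid(counts):
    return m.GriddedSample.from_counts(np.asarray(counts)[:, None], sample_id="t")


NOISE_FREE = m.BiometricModel(
    default=m.SpeciesBiometrics(wet_mg_mean=2.0, wet_mg_cv=0.0, vol_ul_mean=8.0, vol_ul_cv=0.0),
    water_loss_sd=0.0,
    volume_graduation=0.0,
    balance_precision=0.0,
)


class TestAssignBiometrics:
    def test_empty_cells_read_zero(self):
        g = _single_species_grid([0] * 24 + [10])
        g = m.assign_biometrics(g, m.BiometricModel(), seed=0)
        assert np.all(g.cell_wet_mg[:24] == 0)
        assert np.all(g.cell_dry_mg[:24] == 0)
        assert np.all(g.cell_volume_ul[:24] == 0)

    def test_noise_free_limit_is_proportional(self):
        counts = np.arange(25) * 3
        g = m.assign_biometrics(_single_species_grid(counts), NOISE_FREE, seed=0)
        assert np.allclose(g.cell_wet_mg, counts * 2.0)
        assert np.allclose(g.cell_volume_ul, counts * 8.0)
        assert np.allclose(g.cell_dry_mg, g.cell_wet_mg * (1 - 0.273))

    def test_volume_rounds_up_to_graduation(self):
        model = m.BiometricModel(
            default=m.SpeciesBiometrics(vol_ul_cv=0.0, wet_mg_cv=0.0),
            volume_graduation=100.0,
        )
        g = m.assign_biometrics(_single_species_grid([7] + [0] * 24), model, seed=0)
        # 7 specimens x 8 ul = 56 ul, read as the next 100 ul graduation
        assert g.cell_volume_ul[0] == 100.0

    def test_tube_graduation_switches_with_volume(self):
        model = m.BiometricModel(default=m.SpeciesBiometrics(vol_ul_cv=0.0, wet_mg_cv=0.0))
        g = m.assign_biometrics(
            _single_species_grid([10, 500] + [0] * 23), model, seed=0
        )
        assert g.cell_volume_ul[0] % 100.0 == 0.0  # 80 ul -> 2 ml tube
        assert g.cell_volume_ul[1] % 500.0 == 0.0  # 4000 ul -> 15 ml tube

    @given(seed=st.integers(0, 2**20))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_dry_never_exceeds_wet(self, seed):
        comp = m.generate_composition(5, 700, dominance=0.6, seed=3)
        g = m.allocate_to_grid(comp, m.ClusteringModel(theta=2.0), seed=seed,
                               with_positions=False)
        g = m.assign_biometrics(g, m.BiometricModel(), seed=seed)
        assert np.all(g.cell_dry_mg <= g.cell_wet_mg + 1e-9)
        occupied = g.cell_totals > 0
        assert np.all(g.cell_volume_ul[occupied] > 0)


# ---------------------------------------------------------------------------
# random points


class TestPlacePoints:
    def test_bounds_and_count(self):
        pts = place_points(200, seed=0)
        assert pts.shape == (200, 2)
        assert (pts[:, 0] >= 0).all() and (pts[:, 0] <= SHEET_WIDTH_MM).all()
        assert (pts[:, 1] >= 0).all() and (pts[:, 1] <= SHEET_HEIGHT_MM).all()

    def test_determinism(self):
        assert np.array_equal(place_points(50, seed=9), place_points(50, seed=9))

    def test_uniform_over_cells(self):
        pts = place_points(100_000, seed=1)
        cells = cell_of(pts[:, 0], pts[:, 1])
        stat, p = stats.chisquare(np.bincount(cells, minlength=N_CELLS))
        assert p > 0.01

    def test_cell_geometry_constants(self):
        assert CELL_WIDTH_MM == pytest.approx(42.0)
        assert CELL_HEIGHT_MM == pytest.approx(59.4)
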