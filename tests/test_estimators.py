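"""Tests for the five subsampling estimators."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mosqsub as m

# ---------------------------------------------------------------------------
# area method


class TestAreaMethod:
    def test_full_sample_identity(self, study_samples):
        for g in study_samples[:5]:
            r = m.estimate_by_area(g, range(1, 26))
            assert r.est_total == pytest.approx(g.total)
            assert r.detected_species == len(g.composition.counts)
            assert r.est_mas_proportion == pytest.approx(
                g.composition.counts[g.composition.most_abundant()] / g.total
            )

    def test_stated_formula_arithmetic(self):
        # mean of {10, 20, 30, 40, 25} is 25; x 25 cells = 625
        counts = np.zeros(25, dtype=int)
        counts[:5] = [10, 20, 30, 40, 25]
        g = m.GriddedSample.from_counts(counts[:, None])
        r = m.estimate_by_area(g, [1, 2, 3, 4, 5])
        assert r.est_total == pytest.approx(625.0)

    def test_unbiased_over_all_subsets(self, toy4):
        # exhaustive enumeration: mean over all C(4,2) subsets equals the total
        ests = [
            m.estimate_by_area(toy4, cells).est_total
            for cells in itertools.combinations(range(1, 5), 2)
        ]
        assert np.mean(ests) == pytest.approx(40.0)

    @pytest.mark.parametrize("cells", [[], [0], [26], [1, 99]])
    def test_invalid_cells(self, study_samples, cells):
        with pytest.raises(ValueError):
            m.estimate_by_area(study_samples[0], cells)


# ---------------------------------------------------------------------------
# fraction-based methods


class TestFractionMethods:
    def test_fraction_arithmetic(self):
        assert m.estimate_by_fraction(100, 0.2, 1.0) == pytest.approx(500.0)
        assert m.estimate_by_fraction(77, 3.5, 3.5) == pytest.approx(77.0)

    def test_fraction_errors(self):
        with pytest.raises(m.UndefinedEstimateError):
            m.estimate_by_fraction(10, 0.0, 1.0)
        with pytest.raises(m.UndefinedEstimateError):
            m.estimate_by_fraction(10, -1.0, 1.0)
        with pytest.raises(ValueError):
            m.estimate_by_fraction(10, 2.0, 1.0)

    def test_full_sample_identity(self, study_samples):
        for measure in ("volume", "weight_fresh", "weight_dry"):
            r = m.estimate_cellbased(study_samples[0], range(1, 26), measure)
            assert r.est_total == pytest.approx(study_samples[0].total)

    def test_species_stats_match_area_on_same_cells(self, study_samples):
        cells = [1, 7, 13, 19, 25]
        for g in study_samples[:5]:
            area = m.estimate_by_area(g, cells)
            for measure in ("volume", "weight_fresh", "weight_dry"):
                r = m.estimate_cellbased(g, cells, measure)
                assert r.detected_species == area.detected_species
                assert r.est_mas_proportion == pytest.approx(area.est_mas_proportion)

    def test_noise_free_fraction_estimate_is_exact_everywhere(self):
        """With equal specimen masses the measure fraction IS the count
        fraction, so the estimate equals the true total for every subset."""
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 30, size=8)
        g = m.GriddedSample.from_counts(counts[:, None], sample_id="toy8")
        noise_free = m.BiometricModel(
            default=m.SpeciesBiometrics(wet_mg_cv=0.0, vol_ul_cv=0.0),
            water_loss_sd=0.0,
            volume_graduation=0.0,
            balance_precision=0.0,
        )
        g = m.assign_biometrics(g, noise_free, seed=0)
        total = g.total
        for r in range(1, 9):
            for cells in itertools.combinations(range(1, 9), r):
                for measure in ("volume", "weight_fresh", "weight_dry"):
                    est = m.estimate_cellbased(g, cells, measure).est_total
                    assert est == pytest.approx(total)

    def test_equal_count_grid_all_methods_agree(self):
        g = m.GriddedSample.from_counts(np.full((8, 1), 12))
        noise_free = m.BiometricModel(
            default=m.SpeciesBiometrics(wet_mg_cv=0.0, vol_ul_cv=0.0),
            water_loss_sd=0.0,
            volume_graduation=0.0,
            balance_precision=0.0,
        )
        g = m.assign_biometrics(g, noise_free, seed=0)
        for cells in itertools.combinations(range(1, 9), 3):
            area = m.estimate_by_area(g, cells).est_total
            for measure in ("volume", "weight_fresh", "weight_dry"):
                assert m.estimate_cellbased(g, cells, measure).est_total == pytest.approx(area)


# ---------------------------------------------------------------------------
# fixed-n selection


class TestSelectFixedN:
    def test_n_equals_total_returns_everything(self):
        comp = m.SpeciesComposition("s", {"a": 3, "b": 7})
        sel = m.select_fixed_n(comp, 10, seed=0)
        assert sel == {"a": 3, "b": 7}

    def test_n_out_of_range(self):
        comp = m.SpeciesComposition("s", {"a": 3})
        with pytest.raises(ValueError):
            m.select_fixed_n(comp, 4, seed=0)
        with pytest.raises(ValueError):
            m.select_fixed_n(comp, 0, seed=0)

    def test_nearest_point_matches_brute_force(self):
        # toy specimens and points with a known greedy assignment
        positions = pd.DataFrame(
            {
                "specimen_id": [0, 1, 2],
                "species": ["a", "b", "c"],
                "x_mm": [10.0, 50.0, 90.0],
                "y_mm": [10.0, 10.0, 10.0],
                "cell": [0, 1, 2],
            }
        )
        comp = m.SpeciesComposition("s", {"a": 1, "b": 1, "c": 1})
        g = m.GriddedSample(
            comp, ["a", "b", "c"], np.eye(3, dtype=int), positions=positions
        )
        points = np.array([[49.0, 10.0], [11.0, 10.0], [60.0, 10.0]])

        # independent brute force with exclusion, point order, lowest-id ties
        available = [0, 1, 2]
        expected = []
        for px, py in points:
            dists = [
                (np.hypot(positions.x_mm[i] - px, positions.y_mm[i] - py), i)
                for i in available
            ]
            d, i = min(dists)
            expected.append(positions.species[i])
            available.remove(i)

        sel = m.select_fixed_n(g, 3, mode="nearest_point", points=points, seed=0)
        assert sel == {sp: expected.count(sp) for sp in set(expected)}
        # point 1 takes b (nearest), point 2 takes a, point 3 is left with c
        assert expected == ["b", "a", "c"]

    def test_srswor_determinism(self):
        comp = m.SpeciesComposition("s", {"a": 50, "b": 30, "c": 20})
        assert m.select_fixed_n(comp, 40, seed=7) == m.select_fixed_n(comp, 40, seed=7)

    def test_srswor_detection_close_to_hypergeometric(self):
        # small-scale check; the full closed-form check is in the acceptance suite
        comp = m.SpeciesComposition("s", {"a": 199, "b": 1})
        hits = sum(
            "b" in m.select_fixed_n(comp, 100, seed=s) for s in range(1000)
        )
        assert abs(hits / 1000 - 0.5) < 3 * np.sqrt(0.25 / 1000)


# ---------------------------------------------------------------------------
# adjacent blocks


class TestAdjacentCells:
    @pytest.mark.parametrize(
        "fraction,expected",
        [
            (0.2, set(range(1, 6))),
            (0.4, set(range(1, 11))),
            (0.6, set(range(1, 16))),
            (0.8, set(range(1, 21))),
        ],
    )
    def test_whole_top_rows(self, fraction, expected):
        cells = m.adjacent_cells(fraction)
        assert set(cells) == expected
        assert len(cells) == round(fraction * 25)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            m.adjacent_cells(0.5)


# ---------------------------------------------------------------------------
# invariants


@given(seed=st.integers(0, 2**16), k=st.integers(1, 24))
@settings(max_examples=30, derandomize=True, deadline=None)
def test_detected_species_monotone_under_superset(seed, k):
    comp = m.generate_composition(7, 400, dominance=0.6, seed=2)
    g = m.allocate_to_grid(comp, m.ClusteringModel(theta=2.0), seed=seed,
                           with_positions=False)
    rng = np.random.default_rng(seed)
    cells = list(rng.choice(np.arange(1, 26), size=k, replace=False))
    extra = [c for c in range(1, 26) if c not in cells][0]
    small = m.estimate_by_area(g, cells)
    big = m.estimate_by_area(g, cells + [extra])
    assert big.detected_species >= small.detected_species
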