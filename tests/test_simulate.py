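import io as sio

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import luthy
from luthy.simulate import equilibrium_occupancy


class TestEquilibriumOccupancy:
    def test_symmetric_point_closed_form(self):
        # D = A = KD: the binding quadratic gives occupancy (3 - sqrt(5)) / 2
        for k in (1e-9, 1e-7, 1e-5):
            assert equilibrium_occupancy(k, k, k) == pytest.approx(
                (3.0 - np.sqrt(5.0)) / 2.0, rel=1e-12
            )

    def test_no_acceptor_means_no_complex(self):
        assert equilibrium_occupancy(1e-7, 0.0, 1e-8) == 0.0

    def test_stoichiometric_limit(self):
        # KD far below concentrations with acceptor >= donor: all donor bound
        occ = equilibrium_occupancy(1e-7, 1e-7, 1e-13)
        assert occ == pytest.approx(1.0, abs=1e-3)

    def test_invalid_kd_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_occupancy(1e-7, 1e-7, 0.0)

    @given(
        st.floats(1e-9, 1e-5), st.floats(1e-9, 1e-5),
        st.floats(1e-10, 1e-4), st.floats(1.1, 10.0),
    )
    @settings(deadline=None, max_examples=200)
    def test_monotone_in_kd_and_acceptor(self, d, a, kd, factor):
        base = equilibrium_occupancy(d, a, kd)
        assert equilibrium_occupancy(d, a, kd * factor) <= base + 1e-12
        assert equilibrium_occupancy(d, a * factor, kd) >= base - 1e-12

    def test_complex_never_exceeds_either_species(self):
        rng = np.random.default_rng(0)
        d = 10 ** rng.uniform(-9, -5, 200)
        a = 10 ** rng.uniform(-9, -5, 200)
        kd = 10 ** rng.uniform(-10, -4, 200)
        occ = equilibrium_occupancy(d, a, kd)
        assert np.all(occ >= 0) and np.all(occ <= 1)
        assert np.all(occ * d <= np.minimum(d, a) * (1 + 1e-9))


class TestScreenSimulation:
    def test_same_seed_gives_byte_identical_datasets(self):
        params = luthy.SimulationParams(seed=77, n_pairs=5)
        out = []
        for _ in range(2):
            ds, truth = luthy.simulate_screen(params)
            buf = sio.StringIO()
            luthy.write_measurements(ds, buf)
            out.append(buf.getvalue() + truth.to_csv())
        assert out[0] == out[1]

    def test_different_seeds_differ(self):
        a, _ = luthy.simulate_screen(luthy.SimulationParams(seed=1, n_pairs=3))
        b, _ = luthy.simulate_screen(luthy.SimulationParams(seed=2, n_pairs=3))
        assert not np.allclose(a.wells["swl_lum"], b.wells["swl_lum"])

    def test_truth_rows_one_to_one_with_pairs_and_replicates(self, small_screen):
        ds, truth = small_screen
        assert set(truth["pair_id"]) == set(ds.pairs)
        assert len(truth) == len(ds.pairs) * len(ds.experiments)

    def test_controls_and_references_present_per_replicate(self, small_screen):
        ds, _ = small_screen
        for exp, grp in ds.wells.groupby("experiment"):
            roles = grp["role"].value_counts()
            assert roles["interaction"] == len(ds.pairs)
            assert roles["control1"] == len(ds.pairs)
            assert roles["control2"] == len(ds.pairs)
            assert roles["panl"] >= 1 and roles["tandem"] >= 1

    def test_simulated_table_passes_its_own_validation(self, small_screen):
        ds, _ = small_screen
        buf = sio.StringIO()
        luthy.write_measurements(ds, buf)
        buf.seek(0)
        luthy.read_measurements(buf)  # must not raise

    def test_noiseless_negatives_score_exactly_zero(self, noiseless_screen):
        ds, truth = noiseless_screen
        scores = {s.pair_id: s for s in luthy.score_screen(ds)}
        for pair_id in truth.loc[~truth["label"], "pair_id"].unique():
            assert scores[pair_id].c_bret == pytest.approx(0.0, abs=1e-12)
            assert scores[pair_id].c_luc == pytest.approx(0.0, abs=1e-12)

    def test_crowding_inflates_bret_for_co_membrane_pairs_only(self):
        params = luthy.SimulationParams(
            seed=5, n_pairs=40, fraction_positive=0.0, noise_cv=0.0,
            fraction_membrane=0.5, crowding_occupancy=0.3,
        )
        ds, truth = luthy.simulate_screen(params)
        scores = {s.pair_id: s for s in luthy.score_screen(ds)}
        both = truth["donor_membrane"] & truth["acceptor_membrane"]
        assert both.any() and (~both).any()
        for row in truth[both].itertuples():
            assert scores[row.pair_id].c_bret > 0.01  # proximity artifact
            assert scores[row.pair_id].c_luc == pytest.approx(0.0, abs=1e-12)
        for row in truth[~both].itertuples():
            assert scores[row.pair_id].c_bret == pytest.approx(0.0, abs=1e-12)


class TestSaturationAndDoseSimulators:
    def test_half_max_ratio_closed_form(self):
        kd, donor = 3e-8, 1e-9
        grid = np.geomspace(0.25, 256, 10) * kd
        _, truth = luthy.simulate_saturation_series(kd, donor, grid)
        assert truth["half_max_ratio"] == pytest.approx(0.5 + kd / donor)

    def test_non_increasing_grid_rejected(self):
        with pytest.raises(ValueError):
            luthy.simulate_saturation_series(1e-8, 1e-9, [1e-8, 1e-8, 2e-8, 3e-8])

    def test_narrow_grid_flagged_by_fitter(self):
        kd, donor = 1e-8, 1e-9
        grid = np.array([1.0, 1.2, 1.5, 1.9]) * 1e-8  # < 2-fold span
        series, _ = luthy.simulate_saturation_series(kd, donor, grid)
        fit = luthy.fit_saturation(series)
        assert not fit.converged

    def test_dose_response_truth_direction(self):
        doses = np.concatenate([[0.0], np.geomspace(1e-10, 1e-6, 6)])
        _, _, truth = luthy.simulate_dose_response(0.9, 0.1, 1.0, 1e-8, doses)
        assert truth["direction"] == "inhibition"


class TestImageSimulation:
    def test_uniform_ratio_zero_shift_recovered_exactly(self):
        short, long_, _ = luthy.simulate_image_pair(
            (32, 32), 0.3, background=0.0, noise_sd=0.0
        )
        mask = short > 1.0
        np.testing.assert_allclose(long_[mask] / short[mask], 0.3, rtol=1e-12)

    def test_excessive_shift_rejected(self):
        with pytest.raises(ValueError):
            luthy.simulate_image_pair((16, 16), 0.3, shift=(8, 0))
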