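import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import luthy
from luthy.io import WellReading
from luthy.scoring import (
    FretChannels,
    compute_bret_ratio,
    compute_cf,
    compute_fret_efficiency,
    compute_luc_ratio,
    compute_pir_panl,
    correct_ratio,
)


def panl(swl=None, lwl=None, nl_in=None, nl_out=None):
    return WellReading("P1", "A1", "ref", "panl", swl_lum=swl, lwl_lum=lwl,
                       nl_in=nl_in, nl_out=nl_out)


class TestBleedThroughFactor:
    def test_mean_of_per_well_ratios(self):
        wells = [panl(swl=1000, lwl=200), panl(swl=1100, lwl=220)]
        assert compute_cf(wells) == pytest.approx(0.2)

    def test_zero_bleed_through(self):
        assert compute_cf([panl(swl=1000, lwl=0)]) == 0.0

    def test_no_reference_wells_is_an_error(self):
        with pytest.raises(ValueError, match="PA-NL"):
            compute_cf([])

    def test_zero_swl_is_an_error(self):
        with pytest.raises(ValueError):
            compute_cf([panl(swl=0, lwl=10)])


class TestBretRatio:
    @pytest.mark.parametrize(
        "lwl, swl, cf, expected",
        [(300, 1000, 0.2, 0.1), (100, 1000, 0.2, -0.1)],
    )
    def test_hand_arithmetic(self, lwl, swl, cf, expected):
        # negatives are retained, never clipped
        assert compute_bret_ratio((swl, lwl), cf) == pytest.approx(expected)

    def test_reference_scored_with_its_own_factor_gives_zero(self):
        wells = [panl(swl=1234.0, lwl=345.0)]
        cf = compute_cf(wells)
        assert compute_bret_ratio((1234.0, 345.0), cf) == pytest.approx(0.0, abs=1e-15)

    def test_zero_swl_is_an_error(self):
        with pytest.raises(ValueError):
            compute_bret_ratio((0.0, 10.0), 0.2)


class TestPrecipitationRatios:
    @pytest.mark.parametrize(
        "nl_out, nl_in, vf, expected",
        [(600, 1000, 3, 0.2), (0, 1000, 3, 0.0), (500, 1000, 1, 0.5)],
    )
    def test_pir_hand_arithmetic(self, nl_out, nl_in, vf, expected):
        wells = [panl(nl_in=nl_in, nl_out=nl_out)]
        assert compute_pir_panl(wells, volume_factor=vf) == pytest.approx(expected)

    def test_pir_zero_input_is_an_error(self):
        with pytest.raises(ValueError):
            compute_pir_panl([panl(nl_in=0, nl_out=10)])

    @pytest.mark.parametrize(
        "nl_out, nl_in, pir, expected",
        [(150, 500, 0.2, 0.5), (0, 500, 0.2, 0.0)],
    )
    def test_luc_hand_arithmetic(self, nl_out, nl_in, pir, expected):
        assert compute_luc_ratio((nl_in, nl_out), pir) == pytest.approx(expected)

    def test_reference_scored_against_its_own_pir_gives_one(self):
        wells = [panl(nl_in=730.0, nl_out=511.0)]
        pir = compute_pir_panl(wells)
        assert compute_luc_ratio((730.0, 511.0), pir) == pytest.approx(1.0, rel=1e-15)

    def test_zero_pir_is_an_error(self):
        with pytest.raises(ValueError):
            compute_luc_ratio((500, 100), 0.0)


class TestCorrection:
    @pytest.mark.parametrize(
        "value, c1, c2, expected",
        [(0.10, 0.02, 0.04, 0.06), (0.10, 0.0, 0.0, 0.10),
         (0.02, 0.05, 0.01, -0.03)],
    )
    def test_subtracts_larger_control(self, value, c1, c2, expected):
        assert correct_ratio(value, c1, c2) == pytest.approx(expected)

    def test_missing_control_named_in_error(self):
        with pytest.raises(ValueError, match="control2"):
            correct_ratio(0.1, 0.02, np.nan)

    @given(
        st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1),
        st.floats(-10, 10),
    )
    @settings(deadline=None, max_examples=50)
    def test_translation_equivariance(self, v, c1, c2, shift):
        base = correct_ratio(v, c1, c2)
        shifted = correct_ratio(v + shift, c1 + shift, c2 + shift)
        assert shifted == pytest.approx(base, abs=1e-9)


@given(st.floats(0.01, 100.0))
@settings(deadline=None, max_examples=50)
def test_common_channel_scaling_leaves_ratios_unchanged(k):
    # gain changes rescale all luminescence channels together
    swl, lwl, nl_in, nl_out = 1000.0, 300.0, 500.0, 150.0
    assert compute_bret_ratio((swl * k, lwl * k), 0.2) == pytest.approx(
        compute_bret_ratio((swl, lwl), 0.2)
    )
    assert compute_luc_ratio((nl_in * k, nl_out * k), 0.2) == pytest.approx(
        compute_luc_ratio((nl_in, nl_out), 0.2)
    )


class TestFretEfficiency:
    @pytest.mark.parametrize(
        "dd, aa, da, c_d, c_a, expected",
        [
            (100, 200, 50, 0.3, 0.05, 5.0),
            (100, 200, 0.3 * 100 + 0.05 * 200, 0.3, 0.05, 0.0),
            (123, 100, 10, 0.0, 0.0, 10.0),
        ],
    )
    def test_sensitized_emission(self, dd, aa, da, c_d, c_a, expected):
        ch = FretChannels(dd=dd, aa=aa, da=da, c_d=c_d, c_a=c_a)
        assert compute_fret_efficiency(ch) == pytest.approx(expected)

    def test_zero_acceptor_is_an_error(self):
        with pytest.raises(ValueError):
            compute_fret_efficiency(FretChannels(1, 0, 1, 0.1, 0.1))


class TestScreenScoring:
    def test_aggregate_is_mean_of_replicate_corrected_values(self, small_screen):
        ds, _ = small_screen
        scores = luthy.score_screen(ds)
        for s in scores:
            reps = [r.c_bret for r in s.replicates.values()]
            assert len(reps) == 2
            assert s.c_bret == pytest.approx(np.mean(reps))

    def test_zero_noise_reproduces_generative_expectations(self, noiseless_screen):
        ds, truth = noiseless_screen
        scores = {s.pair_id: s for s in luthy.score_screen(ds)}
        agg = luthy.expected_aggregate(truth)
        for row in agg.itertuples():
            s = scores[row.pair_id]
            assert s.c_bret == pytest.approx(row.expected_cbret, abs=1e-9)
            assert s.c_luc == pytest.approx(row.expected_cluc, abs=1e-9)

    def test_noninteracting_pair_scores_zero_without_noise(self, noiseless_screen):
        ds, truth = noiseless_screen
        scores = {s.pair_id: s for s in luthy.score_screen(ds)}
        negatives = truth.loc[~truth["label"], "pair_id"].unique()
        assert len(negatives) > 0
        for pair_id in negatives:
            assert scores[pair_id].c_bret == pytest.approx(0.0, abs=1e-12)
            assert scores[pair_id].c_luc == pytest.approx(0.0, abs=1e-12)

    def test_pair_without_controls_flagged_uncorrected(self, small_screen):
        ds, _ = small_screen
        wells = ds.wells
        pair0 = ds.interaction_pairs()[0]
        acceptor = ds.pairs[pair0][1]
        keep = ~((wells["role"] == "control1") & (wells["acceptor"] == acceptor))
        stripped = luthy.ScreenDataset(
            wells=wells[keep].reset_index(drop=True),
            constructs=ds.constructs, pairs=ds.pairs,
        )
        scores = {s.pair_id: s for s in luthy.score_screen(stripped)}
        assert scores[pair0].uncorrected
        with pytest.raises(ValueError, match="uncorrected"):
            luthy.call_interaction(scores[pair0])

    def test_replicate_reproducibility_at_5pct_noise(self, benchmark):
        _, _, scores, _ = benchmark
        x = [s.replicates["exp1"].c_bret for s in scores]
        y = [s.replicates["exp2"].c_bret for s in scores]
        r, p = luthy.replicate_correlation(x, y)
        assert r > 0.9 and p < 1e-6
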