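"""Shape-matching model: time warping, GMFR scaling, donor selection, fusion."""

import numpy as np
import pytest
from scipy import stats

from phenofuse import synth
from phenofuse.composite import EVI2Series
from phenofuse.phenocam import GCCCollection, GCCSeries
from phenofuse.ssmm import (
    BETA_GRID,
    LAMBDA_GRID,
    InvalidCandidateError,
    ScalingFactors,
    evaluate_match,
    fuse_series,
    gmfr_fit,
    select_best_match,
    warp_time,
)
from phenofuse.timegrid import N_STEPS, WINDOW_CENTER_DOYS


def ramp_donor():
    """Donor whose value equals its window-center DOY (linear ramp)."""
    return GCCSeries("ramp", (0, 0), 2019, WINDOW_CENTER_DOYS.astype(float))


class TestWarpTime:
    def test_identity(self):
        donor = ramp_donor()
        warped, valid = warp_time(donor, 1.0, 0.0)
        np.testing.assert_allclose(warped[valid], donor.values[valid])
        assert valid.all()

    def test_beta_shift_on_ramp(self):
        warped, valid = warp_time(ramp_donor(), 1.0, 3.0)
        t = WINDOW_CENTER_DOYS.astype(float)
        np.testing.assert_allclose(warped[valid], (t + 3.0)[valid])
        assert not valid[-1]  # t=365 maps beyond the donor domain

    def test_lambda_compresses_a_peak(self):
        t = WINDOW_CENTER_DOYS.astype(float)
        peak_doy = 182.0
        donor = GCCSeries("p", (0, 0), 2019, np.exp(-((t - peak_doy) ** 2) / 800))
        warped, valid = warp_time(donor, 1.1, 0.0)
        t_star = t[valid][np.argmax(warped[valid])]
        # peak when 1.1 * (t* + 0) = peak_doy, up to the 3-day grid
        assert t_star == pytest.approx(peak_doy / 1.1, abs=3.0)


class TestGMFR:
    def test_exact_line_recovered(self):
        x = np.linspace(0.3, 0.5, 30)
        a, b = gmfr_fit(x, 2 * x + 1)
        assert a == pytest.approx(2.0)
        assert b == pytest.approx(1.0)

    def test_negative_correlation_gives_negative_slope(self, rng):
        x = rng.normal(0, 1.0, 200)
        y = -2.0 * x + rng.normal(0, 0.1, 200)
        a, _ = gmfr_fit(x, y)
        assert a == pytest.approx(-np.std(y) / np.std(x))

    def test_constant_input_invalid(self):
        with pytest.raises(InvalidCandidateError):
            gmfr_fit(np.full(20, 0.4), np.linspace(0, 1, 20))

    def test_too_few_pairs_invalid(self):
        with pytest.raises(InvalidCandidateError):
            gmfr_fit(np.arange(5.0), np.arange(5.0))

    def test_slope_symmetry(self, rng):
        x = rng.normal(0, 1, 100)
        y = 0.7 * x + rng.normal(0, 0.3, 100)
        axy, _ = gmfr_fit(x, y)
        ayx, _ = gmfr_fit(y, x)
        assert axy * ayx == pytest.approx(1.0)


class TestEvaluateMatch:
    def test_identical_shape_perfect_score(self, matched_pair):
        donor, f, values, valid = matched_pair
        series = EVI2Series(2019, np.where(valid, values, np.nan))
        cand = evaluate_match(series, donor, f.lam, f.beta)
        assert cand.msd == pytest.approx(0.0, abs=1e-20)
        assert cand.r == pytest.approx(1.0)
        assert cand.factors.a == pytest.approx(f.a, abs=1e-9)
        assert cand.factors.b == pytest.approx(f.b, abs=1e-9)

    def test_independent_random_donor_is_insignificant(self, rng, truth122):
        series = EVI2Series(2019, truth122)
        n_significant = 0
        trials = 30
        for _ in range(trials):
            donor = GCCSeries("noise", (0, 0), 2019, rng.uniform(0.3, 0.5, N_STEPS))
            cand = evaluate_match(series, donor, 1.0, 0.0)
            if cand.r > 0.6 and cand.p <= 0.02:
                n_significant += 1
        assert n_significant <= 2

    def test_p_value_is_pearson_t_transform(self, rng, truth122):
        donor = GCCSeries("d", (0, 0), 2019, rng.uniform(0.3, 0.5, N_STEPS))
        series = EVI2Series(2019, truth122)
        cand = evaluate_match(series, donor, 1.0, 0.0)
        warped, valid = warp_time(donor, 1.0, 0.0)
        r_ref, p_ref = stats.pearsonr(warped[valid], truth122[valid])
        assert cand.r == pytest.approx(r_ref)
        assert cand.p == pytest.approx(p_ref)


def collection_with(donor, rng, params):
    return GCCCollection(
        [donor] + synth.make_decoy_donors(rng, 2019, shape_params=params)
    )


class TestSelectBestMatch:
    def test_generating_donor_and_factors_recovered(
        self, matched_pair, rng, single_cycle_params
    ):
        donor, f, values, _ = matched_pair
        deg = synth.degrade(values, 0.0, 0.6, rng)
        coll = collection_with(donor, rng, single_cycle_params)
        best = select_best_match(deg, coll)
        assert best.donor_id == donor.donor_id
        assert best.factors.lam == f.lam
        assert best.factors.beta == f.beta
        assert abs(best.factors.a - f.a) <= 1e-6
        assert abs(best.factors.b - f.b) <= 1e-6

    def test_uncorrelated_collection_yields_no_match(self, rng, truth122):
        series = EVI2Series(2019, truth122)
        donors = [
            GCCSeries("noise", (k, 0), 2019, rng.uniform(0.3, 0.5, N_STEPS))
            for k in range(3)
        ] + [GCCSeries("flat", (0, 0), 2019, np.full(N_STEPS, 0.4))]
        assert select_best_match(series, GCCCollection(donors)) is None

    def test_identical_donors_tie_break_deterministic(self, matched_pair):
        donor, f, values, valid = matched_pair
        series = EVI2Series(2019, np.where(valid, values, np.nan))
        twin = GCCSeries("camB", donor.grid_index, 2019, donor.values)
        best = select_best_match(series, GCCCollection([twin, donor]))
        assert best.donor_id == ("camA", (0, 0))  # lowest sorted donor id wins

    def test_invariant_under_collection_permutation(
        self, matched_pair, rng, single_cycle_params
    ):
        donor, f, values, _ = matched_pair
        deg = synth.degrade(values, 0.0, 0.5, rng)
        donors = [donor] + synth.make_decoy_donors(
            rng, 2019, shape_params=single_cycle_params
        )
        best_fwd = select_best_match(deg, GCCCollection(donors))
        best_rev = select_best_match(deg, GCCCollection(donors[::-1]))
        assert best_fwd.donor_id == best_rev.donor_id
        assert best_fwd.msd == best_rev.msd

    def test_selected_msd_is_minimal_among_qualifiers(
        self, matched_pair, rng, single_cycle_params
    ):
        donor, f, values, _ = matched_pair
        deg = synth.degrade(values, 0.01, 0.4, rng)
        coll = collection_with(donor, rng, single_cycle_params)
        best = select_best_match(deg, coll)
        for gcc in coll:
            for lam in LAMBDA_GRID:
                for beta in BETA_GRID:
                    try:
                        cand = evaluate_match(deg, gcc, lam, beta)
                    except InvalidCandidateError:
                        continue
                    if cand.r > 0.6 and cand.p <= 0.02:
                        assert best.msd <= cand.msd + 1e-15


class TestFuseSeries:
    def test_gap_free_input_unchanged(self, matched_pair):
        donor, f, values, valid = matched_pair
        series = EVI2Series(2019, np.where(valid, values, np.nan))
        best = evaluate_match(series, donor, f.lam, f.beta)
        fused = fuse_series(series, best, GCCCollection([donor]))
        np.testing.assert_array_equal(
            fused.values[valid], series.values[valid]
        )

    def test_single_gap_filled_by_hand_computation(self, matched_pair):
        donor, f, values, valid = matched_pair
        k = 60
        assert valid[k]
        gapped = values.copy()
        gapped[k] = np.nan
        series = EVI2Series(2019, gapped)
        best = evaluate_match(series, donor, f.lam, f.beta)
        fused = fuse_series(series, best, GCCCollection([donor]))
        t_k = WINDOW_CENTER_DOYS[k]
        donor_t = WINDOW_CENTER_DOYS.astype(float)
        by_hand = best.factors.a * np.interp(
            best.factors.lam * (t_k + best.factors.beta), donor_t, donor.values
        ) + best.factors.b
        assert fused.values[k] == pytest.approx(by_hand, abs=1e-12)

    def test_recovery_with_seventy_percent_gaps(
        self, matched_pair, rng, single_cycle_params
    ):
        donor, f, values, valid = matched_pair
        deg = synth.degrade(values, 0.0, 0.7, rng)
        coll = collection_with(donor, rng, single_cycle_params)
        best = select_best_match(deg, coll)
        fused = fuse_series(deg, best, coll)
        filled = deg.gap_mask & ~fused.gap_mask
        rmse = np.sqrt(np.mean((fused.values[filled] - values[filled]) ** 2))
        assert rmse <= 1e-8

    def test_unwarpable_steps_stay_gaps_and_are_reported(self, matched_pair):
        donor, f, values, valid = matched_pair
        gapped = np.where(valid, values, np.nan)
        gapped[~valid] = np.nan
        k_invalid = np.nonzero(~valid)[0]
        assert k_invalid.size  # construction leaves some unwarpable steps
        series = EVI2Series(2019, gapped)
        best = evaluate_match(series, donor, f.lam, f.beta)
        fused = fuse_series(series, best, GCCCollection([donor]))
        assert fused.gap_mask[k_invalid].all()
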