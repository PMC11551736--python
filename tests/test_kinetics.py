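"""Kinetic core: occurrence arithmetic, histogram fits, decomposition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nisp.kinetics import (
    DwellHistogram,
    build_occurrence_table,
    classify_processivity,
    decompose_linear,
    efficiency_ratio,
    fit_background,
    fit_gaussian_plus_background,
    make_histogram,
    occurrence_delta,
    select_bin_width,
)


def counts_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["condition", "n_total", "n_no_drop", "n_one_step", "n_two_step", "n_rejected"],
    )


class TestOccurrence:
    # printed control: 1611/324/120 of 2055; 10 nM condition: 54/22/186 of 262
    TABLE = counts_frame(
        [
            ("control", 2055, 1611, 324, 120, 0),
            ("10nM", 262, 54, 22, 186, 0),
        ]
    )

    def test_probabilities_rounded_to_one_decimal(self):
        occ = build_occurrence_table(self.TABLE, "control")
        row = occ.set_index("condition").loc["10nM"]
        assert (row["p_no_drop"], row["p_one_step"], row["p_two_step"]) == (20.6, 8.4, 71.0)

    def test_two_step_delta(self):
        occ = build_occurrence_table(self.TABLE, "control")
        row = occ.set_index("condition").loc["10nM"]
        assert row["delta_two_step"] == 65.2
        assert row["delta_one_step"] == -7.4

    def test_control_against_itself_is_zero(self):
        occ = build_occurrence_table(self.TABLE, "control")
        ctrl = occ.set_index("condition").loc["control"]
        assert (ctrl["delta_no_drop"], ctrl["delta_one_step"], ctrl["delta_two_step"]) == (0, 0, 0)

    def test_probabilities_sum_to_one_hundred(self):
        occ = build_occurrence_table(self.TABLE, "control")
        total = occ[["p_no_drop", "p_one_step", "p_two_step"]].sum(axis=1)
        assert np.all(np.abs(total - 100.0) <= 0.2)

    def test_missing_control_raises(self):
        with pytest.raises(ValueError):
            build_occurrence_table(self.TABLE, "absent")

    def test_delta_on_printed_probabilities(self):
        assert occurrence_delta(18.3, 5.8) == 12.5


class TestEfficiencyRatio:
    @pytest.mark.parametrize(
        "a, b, expected", [(23.2, 12.5, 1.9), (7.0, 7.0, 1.0), (65.2, 32.6, 2.0)]
    )
    def test_ratio(self, a, b, expected):
        assert efficiency_ratio(a, b) == expected

    def test_nonpositive_denominator(self):
        with pytest.raises(ValueError):
            efficiency_ratio(10.0, 0.0)


class TestBinWidth:
    def test_clean_gaussian_recovers_mean(self):
        rng = np.random.default_rng(30)
        x = rng.normal(3.2, 0.8, 200)
        w = select_bin_width(x)
        hist = make_histogram(x, w)
        from nisp.kinetics import _fit_plain_gaussian

        mu, *_ = _fit_plain_gaussian(hist.centers, hist.counts.astype(float), w)
        assert abs(mu - 3.2) < 0.1

    def test_identical_samples_give_smallest_width(self):
        assert select_bin_width(np.full(50, 2.0), candidate_widths=(0.5, 1.0, 2.0)) == 0.5

    def test_far_separated_bimodal_falls_back_to_fd(self):
        rng = np.random.default_rng(31)
        x = np.concatenate([rng.normal(2, 0.1, 100), rng.normal(80, 0.1, 100)])
        w = select_bin_width(x, candidate_widths=(0.1, 0.2, 0.4), stability_tol=1e-6)
        fd = np.histogram_bin_edges(x, bins="fd")
        assert w == pytest.approx(fd[1] - fd[0])

    def test_too_few_samples_raise(self):
        with pytest.raises(ValueError):
            select_bin_width(np.ones(10))


class TestBackgroundFit:
    def test_exact_quartic_recovered(self):
        coeffs = np.array([5.0, -0.3, 0.02, 1e-4, -2e-6])
        edges = np.arange(0.0, 20.5, 1.0)
        centers = 0.5 * (edges[:-1] + edges[1:])
        counts = np.polynomial.polynomial.polyval(centers, coeffs)
        hist = DwellHistogram(edges, counts, int(counts.sum()), 1.0)
        fit = fit_background(hist)
        assert np.allclose(fit.coeffs, coeffs, rtol=1e-6)

    def test_flat_histogram(self):
        edges = np.arange(0.0, 11.0, 1.0)
        hist = DwellHistogram(edges, np.full(10, 7.0), 70, 1.0)
        fit = fit_background(hist)
        assert fit.coeffs[0] == pytest.approx(7.0, abs=1e-6)
        assert np.allclose(fit.coeffs[1:], 0.0, atol=1e-6)

    def test_too_few_bins_raise(self):
        edges = np.arange(0.0, 6.0, 1.0)
        hist = DwellHistogram(edges, np.array([1.0, 2, 0, 0, 1]), 4, 1.0)
        with pytest.raises(ValueError):
            fit_background(hist)

    def test_mass_conservation_on_bleach_dwells(self):
        # quartic fitted to simulated enzyme-free dwell gaps integrates to
        # the event count within 5%
        from nisp.models import PhotophysicsModel
        from nisp.simulate import simulate_bleach_only_trace

        photo = PhotophysicsModel(noise_sd=0.0, k_bleach=0.004)
        gaps = []
        i = 0
        while len(gaps) < 1000:
            tr = simulate_bleach_only_trace(photo, [32, i], render=False)
            ev = [e for e in tr.truth if not e.censored]
            if len(ev) == 2:
                gaps.append(ev[1].time - ev[0].time)
            i += 1
        hist = make_histogram(np.array(gaps), 5.0)
        fit = fit_background(hist)
        mass = fit.predict(hist.centers).sum()
        assert abs(mass - 1000) / 1000 < 0.05


class TestGaussPlusBackground:
    @staticmethod
    def hist_from_fn(fn, edges):
        centers = 0.5 * (edges[:-1] + edges[1:])
        counts = fn(centers)
        return DwellHistogram(edges, counts, int(round(counts.sum())), edges[1] - edges[0])

    def test_pure_gaussian_recovered_exactly(self):
        edges = np.arange(0.0, 8.05, 0.25)
        hist = self.hist_from_fn(
            lambda t: 40.0 * np.exp(-0.5 * ((t - 3.2) / 0.8) ** 2), edges
        )
        fit = fit_gaussian_plus_background(hist, None)
        assert fit.mu == pytest.approx(3.2, abs=1e-6)
        assert fit.sigma == pytest.approx(0.8, abs=1e-6)

    def test_contaminated_sample_recovers_truth(self):
        # degradation peak over a bleach-like sloping background
        rng = np.random.default_rng(33)
        peak = rng.normal(3.26, 0.8, 200)
        bleach = rng.uniform(0, 40, 40)
        ctrl = rng.uniform(0, 40, 400)
        w = select_bin_width(np.concatenate([peak, bleach]))
        hist = make_histogram(np.concatenate([peak, bleach]), w)
        bg = fit_background(make_histogram(ctrl, w))
        for mode in ("joint", "fixed_shape"):
            fit = fit_gaussian_plus_background(hist, bg, mode=mode)
            assert abs(fit.mu - 3.26) < 0.3

    def test_background_subtraction_shifts_mean_by_a_few_percent(self):
        rng = np.random.default_rng(34)
        peak = rng.normal(3.2, 0.8, 300)
        bleach = rng.uniform(0, 30, 45)
        x = np.concatenate([peak, bleach])
        w = select_bin_width(x)
        hist = make_histogram(x, w)
        from nisp.kinetics import _fit_plain_gaussian

        mu_plain, *_ = _fit_plain_gaussian(hist.centers, hist.counts.astype(float), w)
        bg = fit_background(make_histogram(rng.uniform(0, 30, 450), w))
        mu_sub = fit_gaussian_plus_background(hist, bg).mu
        assert abs(mu_sub - mu_plain) / mu_sub < 0.10
        assert abs(mu_sub - 3.2) <= abs(mu_plain - 3.2) + 0.05


class TestDecomposeLinear:
    def test_printed_icy3_five_prime_slope(self):
        dec = decompose_linear([(8, 1.7), (13, 2.5), (18, 3.2), (28, 5.0)])
        assert round(dec.slope, 2) == 0.16

    def test_printed_icy3_three_prime_rate(self):
        dec = decompose_linear([(8, 5.0), (13, 7.6), (18, 10.4), (28, 14.9)])
        assert round(dec.rate, 1) == 2.0

    def test_exact_line(self):
        dec = decompose_linear([(S, 0.5 * S + 1.0) for S in (8, 13, 18, 28)])
        assert dec.slope == pytest.approx(0.5)
        assert dec.intercept == pytest.approx(1.0)
        assert dec.r_squared == pytest.approx(1.0)
        assert dec.rate == pytest.approx(2.0)

    def test_rate_slope_identity_and_delta_method(self):
        dec = decompose_linear([(8, 1.7), (13, 2.5), (18, 3.2), (28, 5.0)])
        assert dec.rate * dec.slope == 1.0
        assert dec.se_rate == pytest.approx(dec.se_slope / dec.slope**2)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(k=st.floats(0.1, 10.0))
    def test_scale_equivariance(self, k):
        pts = [(8, 1.7), (13, 2.5), (18, 3.2), (28, 5.0)]
        base = decompose_linear(pts)
        scaled = decompose_linear([(S, k * y) for S, y in pts])
        assert scaled.slope == pytest.approx(k * base.slope, rel=1e-9)
        assert scaled.intercept == pytest.approx(k * base.intercept, rel=1e-6, abs=1e-9)
        assert scaled.rate == pytest.approx(base.rate / k, rel=1e-9)

    def test_weighted_fit_matches_ols_for_equal_ses(self):
        pts = [(8, 1.7, 0.1), (13, 2.5, 0.1), (18, 3.2, 0.1), (28, 5.0, 0.1)]
        w = decompose_linear(pts, weighted=True)
        o = decompose_linear(pts)
        assert w.slope == pytest.approx(o.slope)
        assert w.intercept == pytest.approx(o.intercept)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            decompose_linear([(8, 1.0), (8, 2.0), (8, 3.0)])
        with pytest.raises(ValueError):
            decompose_linear([(8, 5.0), (13, 3.0), (18, 1.0)])  # negative slope


class TestProcessivityClassifier:
    def test_concentration_independent_t2_is_processive(self):
        call = classify_processivity([(1, 3.2), (5, 3.3), (10, 3.2)])
        assert call.classification == "processive"

    def test_decreasing_t2_is_distributive(self):
        call = classify_processivity([(1, 21.0), (5, 12.8), (10, 11.3), (50, 9.8)])
        assert call.classification == "distributive"
        assert call.slope < 0

    def test_constant_t2_is_processive(self):
        call = classify_processivity([(1, 5.0), (5, 5.0), (10, 5.0)])
        assert call.classification == "processive"

    def test_too_few_concentrations_raise(self):
        with pytest.raises(ValueError):
            classify_processivity([(1, 3.0), (10, 3.0)])
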