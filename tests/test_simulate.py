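"""Generator oracles: analytic means of the event model, censoring, rendering."""

import math

import numpy as np
import pytest
from scipy import stats

from nisp.models import (
    EnzymeKineticsModel,
    EnzymeMode,
    PhotophysicsModel,
    SubstrateSpec,
)
from nisp.simulate import (
    simulate_bleach_only_trace,
    simulate_distributive_trace,
    simulate_fret_trace,
    simulate_processive_trace,
)


def interdrop_truth(trace):
    ev = [e for e in trace.truth]
    assert len(ev) == 2
    return ev[1].time - ev[0].time


class TestProcessive:
    def test_no_event_case_is_flat_two_units(self, substrate18, clean_photo):
        enz = EnzymeKineticsModel(mode=EnzymeMode.INACTIVE)
        tr = simulate_processive_trace(substrate18, enz, clean_photo, seed=0)
        assert len(tr.intensities) == 1000
        assert np.all(tr.intensities == 2.0 * clean_photo.unit_intensity)
        assert tr.truth == []

    def test_mean_interdrop_matches_gamma_sum(self, clean_photo, fast_enzyme):
        # with no label-bond time the inter-drop dwell is Gamma(S, tau_bond):
        # mean 18 * 0.159 = 2.862 s, SE over 1e4 draws ~ 0.0067 s
        sub = SubstrateSpec(spacing=18, lead_nt=0)
        gaps = [
            interdrop_truth(
                simulate_processive_trace(sub, fast_enzyme, clean_photo, [5, i], render=False)
            )
            for i in range(10_000)
        ]
        se = math.sqrt(18) * 0.159 / 100
        assert abs(np.mean(gaps) - 2.862) < 3 * se

    def test_mean_interdrop_with_label_bond(self, clean_photo):
        # generator truth for the 18-nt iCy3 substrate: S*tau_bond + tau_label,
        # consistent with a measured dwell of ~3.2 s
        sub = SubstrateSpec(spacing=18, lead_nt=0)
        enz = EnzymeKineticsModel(
            mode=EnzymeMode.PROCESSIVE, tau_bond=0.16, tau_label=0.40, prebound=True
        )
        gaps = [
            interdrop_truth(
                simulate_processive_trace(sub, enz, clean_photo, [6, i], render=False)
            )
            for i in range(10_000)
        ]
        expected = 18 * 0.16 + 0.40
        sd = math.sqrt(18 * 0.16**2 + 0.40**2 / 4.0)
        assert abs(np.mean(gaps) - expected) < 3 * sd / 100
        assert round(expected, 1) == 3.3  # within the 3.2 +/- 0.8 band

    def test_rejects_blunt_duplex(self, clean_photo):
        from nisp.models import LabelType, OverhangEnd

        sub = SubstrateSpec(spacing=18, overhang_end=OverhangEnd.BLUNT_DUPLEX)
        enz = EnzymeKineticsModel(mode=EnzymeMode.PROCESSIVE)
        with pytest.raises(ValueError):
            simulate_processive_trace(sub, enz, clean_photo, 0)

    def test_intensity_levels_and_monotone_before_noise(self, substrate18, clean_photo):
        enz = EnzymeKineticsModel(
            mode=EnzymeMode.PROCESSIVE, tau_bond=0.16, tau_label=0.4, prebound=True
        )
        for i in range(20):
            tr = simulate_processive_trace(substrate18, enz, clean_photo, [7, i])
            levels = np.unique(tr.intensities)
            assert set(levels).issubset({0.0, 1000.0, 2000.0})
            assert np.all(np.diff(tr.intensities) <= 0)

    def test_censoring_flags(self, substrate18):
        photo = PhotophysicsModel(noise_sd=0.0, k_bleach=0.0, window=10.0)
        enz = EnzymeKineticsModel(
            mode=EnzymeMode.PROCESSIVE, tau_bond=2.0, tau_label=0.0, prebound=True
        )
        censored_seen = rendered_seen = False
        for i in range(50):
            tr = simulate_processive_trace(substrate18, enz, photo, [8, i])
            for ev in tr.truth:
                if ev.censored:
                    censored_seen = True
                    assert ev.time > photo.window
                    # censored events are not rendered
                else:
                    rendered_seen = True
                    assert ev.time <= photo.window
        assert censored_seen and rendered_seen


class TestDistributive:
    def test_instantaneous_cleavage_limit(self, substrate18, clean_photo):
        enz = EnzymeKineticsModel(mode=EnzymeMode.DISTRIBUTIVE, k_site=1e12)
        tr = simulate_distributive_trace(substrate18, enz, clean_photo, 0)
        assert np.all(tr.intensities[1:] == 0.0)

    def test_mean_gap_is_exponential(self, substrate18, clean_photo):
        # memorylessness: the gap between the two site cleavages is
        # Exponential(k_site); mean 21.0 s at k_site = 1/21
        enz = EnzymeKineticsModel(mode=EnzymeMode.DISTRIBUTIVE, k_site=1.0 / 21.0)
        gaps = [
            interdrop_truth(
                simulate_distributive_trace(substrate18, enz, clean_photo, [9, i], render=False)
            )
            for i in range(10_000)
        ]
        assert abs(np.mean(gaps) - 21.0) < 3 * 21.0 / 100

    def test_saturating_site_rate_monotone_in_concentration(self):
        rates = [
            EnzymeKineticsModel(
                mode=EnzymeMode.DISTRIBUTIVE, k_max=0.5, c_half=8.0, concentration=c
            ).site_rate()
            for c in (1.0, 5.0, 10.0, 50.0)
        ]
        assert all(a < b for a, b in zip(rates, rates[1:]))


class TestBleachOnly:
    def test_no_bleaching_means_no_drops(self):
        photo = PhotophysicsModel(noise_sd=0.0, k_bleach=0.0)
        tr = simulate_bleach_only_trace(photo, 0)
        assert tr.truth == [] and np.all(tr.intensities == 2000.0)

    def test_zero_drop_fraction_matches_survival_product(self):
        # per-fluorophore survival 0.9 over the window -> both survive 0.81
        k = -math.log(0.9) / 100.0
        photo = PhotophysicsModel(noise_sd=0.0, k_bleach=k)
        n_zero = sum(
            not any(not e.censored for e in simulate_bleach_only_trace(photo, [10, i], render=False).truth)
            for i in range(10_000)
        )
        se = math.sqrt(0.81 * 0.19 / 10_000)
        assert abs(n_zero / 10_000 - 0.81) < 3 * se

    def test_mixture_mode_reproduces_supplied_scenario_vector(self):
        probs = (0.784, 0.158, 0.058)
        photo = PhotophysicsModel(noise_sd=0.0, bleach_mixture=probs)
        counts = [0, 0, 0]
        n = 5000
        for i in range(n):
            tr = simulate_bleach_only_trace(photo, [11, i], render=False)
            counts[sum(1 for e in tr.truth if not e.censored)] += 1
        for k in range(3):
            se = math.sqrt(probs[k] * (1 - probs[k]) / n)
            assert abs(counts[k] / n - probs[k]) < 4 * se

    def test_all_causes_are_bleach(self, default_photo):
        for i in range(50):
            tr = simulate_bleach_only_trace(default_photo, [12, i], render=False)
            assert all(e.cause == "bleach" for e in tr.truth)


class TestFret:
    def test_static_half_efficiency_symmetric(self, clean_photo):
        tr = simulate_fret_trace("static", clean_photo, 0, level=0.5)
        assert np.allclose(tr.donor, tr.acceptor)

    def test_static_high_efficiency_mean(self):
        photo = PhotophysicsModel(noise_sd=1e-6)
        tr = simulate_fret_trace("static", photo, 1, level=0.85)
        eff = tr.acceptor / (tr.acceptor + tr.donor)
        assert abs(eff.mean() - 0.85) < 1e-4

    def test_mean_ramp_duration(self):
        photo = PhotophysicsModel(noise_sd=0.0, window=10.0)
        durs = [
            simulate_fret_trace("unwinding", photo, [13, i], t_unwind_mean=1.4).truth["t_unwind"]
            for i in range(10_000)
        ]
        se = 1.4 / math.sqrt(19.0) / 100  # gamma(19) sd = mean/sqrt(19)
        assert abs(np.mean(durs) - 1.4) < 3 * se

    def test_invalid_levels_raise(self, clean_photo):
        with pytest.raises(ValueError):
            simulate_fret_trace("unwinding", clean_photo, 0, low=0.8, high=0.3)
        with pytest.raises(ValueError):
            simulate_fret_trace("static", clean_photo, 0, level=1.5)


class TestConcentrationIndependence:
    def test_prebound_interdrop_distribution_independent_of_concentration(self, clean_photo):
        # prebound traversal times do not depend on bulk enzyme concentration
        sub = SubstrateSpec(spacing=18, lead_nt=0)

        def gaps(conc, base):
            enz = EnzymeKineticsModel(
                mode=EnzymeMode.PROCESSIVE, tau_bond=0.16, tau_label=0.4,
                prebound=True, concentration=conc,
            )
            return [
                interdrop_truth(
                    simulate_processive_trace(sub, enz, clean_photo, [base, i], render=False)
                )
                for i in range(1000)
            ]

        g1, g10 = gaps(1.0, 14), gaps(10.0, 15)
        assert stats.ks_2samp(g1, g10).pvalue > 0.01

    def test_inactive_equals_bleach_only(self, default_photo, substrate18):
        enz = EnzymeKineticsModel(mode=EnzymeMode.INACTIVE)
        for i in range(25):
            a = simulate_processive_trace(substrate18, enz, default_photo, [16, i])
            b = simulate_bleach_only_trace(default_photo, [16, i])
            assert np.array_equal(a.intensities, b.intensities)
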