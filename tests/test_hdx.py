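"""Peak-decay fitting, protection energies and EX1/EX2 classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermofold.hdx import (
    ExchangeRateEstimate,
    PeakDecayModel,
    PeakDecaySeries,
    classify_regime,
    count_survivors,
    fit_decay,
    protection_energy,
)


def make_series(times, heights, pD=6.5, idx=5, aa="L", normalized=True):
    return PeakDecaySeries(
        residue_index=idx, residue=aa, times=np.asarray(times, float),
        heights=np.asarray(heights, float), pD=pD, normalized=normalized,
    )


def estimate(k, ci=None, hyper=False, idx=1, aa="A"):
    ci = ci or (0.9 * k, 1.1 * k)
    return ExchangeRateEstimate(
        residue_index=idx, residue=aa, k_HDX=k, confidence_interval=ci,
        amplitude=1.0, fit_quality=0.0, hyperprotected=hyper,
    )


class TestFitDecay:
    def test_noiseless_exponential_recovered_to_machine_precision(self):
        t = np.arange(0.0, 500.0, 10.0)
        s = make_series(t, np.exp(-0.01 * t))
        est = fit_decay(s)
        assert est.k_HDX == pytest.approx(0.01, rel=1e-8)
        assert est.amplitude == pytest.approx(1.0, rel=1e-8)
        assert est.resolvable

    def test_two_point_closed_form_agreement(self):
        """Independent closed form: k = ln(y0/y1)/(t1-t0) from any two
        points of a noiseless decay must match the least-squares fit."""
        t = np.array([10.0, 30.0, 70.0, 150.0, 400.0])
        k_true = 3.3e-3
        y = 0.8 * np.exp(-k_true * t)
        k_closed = math.log(y[0] / y[-1]) / (t[-1] - t[0])
        est = fit_decay(make_series(t, y))
        assert est.k_HDX == pytest.approx(k_closed, rel=1e-8)

    def test_constant_heights_over_month_flagged_hyperprotected(self):
        """A peak flat over a month-long window (1-month persistence of
        the most protected amide) has no determinable rate, only the
        detection-limit bound ln(1/0.8)/t_max."""
        t = np.concatenate([np.arange(10.0, 1001.0, 10.0), [40320.0]])
        s = make_series(t, np.ones_like(t), idx=15, aa="I")
        est = fit_decay(s)
        assert est.hyperprotected
        assert not est.resolvable
        assert est.resolvable_lower_bound == pytest.approx(
            math.log(1 / 0.8) / (40320.0 - 10.0)
        )

    def test_noisy_recovery_median_within_five_percent(self):
        """100 seeded replicates at 2% multiplicative noise recover
        k = 0.005/min with a median error under 5%."""
        t = np.arange(10.0, 1001.0, 10.0)
        k_true = 0.005
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = np.exp(-k_true * t) * (1 + rng.normal(0, 0.02, t.shape))
            est = fit_decay(make_series(t, np.clip(y, 0, None)))
            errs.append(abs(est.k_HDX - k_true) / k_true)
        assert np.median(errs) < 0.05

    def test_sub_detection_series_is_unresolvable_not_hyperprotected(self):
        t = np.arange(10.0, 201.0, 10.0)
        s = make_series(t, np.full_like(t, 1e-4))
        est = fit_decay(s)
        assert not est.resolvable
        assert not est.hyperprotected
        assert np.isnan(est.k_HDX)

    def test_plateau_variant_recovers_offset_decay(self):
        t = np.arange(0.0, 600.0, 10.0)
        y = 0.7 * np.exp(-0.02 * t) + 0.3
        res = PeakDecayModel(make_series(t, y), plateau=True).fit()
        assert res.params[1] == pytest.approx(0.02, rel=1e-6)
        assert res.params[2] == pytest.approx(0.3, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            make_series([0.0, 10.0], [1.0, 0.5])

    def test_all_zero_heights_rejected(self):
        with pytest.raises(ValueError):
            fit_decay(make_series([0, 10, 20], [0.0, 0.0, 0.0]))

    def test_summary_mentions_rate_or_hyperprotection(self):
        t = np.arange(0.0, 500.0, 10.0)
        res = PeakDecayModel(make_series(t, np.exp(-0.01 * t))).fit()
        assert "k_HDX" in res.summary()


class TestProtectionEnergy:
    def test_unprotected_limit_is_zero_energy(self):
        pr = protection_energy(0.02, 0.02, 298.15)
        assert pr.K_unfold == pytest.approx(1.0)
        assert pr.dG_local == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "temperature,expected",
        [(298.15, 6.82), (323.15, 7.39)],
        ids=["25C", "50C"],
    )
    def test_frozen_values_for_1e5_equilibrium(self, temperature, expected):
        """-RT ln(1e-5) with R = 1.987e-3 kcal/mol/K, evaluated by hand."""
        pr = protection_energy(1e-5, 1.0, temperature)
        assert pr.dG_local == pytest.approx(expected, abs=5e-3)

    @settings(deadline=None, derandomize=True)
    @given(
        logk1=st.floats(-6, -1), logk2=st.floats(-6, -1)
    )
    def test_strictly_decreasing_in_K_unfold(self, logk1, logk2):
        k1, k2 = 10.0**logk1, 10.0**logk2
        if k1 == k2:
            return
        lo, hi = sorted((k1, k2))
        g_lo = protection_energy(lo, 1.0, 298.15).dG_local
        g_hi = protection_energy(hi, 1.0, 298.15).dG_local
        assert g_lo > g_hi

    def test_non_positive_rates_rejected(self):
        with pytest.raises(ValueError):
            protection_energy(0.0, 1.0, 298.15)
        with pytest.raises(ValueError):
            protection_energy(1.0, -2.0, 298.15)


class TestClassifyRegime:
    def test_tenfold_shift_is_ex2(self):
        rc = classify_regime(estimate(1e-3), estimate(1e-2), delta_pD=1.0)
        assert rc.label == "EX2"
        assert rc.log_rate_shift == pytest.approx(1.0)

    def test_equal_rates_are_ex1(self):
        rc = classify_regime(estimate(1e-3), estimate(1e-3), delta_pD=1.0)
        assert rc.label == "EX1"
        assert rc.log_rate_shift == pytest.approx(0.0)

    def test_half_shift_is_intermediate(self):
        rc = classify_regime(
            estimate(1e-3), estimate(10**-2.5), delta_pD=1.0, tolerance=0.3
        )
        assert rc.label == "intermediate"

    def test_ambiguous_overlap_breaks_to_intermediate(self):
        """With delta_pD smaller than twice the tolerance a shift can sit
        in both bands; the tie goes to intermediate."""
        rc = classify_regime(
            estimate(1e-3), estimate(10**-2.9), delta_pD=0.2, tolerance=0.3
        )
        assert rc.label == "intermediate"

    def test_hyperprotected_input_not_classifiable(self):
        hyper = ExchangeRateEstimate(
            residue_index=15, residue="I", k_HDX=float("nan"),
            confidence_interval=(float("nan"),) * 2, amplitude=1.0,
            fit_quality=0.0, hyperprotected=True,
        )
        with pytest.raises(ValueError):
            classify_regime(hyper, estimate(1e-2), delta_pD=1.0)


class TestCountSurvivors:
    def _set(self, ks, t=np.arange(10.0, 101.0, 10.0)):
        return [make_series(t, np.exp(-k * t), idx=i) for i, k in enumerate(ks, 1)]

    def test_zero_threshold_counts_everything(self):
        s = self._set([0.001, 0.05, 1.0])
        assert count_survivors(s, 50.0, threshold=0.0) == 3

    def test_empty_set_counts_zero(self):
        assert count_survivors([], 10.0, threshold=0.1) == 0

    def test_interpolation_between_grid_points(self):
        t = np.array([0.0, 100.0, 200.0])
        s = [make_series(t, np.array([1.0, 0.5, 0.0]))]
        assert count_survivors(s, 50.0, threshold=0.74) == 1
        assert count_survivors(s, 50.0, threshold=0.76) == 0

    def test_time_outside_range_rejected(self):
        s = self._set([0.01])
        with pytest.raises(ValueError):
            count_survivors(s, 1e6, threshold=0.1)

    def test_preset_reproduces_46_of_60_survivors(self, preset, preset_series):
        n = count_survivors(
            preset_series[6.5], preset.survivor_time_min, preset.survivor_threshold
        )
        assert n == 46


class TestPipelineRecovery:
    def test_dG_local_round_trip_through_fits(self, preset, preset_estimates, preset_krc):
        """Exchange simulated from per-residue dG_local, fitted, and
        converted back through K_unfold = k_HDX/k_rc must return the
        generating free energies (median error well under 5%)."""
        errs = []
        for idx, est in preset_estimates[6.5].items():
            if est.resolvable:
                pr = protection_energy(est.k_HDX, preset_krc[idx], preset.hdx.temperature)
                truth = preset.hdx.dG_local[idx]
                errs.append(abs(pr.dG_local - truth) / truth)
        assert len(errs) >= 40
        assert np.median(errs) < 0.05

    def test_ex2_simulated_data_classified_ex2(self, preset_estimates):
        labels = []
        lo, hi = preset_estimates[5.5], preset_estimates[6.5]
        for idx in lo:
            if lo[idx].resolvable and hi[idx].resolvable:
                labels.append(classify_regime(lo[idx], hi[idx], 1.0).label)
        assert len(labels) >= 40
        assert labels.count("EX2") / len(labels) >= 0.95

    def test_ex1_simulated_data_classified_ex1(self):
        from thermofold.simulate import HDXSimulationSpec, simulate_hdx

        positions = list(range(2, 22))
        spec = HDXSimulationSpec(
            sequence="A" * 30,
            dG_local={},
            mechanism_ex1=frozenset(positions),
            k_unfold={p: 10 ** np.random.default_rng(p).uniform(-3.5, -2) for p in positions},
            noise_sd=0.02,
            seed=4,
        )
        series = simulate_hdx(spec)
        fits = {
            pD: {s.residue_index: fit_decay(s) for s in lst}
            for pD, lst in series.items()
        }
        labels = [
            classify_regime(fits[5.5][p], fits[6.5][p], 1.0).label
            for p in positions
            if fits[5.5][p].resolvable and fits[6.5][p].resolvable
        ]
        assert len(labels) >= 15
        assert labels.count("EX1") / len(labels) >= 0.95
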