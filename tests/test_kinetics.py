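"""1:1 kinetics: closed-form model, global fitting, fold triage."""

import numpy as np
import pandas as pd
import pytest

from macropan.kinetics import (
    Sensorgram,
    classify_alascan,
    fit_global_1to1,
    fold_selectivity,
    model_1to1,
    sensorgrams_from_frame,
    sensorgrams_to_frame,
    simulate_sensorgrams,
)

KON, KOFF, RMAX = 2.0e5, 0.027, 1.0     # K_D = 135 nM
CONCS = [25e-9, 50e-9, 100e-9, 200e-9, 400e-9]


class TestModel:
    def test_plateau_is_half_rmax_at_kd(self):
        kd = KOFF / KON
        r = model_1to1(1e7, kd, KON, KOFF, RMAX, t_assoc=0.0)
        assert r == pytest.approx(RMAX / 2, rel=1e-9)

    def test_zero_at_association_start(self):
        assert model_1to1(10.0, 1e-7, KON, KOFF, RMAX, t_assoc=10.0) == 0.0

    def test_slow_dissociation_plateaus(self):
        r_td = model_1to1(400.0, 1e-7, KON, 1e-12, RMAX, t_assoc=0.0, t_dissoc=400.0)
        later = model_1to1(5000.0, 1e-7, KON, 1e-12, RMAX, t_assoc=0.0, t_dissoc=400.0)
        assert later == pytest.approx(r_td, rel=1e-6)

    def test_association_monotone_up_dissociation_monotone_down(self):
        t = np.linspace(0, 900, 4000)
        r = model_1to1(t, 1e-7, KON, KOFF, RMAX, t_assoc=100.0, t_dissoc=500.0)
        assoc = r[(t >= 100) & (t <= 500)]
        dissoc = r[t >= 500]
        assert np.all(np.diff(assoc) >= 0)
        assert np.all(np.diff(dissoc) <= 0)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            model_1to1(1.0, 1e-7, -KON, KOFF, RMAX)


class TestSimulation:
    def test_noiseless_trace_equals_model(self):
        grams = simulate_sensorgrams(KON, KOFF, RMAX, CONCS, noise_sd=0.0)
        g = grams[0]
        expected = model_1to1(g.time, g.concentration, KON, KOFF, RMAX,
                              g.t_assoc, g.t_dissoc)
        np.testing.assert_allclose(g.response, expected)

    def test_seeded_noise_reproducible(self):
        a = simulate_sensorgrams(KON, KOFF, RMAX, CONCS, noise_sd=0.02, seed=5)
        b = simulate_sensorgrams(KON, KOFF, RMAX, CONCS, noise_sd=0.02, seed=5)
        for ga, gb in zip(a, b):
            np.testing.assert_array_equal(ga.response, gb.response)

    def test_noise_mean_zero_within_3se(self):
        grams = simulate_sensorgrams(KON, KOFF, RMAX, CONCS, noise_sd=0.02, seed=7)
        resid = np.concatenate([
            g.response - model_1to1(g.time, g.concentration, KON, KOFF, RMAX,
                                    g.t_assoc, g.t_dissoc)
            for g in grams
        ])
        se = 0.02 / np.sqrt(len(resid))
        assert abs(resid.mean()) < 3 * se

    def test_requires_two_concentrations(self):
        with pytest.raises(ValueError):
            simulate_sensorgrams(KON, KOFF, RMAX, [1e-7])


class TestGlobalFit:
    def test_noiseless_recovery_exact(self):
        grams = simulate_sensorgrams(KON, KOFF, RMAX, CONCS, noise_sd=0.0)
        fit = fit_global_1to1(grams)
        assert fit.k_on == pytest.approx(KON, rel=1e-3)
        assert fit.k_off == pytest.approx(KOFF, rel=1e-3)
        assert fit.r_max == pytest.approx(RMAX, rel=1e-3)
        assert fit.k_d == pytest.approx(KOFF / KON, rel=1e-3)

    def test_kd_equals_quotient_exactly(self):
        grams = simulate_sensorgrams(KON, KOFF, RMAX, CONCS, noise_sd=0.01, seed=1)
        fit = fit_global_1to1(grams)
        assert fit.k_d == fit.k_off / fit.k_on

    def test_recovery_within_5pct_across_seeds(self):
        """2% noise, 5 concentrations: k_on, k_off, K_D within 5% on every
        one of 20 seeds."""
        for seed in range(20):
            grams = simulate_sensorgrams(KON, KOFF, RMAX, CONCS,
                                         noise_sd=0.02, seed=seed)
            fit = fit_global_1to1(grams)
            assert fit.k_on == pytest.approx(KON, rel=0.05)
            assert fit.k_off == pytest.approx(KOFF, rel=0.05)
            assert fit.k_d == pytest.approx(KOFF / KON, rel=0.05)

    def test_log_kd_bias_small_at_1pct_noise(self):
        logs = []
        for seed in range(20):
            grams = simulate_sensorgrams(KON, KOFF, RMAX, CONCS,
                                         noise_sd=0.01, seed=seed)
            logs.append(np.log(fit_global_1to1(grams).k_d))
        bias = abs(np.mean(logs) - np.log(KOFF / KON))
        assert bias < 0.02 * abs(np.log(KOFF / KON))

    def test_invariant_to_trace_order_and_time_shift(self):
        grams = simulate_sensorgrams(KON, KOFF, RMAX, CONCS, noise_sd=0.01, seed=3)
        base = fit_global_1to1(grams)
        reordered = fit_global_1to1(grams[::-1])
        shifted = fit_global_1to1([
            Sensorgram(g.concentration, g.time + 500.0, g.response,
                       g.t_assoc + 500.0, g.t_dissoc + 500.0)
            for g in grams
        ])
        for other in (reordered, shifted):
            assert other.k_d == pytest.approx(base.k_d, rel=1e-6)

    def test_heterogeneous_data_raises_rmse(self):
        """Traces generated from a two-site mixture misfit the 1:1 model,
        with clearly elevated RMSE over a true-1:1 fit at equal noise."""
        noise = 0.005
        true_grams = simulate_sensorgrams(KON, KOFF, RMAX, CONCS,
                                          noise_sd=noise, seed=9)
        hetero = []
        for g in simulate_sensorgrams(KON, KOFF, 0.5, CONCS, noise_sd=noise, seed=9):
            # second site with near-irreversible dissociation: biphasic decay
            second = model_1to1(g.time, g.concentration, 2e4, 1e-4, 0.5,
                                g.t_assoc, g.t_dissoc)
            hetero.append(Sensorgram(g.concentration, g.time,
                                     g.response + second, g.t_assoc, g.t_dissoc))
        rmse_true = fit_global_1to1(true_grams).rmse
        rmse_hetero = fit_global_1to1(hetero).rmse
        assert rmse_hetero > 3 * rmse_true

    def test_identical_concentrations_rejected(self):
        grams = simulate_sensorgrams(KON, KOFF, RMAX, [1e-7, 1.2e-7], noise_sd=0.0)
        with pytest.raises(ValueError):
            fit_global_1to1(grams)

    def test_csv_dialect_round_trip(self):
        grams = simulate_sensorgrams(KON, KOFF, RMAX, CONCS, noise_sd=0.01, seed=2)
        frame = sensorgrams_to_frame(grams)
        back = sensorgrams_from_frame(frame)
        assert len(back) == len(grams)
        for ga, gb in zip(grams, back):
            assert gb.concentration == ga.concentration
            np.testing.assert_allclose(gb.response, ga.response)


class TestTriage:
    @pytest.mark.parametrize(
        "off,target,expected",
        [(639.2e-9, 136e-9, 4.7), (272e-9, 136e-9, 2.0), (136e-9, 136e-9, 1.0)],
    )
    def test_fold_selectivity_ratio(self, off, target, expected):
        assert fold_selectivity(off, target) == pytest.approx(expected, rel=0.001)

    def test_fold_selectivity_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            fold_selectivity(0.0, 1e-7)

    @pytest.mark.parametrize(
        "fold,expected",
        [(10.0, "essential"), (9.0, "intermediate"), (5.0, "intermediate"),
         (4.0, "mild"), (3.0, "mild"), (2.0, "mild"), (1.0, "neutral"),
         (0.5, "neutral")],
    )
    def test_fold_class_boundaries(self, fold, expected):
        parent = 136e-9
        table = classify_alascan(parent, {"V": parent * fold})
        assert table["class"].iloc[0] == expected
        assert table.fold_change.iloc[0] == pytest.approx(fold)

    def test_missing_variant_flagged_not_determined(self):
        table = classify_alascan(136e-9, {"W3A": None, "F4A": np.nan})
        assert (table["class"] == "not-determined").all()

    def test_alascan_pattern_from_simulated_fits(self):
        """End-to-end: fit parent and variants from synthetic sensorgrams,
        then classify; an engineered >9-fold variant lands 'essential'."""
        parent = fit_global_1to1(
            simulate_sensorgrams(KON, KOFF, RMAX, CONCS, noise_sd=0.01, seed=0)
        ).k_d
        variants = {}
        for name, factor in [("W3A", 12.0), ("T9A", 3.0), ("S2A", 1.1)]:
            concs = [c * factor for c in CONCS]
            grams = simulate_sensorgrams(KON / factor, KOFF, RMAX, concs,
                                         noise_sd=0.01, seed=1)
            variants[name] = fit_global_1to1(grams).k_d
        table = classify_alascan(parent, variants).set_index("variant")
        assert table.loc["W3A", "class"] == "essential"
        assert table.loc["T9A", "class"] == "mild"
        assert table.loc["S2A", "class"] == "neutral"
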