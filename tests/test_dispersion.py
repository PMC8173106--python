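"""Dispersion and R1 fitting: conversion, recovery, selection, classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from allokit.exchange import ExchangeParams, FieldContext, r2eff_carver_richards
from allokit.dispersion import (
    DispersionCurve,
    DispersionModel,
    RelaxationSeries,
    classify_kex,
    compute_r2eff,
    detect_fast_component,
    fit_global,
    fit_r1,
    fit_residue,
    rex_metric,
    select_model,
)
from conftest import make_curves

NU = np.arange(50.0, 1001.0, 50.0)


class TestComputeR2eff:
    def test_identity_intensity_gives_zero(self):
        r2, _ = compute_r2eff(100.0, 100.0, 0.04, 1.0)
        assert r2 == 0.0

    def test_one_e_fold_decay(self):
        r2, _ = compute_r2eff(100.0 * math.exp(-1), 100.0, 0.04, 1.0)
        assert r2 == pytest.approx(25.0, rel=1e-12)

    def test_error_propagation_is_linear(self):
        i = 100.0 * math.exp(-2)
        r2, s1 = compute_r2eff(i, 100.0, 0.05, 1.0)
        _, s2 = compute_r2eff(i, 100.0, 0.05, 2.0)
        assert r2 == pytest.approx(40.0, rel=1e-12)
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    def test_nonpositive_intensity_flagged_not_raised(self):
        assert compute_r2eff(-1.0, 100.0, 0.04, 1.0) is None

    def test_bad_reference_raises(self):
        with pytest.raises(ValueError):
            compute_r2eff(1.0, 0.0, 0.04, 1.0)


class TestRexMetric:
    def test_flat_curve(self, field_900, nu_grid):
        c = DispersionCurve(
            "A1", field_900, nu_grid,
            np.full(nu_grid.size, 10.0), np.full(nu_grid.size, 0.3),
        )
        r2_50, d_r2 = rex_metric(c)
        assert r2_50 == 10.0 and d_r2 == 0.0

    def test_matches_oracle_at_50hz(self, field_900, nu_grid):
        from allokit.exchange import r2eff_bloch_mcconnell

        truth = ExchangeParams(10.0, 1500.0, 0.05, 2.0)
        clean = r2eff_bloch_mcconnell(truth, nu_grid, field_900)
        c = DispersionCurve("A1", field_900, nu_grid, clean,
                            np.full(nu_grid.size, 0.3))
        r2_50, _ = rex_metric(c, nu_low=50.0)
        assert r2_50 == pytest.approx(
            r2eff_bloch_mcconnell(truth, 50.0, field_900), rel=1e-12
        )

    def test_larger_minor_population_gives_larger_delta_r2(self, field_900, nu_grid):
        deltas = []
        for pb in (0.02, 0.05):
            truth = ExchangeParams(10.0, 1500.0, pb, 2.0)
            from allokit.exchange import r2eff_bloch_mcconnell

            clean = r2eff_bloch_mcconnell(truth, nu_grid, field_900)
            c = DispersionCurve("A1", field_900, nu_grid, clean,
                                np.full(nu_grid.size, 0.3))
            deltas.append(rex_metric(c)[1])
        assert deltas[1] > deltas[0]

    def test_empty_curve_rejected(self, field_900):
        with pytest.raises(ValueError):
            DispersionCurve("A1", field_900, np.array([]), np.array([]), np.array([]))


class TestFitResidue:
    def test_flat_noisy_data_too_low_to_fit(self, nu_grid):
        truth = ExchangeParams(10.0, 1500.0, 0.0, 0.0)
        curves = make_curves(truth, seed=0, nu_grid=nu_grid)
        res = fit_residue(curves)
        assert res.status == "too_low_to_fit"
        assert "kex" not in res.params

    def test_noiseless_closed_form_self_consistency(self, field_900, nu_grid):
        truth = ExchangeParams(11.0, 1200.0, 0.04, 1.8)
        clean = r2eff_carver_richards(truth, nu_grid, field_900)
        c = DispersionCurve("A1", field_900, nu_grid, clean,
                            np.full(nu_grid.size, 0.05))
        res = fit_residue([c])
        assert res.status == "ok"
        assert res.params["kex"] == pytest.approx(1200.0, rel=1e-3)
        assert res.params["dw_ppm"] == pytest.approx(1.8, rel=1e-3)
        assert res.single_field_degenerate

    def test_two_field_parameter_recovery(self, nu_grid):
        """Median over seeded replicates: kex within 15%, p_b dw^2 within 20%."""
        truth = ExchangeParams(10.0, 1500.0, 0.03, 2.0)
        kex_err, amp_err = [], []
        for seed in range(20):
            res = fit_residue(make_curves(truth, seed=100 + seed, nu_grid=nu_grid))
            assert res.status == "ok"
            kex_err.append(abs(res.params["kex"] - truth.kex) / truth.kex)
            amp_true = truth.p_b * truth.delta_omega_ppm**2
            amp_fit = res.params["p_b"] * res.params["dw_ppm"] ** 2
            amp_err.append(abs(amp_fit - amp_true) / amp_true)
        assert np.median(kex_err) <= 0.15
        assert np.median(amp_err) <= 0.20

    def test_too_few_points_rejected(self, field_900):
        c = DispersionCurve("A1", field_900, np.array([50.0, 100.0, 200.0]),
                            np.full(3, 10.0), np.full(3, 0.3))
        with pytest.raises(ValueError):
            DispersionModel([c])


class TestSelectModel:
    def test_flat_truth_calibration(self, nu_grid):
        """Type-I error of the AICc rule at sigma = 0.3: <= 5 in 100."""
        truth = ExchangeParams(10.0, 1500.0, 0.0, 0.0)
        flat_wins = sum(
            select_model(make_curves(truth, seed=200 + s, nu_grid=nu_grid,
                                     fields=(900.0,)))[0] == "flat"
            for s in range(30)
        )
        assert flat_wins >= math.ceil(0.95 * 30)

    def test_strong_exchange_always_selected(self, nu_grid):
        truth = ExchangeParams(10.0, 1500.0, 0.05, 2.5)  # Rex ~ 10 /s
        for s in range(20):
            chosen, _ = select_model(
                make_curves(truth, seed=300 + s, nu_grid=nu_grid, fields=(900.0,))
            )
            assert chosen == "carver_richards"

    def test_equal_fit_quality_prefers_fewer_parameters(self, field_900, nu_grid):
        """On exactly flat data the exchange model cannot beat flat by AICc."""
        c = DispersionCurve("A1", field_900, nu_grid,
                            np.full(nu_grid.size, 10.0), np.full(nu_grid.size, 0.3))
        chosen, fits = select_model([c])
        assert chosen == "flat"
        if fits["carver_richards"].status == "ok":
            assert fits["flat"].aicc < fits["carver_richards"].aicc


class TestGlobalFit:
    def test_shared_kex_recovered(self, nu_grid):
        groups = {}
        for i, dw in enumerate((1.0, 2.0, 3.0)):
            truth = ExchangeParams(10.0, 1500.0, 0.04, dw)
            groups[f"G{i}"] = make_curves(truth, seed=400 + i, nu_grid=nu_grid,
                                          residue_id=f"G{i}")
        res = fit_global(groups, shared=("kex", "p_b"))
        assert res.kex == pytest.approx(1500.0, rel=0.10)
        for i, dw in enumerate((1.0, 2.0, 3.0)):
            assert res.dw_ppm(f"G{i}") == pytest.approx(dw, rel=0.15)

    def test_single_member_group_matches_individual_fit(self, nu_grid):
        truth = ExchangeParams(10.0, 1500.0, 0.04, 2.0)
        curves = make_curves(truth, seed=410, nu_grid=nu_grid)
        solo = fit_global({"X1": curves}, shared=("kex",))
        indiv = fit_residue(curves)
        assert solo.kex == pytest.approx(indiv.params["kex"], rel=1e-3)

    def test_heterogeneous_group_detected_by_chi2(self, nu_grid):
        homo = {
            f"H{i}": make_curves(ExchangeParams(10.0, 1500.0, 0.04, 2.0),
                                 seed=420 + i, nu_grid=nu_grid, residue_id=f"H{i}")
            for i in range(2)
        }
        hetero = {
            "F": make_curves(ExchangeParams(10.0, 800.0, 0.04, 2.0),
                             seed=430, nu_grid=nu_grid, residue_id="F"),
            "S": make_curves(ExchangeParams(10.0, 4000.0, 0.04, 2.0),
                             seed=431, nu_grid=nu_grid, residue_id="S"),
        }
        assert (fit_global(hetero).reduced_chi2
                > fit_global(homo).reduced_chi2)

    def test_unfittable_member_excluded(self, nu_grid):
        groups = {
            "OK": make_curves(ExchangeParams(10.0, 1500.0, 0.04, 2.0),
                              seed=440, nu_grid=nu_grid, residue_id="OK"),
            "LOW": make_curves(ExchangeParams(10.0, 1500.0, 0.0, 0.0),
                               seed=441, nu_grid=nu_grid, residue_id="LOW"),
        }
        res = fit_global(groups)
        assert res.excluded == ["LOW"]


class TestClassifyKex:
    @pytest.mark.parametrize(
        "kex,label",
        [
            (1500.0, "intermediate_yellow"),  # the shared active-site rate
            (999.0, "slow_blue"),
            (1000.0, "intermediate_yellow"),
            (3000.0, "intermediate_yellow"),
            (3000.0001, "fast_red"),
            (3500.0, "fast_red"),
            (0.0, "slow_blue"),
        ],
    )
    def test_boundaries(self, kex, label):
        assert classify_kex(kex) == label

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_kex(-1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(kex=st.floats(0.0, 1e6, allow_nan=False))
    def test_total_partition(self, kex):
        assert classify_kex(kex) in {"slow_blue", "intermediate_yellow", "fast_red"}


class TestDetectFastComponent:
    def test_elevated_plateau_flagged(self, field_900, nu_grid):
        clean = r2eff_carver_richards(
            ExchangeParams(10.0, 1500.0, 0.04, 2.0), nu_grid, field_900
        ) + 5.0  # constant plateau offset: a second, faster process
        c = DispersionCurve("A1", field_900, nu_grid, clean,
                            np.full(nu_grid.size, 0.3))
        res = fit_residue([c])
        assert res.status == "ok"
        assert detect_fast_component(res, baseline_r2=10.0)

    def test_threshold_arithmetic(self, field_900, nu_grid):
        clean = r2eff_carver_richards(
            ExchangeParams(10.0, 1500.0, 0.04, 2.0), nu_grid, field_900
        )
        c = DispersionCurve("A1", field_900, nu_grid, clean,
                            np.full(nu_grid.size, 0.3))
        res = fit_residue([c])
        assert not detect_fast_component(res, baseline_r2=10.0)
        assert detect_fast_component(res, baseline_r2=2.0)

    def test_missing_baseline_rejected(self, field_900, nu_grid):
        clean = r2eff_carver_richards(
            ExchangeParams(10.0, 1500.0, 0.04, 2.0), nu_grid, field_900
        )
        c = DispersionCurve("A1", field_900, nu_grid, clean,
                            np.full(nu_grid.size, 0.3))
        res = fit_residue([c])
        with pytest.raises(ValueError):
            detect_fast_component(res, baseline_r2=None)


class TestR1:
    DELAYS = np.array([0.01, 0.1, 0.3, 0.5, 0.7, 0.9, 1.1])

    def test_noiseless_recovery(self):
        y = 3.0 * np.exp(-1.2 * self.DELAYS)
        res = fit_r1(RelaxationSeries("A1", self.DELAYS, y))
        assert res.status == "ok"
        assert res.r1 == pytest.approx(1.2, abs=1e-6)

    def test_noisy_mean_recovery_within_3pct(self):
        rng = np.random.default_rng(5)
        fitted = []
        for _ in range(50):
            y = np.exp(-1.2 * self.DELAYS) * (1 + rng.normal(0, 0.02, 7))
            res = fit_r1(RelaxationSeries("A1", self.DELAYS, y))
            fitted.append(res.r1)
        assert np.mean(fitted) == pytest.approx(1.2, rel=0.03)

    def test_constant_intensities_fail(self):
        res = fit_r1(RelaxationSeries("A1", self.DELAYS, np.full(7, 2.0)))
        assert res.status == "failed"

    def test_too_few_delays_rejected(self):
        with pytest.raises(ValueError):
            RelaxationSeries("A1", np.array([0.1, 0.1, 0.1]), np.ones(3))
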