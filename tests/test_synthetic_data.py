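"""Determinism, energy closure and recovery properties of the generator."""

import math
from statistics import fmean

import numpy as np
import pandas as pd
import pytest

from swinecal import (
    NoiseConfig,
    PanelConfig,
    brouwer_thp,
    fit_ols,
    generate_experiment,
    generate_ingredient_panel,
    metabolic_weight,
    reference_study_config,
    pig_energy_balance,
    summarize_diet,
)
from swinecal.calorimetry import methane_energy
from swinecal.ne_prediction import panel_frame
from swinecal.synthetic_data import REFERENCE_EP_SOURCES, compose_diet


class TestDietComposition:
    def test_basal_truth_matches_configured_mixture(self, zero_noise_experiment):
        basal = zero_noise_experiment.diet_truths["basal"]
        assert basal.f_mix == pytest.approx(0.975)
        assert basal.de == pytest.approx(16.08, abs=1e-9)
        assert basal.me == pytest.approx(15.54, abs=1e-9)
        assert basal.ne == pytest.approx(12.05, abs=1e-9)

    def test_test_diet_energy_is_inclusion_weighted(self, zero_noise_experiment):
        cfg = zero_noise_experiment.config
        dt = zero_noise_experiment.diet_truths["EP-RSM 1"]
        mix = cfg.ingredients["corn-soy mixture"]
        rsm = cfg.ingredients["EP-RSM 1"]
        assert dt.ne == pytest.approx(0.78 * mix.ne + 0.195 * rsm.ne, rel=1e-12)
        assert dt.f_test == pytest.approx(0.195)


class TestDeterminism:
    def test_same_seed_identical_datasets(self):
        cfg = reference_study_config()
        a = generate_experiment(cfg, seed=99)
        b = generate_experiment(cfg, seed=99)
        for ra, rb in zip(a.records, b.records):
            assert ra == rb

    def test_different_seeds_differ(self):
        cfg = reference_study_config()
        a = generate_experiment(cfg, seed=1)
        b = generate_experiment(cfg, seed=2)
        assert a.records[0].bw_kg != b.records[0].bw_kg


class TestEnergyClosure:
    def test_closure_at_zero_noise(self, zero_noise_experiment):
        """GE intake = fecal + urinary + CH4 + THP + RE per pig, 1e-9 relative."""
        for r in zero_noise_experiment.records:
            b = pig_energy_balance(r)
            total = (
                r.fecal_energy_kj_per_d
                + r.urinary_energy_kj_per_d
                + methane_energy(r.ch4_l_per_d)
                + b.thp_kj_per_d
                + b.re_kj_per_d
            )
            assert total == pytest.approx(r.ge_intake_kj_per_d, rel=1e-9)

    def test_fed_windows_return_intended_thp(self, zero_noise_experiment):
        cfg = zero_noise_experiment.config
        for r in zero_noise_experiment.records:
            dt = zero_noise_experiment.diet_truths[r.diet_id]
            me_intake = cfg.feeding_level_per_mbw * metabolic_weight(r.bw_kg)
            ne_intake = me_intake * dt.ne / dt.me
            fhp = cfg.true_fhp_per_mbw * metabolic_weight(r.bw_kg)
            thp_true = me_intake - (ne_intake - fhp)
            for w in r.fed_windows:
                assert brouwer_thp(w) == pytest.approx(thp_true, rel=1e-10)

    def test_fhp_recovered_exactly_at_zero_noise(self, zero_noise_experiment):
        for r in zero_noise_experiment.records:
            b = pig_energy_balance(r)
            assert b.per_mbw["fhp"] == pytest.approx(790.0, rel=1e-10)


class TestRecovery:
    def test_zero_noise_diet_ne_equals_truth(self, zero_noise_experiment):
        by_diet = {}
        for r in zero_noise_experiment.records:
            by_diet.setdefault(r.diet_id, []).append(r)
        for diet_id, recs in by_diet.items():
            s = summarize_diet(recs)
            truth = zero_noise_experiment.diet_truths[diet_id]
            assert s.ne_mj_per_kg_dm == pytest.approx(truth.ne, rel=1e-9)
            assert s.de_mj_per_kg_dm == pytest.approx(truth.de, rel=1e-9)
            assert s.me_mj_per_kg_dm == pytest.approx(truth.me, rel=1e-9)

    def test_bias_shrinks_with_more_pigs(self):
        """Recovered basal NE approaches truth as the herd grows, at fixed noise."""
        noise = NoiseConfig()  # default calibrated CVs
        errors = []
        for n_pigs in (4, 64):
            cfg = reference_study_config(noise=noise, n_pigs_per_diet=n_pigs)
            exp = generate_experiment(cfg, seed=555)
            recs = [r for r in exp.records if r.diet_id == "basal"]
            s = summarize_diet(recs)
            errors.append(abs(s.ne_mj_per_kg_dm - exp.diet_truths["basal"].ne))
        assert errors[1] < errors[0]
        assert errors[1] < 0.1  # well under 1% of 12.05

    def test_negative_ch4_configuration_rejected_before_sampling(self):
        from dataclasses import replace

        bad = replace(reference_study_config(), urinary_energy_frac_of_de=0.2)
        with pytest.raises(ValueError, match="CH4"):
            generate_experiment(bad, seed=0)


class TestIngredientPanel:
    def test_planted_ee_ge_correlation(self):
        rows = generate_ingredient_panel(1000, seed=42)
        df = panel_frame(rows)
        r = np.corrcoef(df["ee"], df["ge"])[0, 1]
        assert r == pytest.approx(0.98, abs=0.03)
        # sign structure: oil dilutes protein, fiber fractions co-vary
        assert np.corrcoef(df["ee"], df["cp"])[0, 1] < -0.4
        assert np.corrcoef(df["ndf"], df["adf"])[0, 1] > 0.7

    def test_zero_covariance_gives_near_zero_correlations(self):
        cfg = PanelConfig(correlations=())
        rows = generate_ingredient_panel(1000, cfg, seed=43)
        df = panel_frame(rows)
        for a, b in (("cp", "ee"), ("ndf", "adf"), ("ash", "starch")):
            assert abs(np.corrcoef(df[a], df[b])[0, 1]) < 0.1

    def test_noiseless_linear_truth_recovered_by_ols(self):
        models = dict(PanelConfig().energy_models)
        models["ne"] = (-1.48, {"me": 0.85}, 0.0)  # exact published ME equation
        cfg = PanelConfig(energy_models=models)
        rows = generate_ingredient_panel(50, cfg, seed=44)
        df = panel_frame(rows)
        m = fit_ols(df["ne"], df[["me"]])
        assert m.coefficients["me"] == pytest.approx(0.85, abs=1e-9)
        assert m.intercept == pytest.approx(-1.48, abs=1e-7)

    def test_non_positive_definite_correlations_rejected(self):
        cfg = PanelConfig(
            correlations=(("cp", "ee", 0.99), ("ee", "ndf", 0.99), ("cp", "ndf", -0.99))
        )
        with pytest.raises(ValueError, match="positive definite"):
            generate_ingredient_panel(10, cfg, seed=0)

    def test_minimum_panel_size(self):
        with pytest.raises(ValueError):
            generate_ingredient_panel(2, seed=0)
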