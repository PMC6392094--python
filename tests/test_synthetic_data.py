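"""Tests of the labeling-experiment generator against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from picoflux.enrichment import enrich_table, natural_abundance_vector
from picoflux.physiology import c14_fixation_rate, glycogen_concentration
from picoflux.synthetic_data import (
    LabelingExperimentConfig,
    MetabolitePoolSpec,
    default_metabolite_panel,
    mdv_progression,
    simulate_c14_assay,
    simulate_condition_pair,
    simulate_glycogen_assay,
    simulate_labeling_experiment,
    true_fractional_contribution,
)


# ---------------------------------------------------------------------------
# Independent fine-step oracle for the synthesis integral (plain left-endpoint
# Riemann sum, dt = 0.01 min — deliberately a different scheme from the
# implementation's exact-survival-weight midpoint stepping).
# ---------------------------------------------------------------------------

def oracle_mdv(t, c, k, k_pre, p_sub, dt=0.01):
    i = np.arange(c + 1)
    if t == 0 or k == 0:
        out = np.zeros(c + 1)
        out[0] = 1.0
        return out
    s = np.arange(0.0, t, dt)
    e = p_sub * (1.0 - np.exp(-k_pre * s))
    w = k * np.exp(-k * (t - s)) * dt
    mdv = stats.binom.pmf(i[:, None], c, e[None, :]) @ w
    mdv[0] += math.exp(-k * t)
    return mdv / mdv.sum()


def oracle_fc(t, c, k, k_pre, p_sub, dt=0.01):
    mdv = oracle_mdv(t, c, k, k_pre, p_sub, dt)
    return float(np.dot(mdv, np.arange(c + 1)) / c)


class TestForwardModel:
    def test_no_turnover_stays_at_natural_abundance(self):
        """k = 0: the pool never exchanges, so only natural abundance shows."""
        p_na = 0.0107
        baseline = natural_abundance_vector(4, p_na)
        for t in (0.0, 30.0, 90.0):
            mdv = mdv_progression(t, 4, 0.0, 0.1, 0.5, p_na=p_na)
            assert mdv == pytest.approx(baseline, abs=1e-12)

    def test_instantly_equilibrated_pool_is_binomial(self):
        """k, k_pre -> inf, no NA: MDV(t>0) = Binomial(c, p_sub), FC = p_sub."""
        c, p_sub = 5, 0.5
        mdv = mdv_progression(30.0, c, math.inf, math.inf, p_sub)
        assert mdv == pytest.approx(stats.binom.pmf(np.arange(c + 1), c, p_sub), abs=1e-12)
        assert true_fractional_contribution(30.0, c, math.inf, math.inf, p_sub) == (
            pytest.approx(p_sub, abs=1e-12)
        )

    @pytest.mark.parametrize("t", [30.0, 60.0, 90.0])
    def test_fc_matches_fine_step_oracle(self, t):
        """FC from the generator's stepping agrees with an independent
        dt = 0.01 min Riemann integration of the same integral."""
        k, k_pre, p_sub, c = 0.02, 0.05, 0.5, 5
        got = true_fractional_contribution(t, c, k, k_pre, p_sub)
        want = oracle_fc(t, c, k, k_pre, p_sub)
        assert got == pytest.approx(want, abs=1e-3)
        got_mdv = mdv_progression(t, c, k, k_pre, p_sub)
        assert got_mdv == pytest.approx(oracle_mdv(t, c, k, k_pre, p_sub), abs=1e-3)

    def test_mdv_is_a_distribution(self):
        for t in (0.0, 15.0, 45.0, 90.0):
            mdv = mdv_progression(t, 6, 0.04, 0.2, 0.5, p_na=0.0107)
            assert mdv.sum() == pytest.approx(1.0, abs=1e-9)
            assert (mdv >= 0).all()


class TestLabelingExperiment:
    def test_output_shape_and_nonnegativity(self, small_panel):
        cfg = LabelingExperimentConfig(seed=3)
        exp = simulate_labeling_experiment(small_panel, cfg)
        # complete i = 0..c block per metabolite/time/replicate
        for (met, _, _, _, _), grp in exp.table.groupby(
            ["metabolite", "condition", "biological_replicate",
             "technical_replicate", "time_min"]
        ):
            c = int(grp["c"].iloc[0])
            assert sorted(grp["i"]) == list(range(c + 1))
        assert (exp.table["ion_count"] >= 0).all()

    def test_replicate_mean_tic_recovers_pool_size(self, small_panel):
        """Mean TIC / cell density = pool_size within 3 CV / sqrt(n)."""
        cfg = LabelingExperimentConfig(seed=5, noise_cv=0.05)
        exp = simulate_labeling_experiment(small_panel, cfg)
        n = cfg.n_technical * cfg.n_biological
        tol = 3 * cfg.noise_cv / math.sqrt(n)
        tics = (
            exp.table.groupby(
                ["metabolite", "time_min", "biological_replicate", "technical_replicate"]
            )["ion_count"].sum().groupby(["metabolite", "time_min"]).mean()
        )
        for spec in small_panel:
            for t in cfg.timepoints:
                rel = tics.loc[(spec.name, t)] / cfg.cell_density
                assert abs(rel - spec.pool_size) / spec.pool_size < tol

    def test_noise_free_fc_equals_ground_truth(self, small_panel, noisefree_config):
        exp = simulate_labeling_experiment(small_panel, noisefree_config)
        fc = enrich_table(exp.table)["fc"]
        merged = fc.merge(exp.ground_truth, on=["metabolite", "condition", "time_min"])
        assert np.allclose(merged["fc"], merged["fc_true"], atol=1e-6)

    def test_fc_nondecreasing_in_time(self, noisefree_config):
        exp = simulate_labeling_experiment(default_metabolite_panel(), noisefree_config)
        for _, grp in exp.ground_truth.groupby("metabolite"):
            fc = grp.sort_values("time_min")["fc_true"].to_numpy()
            assert (np.diff(fc) >= -1e-12).all()

    def test_time_zero_is_pure_natural_abundance(self, small_panel):
        cfg = LabelingExperimentConfig(seed=1, noise_cv=0.0)
        exp = simulate_labeling_experiment(small_panel, cfg)
        t0 = exp.table[exp.table["time_min"] == 0]
        for (met,), grp in t0.groupby(["metabolite"]):
            spec = next(s for s in small_panel if s.name == met)
            block = grp[
                (grp["biological_replicate"] == 1) & (grp["technical_replicate"] == 1)
            ].sort_values("i")
            mdv = block["ion_count"].to_numpy() / block["ion_count"].sum()
            assert mdv == pytest.approx(
                natural_abundance_vector(spec.c, cfg.natural_abundance), abs=1e-9
            )

    def test_same_seed_bit_identical(self, small_panel):
        cfg = LabelingExperimentConfig(seed=42)
        a = simulate_labeling_experiment(small_panel, cfg)
        b = simulate_labeling_experiment(small_panel, cfg)
        pd.testing.assert_frame_equal(a.table, b.table)
        c = simulate_labeling_experiment(
            small_panel, LabelingExperimentConfig(seed=43)
        )
        assert not a.table["ion_count"].equals(c.table["ion_count"])

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            LabelingExperimentConfig(timepoints=(0.0, 30.0, 30.0))
        with pytest.raises(ValueError):
            LabelingExperimentConfig(timepoints=(10.0, 30.0))
        with pytest.raises(ValueError):
            LabelingExperimentConfig(noise_cv=-0.1)
        with pytest.raises(ValueError):
            MetabolitePoolSpec("x", 3, -1.0, 0.1, 0.1)
        with pytest.raises(ValueError):
            MetabolitePoolSpec("x", 3, 1.0, -0.1, 0.1)


class TestConditionPair:
    def test_unit_factor_statistically_identical(self, small_panel):
        cfg = LabelingExperimentConfig(seed=9, noise_cv=0.0)
        pair = simulate_condition_pair(small_panel, cfg, 1.0, allow_unit_factor=True)
        assert np.allclose(
            pair.replete.table["ion_count"], pair.limited.table["ion_count"]
        )

    def test_factor_must_exceed_one(self, small_panel):
        cfg = LabelingExperimentConfig(seed=9)
        with pytest.raises(ValueError):
            simulate_condition_pair(small_panel, cfg, 1.0)
        with pytest.raises(ValueError):
            simulate_condition_pair(small_panel, cfg, 0.5, allow_unit_factor=True)

    def test_limited_labels_slower_and_pools_larger(self, small_panel):
        """Factor 3, noise-free: limited FC(30) < replete FC(30) and limited
        pools exactly 3x for every metabolite; flux proxy k x pool preserved."""
        cfg = LabelingExperimentConfig(seed=9, noise_cv=0.0)
        pair = simulate_condition_pair(small_panel, cfg, 3.0)
        rep = pair.replete.ground_truth.set_index(["metabolite", "time_min"])
        lim = pair.limited.ground_truth.set_index(["metabolite", "time_min"])
        for spec in small_panel:
            assert (
                lim.loc[(spec.name, 30.0), "fc_true"]
                < rep.loc[(spec.name, 30.0), "fc_true"]
            )
            assert lim.loc[(spec.name, 30.0), "pool_size"] == pytest.approx(
                3.0 * rep.loc[(spec.name, 30.0), "pool_size"]
            )
            flux_rep = rep.loc[(spec.name, 0.0), "turnover_rate"] * rep.loc[
                (spec.name, 0.0), "pool_size"
            ]
            flux_lim = lim.loc[(spec.name, 0.0), "turnover_rate"] * lim.loc[
                (spec.name, 0.0), "pool_size"
            ]
            assert flux_lim == pytest.approx(flux_rep, rel=1e-12)


class TestC14Generator:
    def test_zero_rate_means_light_equals_dark(self):
        toc, _ = simulate_c14_assay(0.0, 0.5, dark_rate=1e-19, counting_noise=0.0)
        assert np.mean(toc.light_counts) == pytest.approx(np.mean(toc.dark_counts))

    def test_full_particulate_fraction_same_means(self):
        toc, poc = simulate_c14_assay(2e-18, 1.0, counting_noise=0.0)
        assert np.mean(toc.light_counts) == pytest.approx(np.mean(poc.light_counts))

    def test_zero_noise_round_trip(self):
        true_rate = 2.0e-18
        toc, poc = simulate_c14_assay(true_rate, 0.7, counting_noise=0.0)
        assert c14_fixation_rate(toc).rate == pytest.approx(true_rate, rel=1e-12)
        assert c14_fixation_rate(poc).rate == pytest.approx(0.7 * true_rate, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_c14_assay(-1.0, 0.5)
        with pytest.raises(ValueError):
            simulate_c14_assay(1e-18, 1.5)


class TestGlycogenGenerator:
    def test_zero_noise_recovers_line_and_conc(self):
        assay = simulate_glycogen_assay(60.0, slope=0.004, intercept=0.02, noise_sd=0.0)
        res = glycogen_concentration(assay)
        assert res.slope == pytest.approx(0.004, rel=1e-12)
        assert res.intercept == pytest.approx(0.02, abs=1e-12)
        assert res.concentration == pytest.approx(60.0, rel=1e-12)

    def test_conc_at_a_standard_recovers_that_standard(self):
        assay = simulate_glycogen_assay(75.0, noise_sd=0.0)
        assert glycogen_concentration(assay).concentration == pytest.approx(75.0)

    def test_monte_carlo_recovery_within_five_percent(self):
        """Median |est - true|/true < 5% at 75 mg/ml with absorbance SD 0.005."""
        errs = []
        for seed in range(200):
            assay = simulate_glycogen_assay(75.0, noise_sd=0.005, seed=seed)
            est = glycogen_concentration(assay).concentration
            errs.append(abs(est - 75.0) / 75.0)
        assert np.median(errs) < 0.05
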