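"""Precision weights, the weighted contrast, variance moderation and FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import guidescreen as gs
from guidescreen.diffexp import (
    bh_fdr,
    fit_contrast,
    moderate_t,
    voom_weights,
)

DESIGN_3V3 = np.array(["treat"] * 3 + ["ctrl"] * 3)


def _frame(values):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )


def _unit_weights(df):
    return pd.DataFrame(1.0, index=df.index, columns=df.columns)


class TestVoomWeights:
    def test_homoskedastic_data_flat_weights(self):
        """Constant-variance Gaussian log-counts: weights near-constant
        across the abundance range."""
        rng = np.random.default_rng(0)
        mu = rng.uniform(2, 12, 2000)
        y = mu[:, None] + rng.normal(0, 0.4, (2000, 6))
        w = voom_weights(_frame(y), DESIGN_3V3)
        spread = w.to_numpy().max() / w.to_numpy().min()
        assert spread < 1.35  # within ~10% of constant on the sd scale

    def test_count_like_variance_gives_increasing_weights(self):
        """Variance shrinking with abundance: weights rise with abundance."""
        rng = np.random.default_rng(1)
        mu = rng.uniform(1, 12, 2000)
        sd = 2.0 / np.sqrt(2.0**mu)  # variance ~ 1/mean-count
        y = mu[:, None] + rng.normal(0, 1, (2000, 6)) * sd[:, None]
        w = voom_weights(_frame(y), DESIGN_3V3)
        rho = stats.spearmanr(mu, w.mean(axis=1)).statistic
        assert rho > 0.9

    def test_duplicated_guides_get_equal_weights(self):
        rng = np.random.default_rng(2)
        base = rng.normal(8, 1, 6)
        y = np.vstack([base] * 100 + [rng.normal(5, 1, (50, 6))])
        w = voom_weights(_frame(y), DESIGN_3V3)
        dup = w.to_numpy()[:100]
        assert np.allclose(dup, dup[0], atol=1e-12)

    def test_too_few_guides_or_samples_rejected(self):
        y = _frame(np.ones((3, 6)))
        with pytest.raises(ValueError, match="4 guides"):
            voom_weights(y, DESIGN_3V3)
        with pytest.raises(ValueError, match="fewer than 2"):
            voom_weights(_frame(np.ones((10, 4))), np.array(["a", "a", "a", "b"]))


class TestFitContrast:
    def test_identical_conditions_zero_lfc(self):
        rng = np.random.default_rng(3)
        half = rng.normal(8, 1, (20, 3))
        y = _frame(np.hstack([half, half]))
        fit = fit_contrast(y, _unit_weights(y), DESIGN_3V3, ("treat", "ctrl"))
        assert np.allclose(fit["lfc"], 0.0, atol=1e-14)

    def test_unit_weights_match_pooled_two_sample_oracle(self):
        """With unit weights the fit is the textbook two-sample problem:
        lfc = difference of means, s2 = pooled variance."""
        rng = np.random.default_rng(4)
        y = rng.normal(8, 1, (50, 6))
        fit = fit_contrast(_frame(y), _unit_weights(_frame(y)), DESIGN_3V3,
                           ("treat", "ctrl"))
        t, c = y[:, :3], y[:, 3:]
        lfc = t.mean(axis=1) - c.mean(axis=1)
        pooled = (t.var(axis=1, ddof=1) * 2 + c.var(axis=1, ddof=1) * 2) / 4
        assert np.allclose(fit["lfc"], lfc, atol=1e-12)
        assert np.allclose(fit["s2"], pooled, atol=1e-12)
        assert (fit["df"] == 4).all()
        assert np.allclose(fit["v"], 2 / 3, atol=1e-12)

    def test_planted_twofold_depletion_recovered(self, small_cfg, small_lib):
        """A gene depleting 2-fold by day 21 comes out with lfc near -1."""
        delta = -1.0 / 21
        eff = gs.EffectTable(delta={("GENE0003", "MEKi"): delta})
        cfg = gs.SimulationConfig(
            **{
                **small_cfg.__dict__,
                "coverage": 4000,
                "dispersion": 0.01,
                "seed": 21,
            }
        )
        cm = gs.simulate_screen(small_lib, eff, cfg)
        res = gs.differential_abundance(cm, small_lib, "MEKi", "vehicle", 21)
        lfcs = res.loc[small_lib.guides_for("GENE0003"), "lfc"]
        assert np.abs(lfcs.mean() + 1.0) < 0.1

    def test_missing_condition_named(self):
        y = _frame(np.ones((10, 6)))
        with pytest.raises(ValueError, match="'drugX'"):
            fit_contrast(y, _unit_weights(y), DESIGN_3V3, ("drugX", "ctrl"))


class TestModerateT:
    @pytest.fixture
    def fit(self):
        rng = np.random.default_rng(5)
        y = rng.normal(8, 1, (200, 6))
        y[:20, :3] += 1.5
        df = _frame(y)
        return fit_contrast(df, _unit_weights(df), DESIGN_3V3, ("treat", "ctrl"))

    def test_d0_zero_recovers_ordinary_t(self, fit):
        res = moderate_t(fit, d0=0.0, s0sq=1.0)
        ordinary = fit["lfc"] / np.sqrt(fit["s2"] * fit["v"])
        assert np.allclose(res["t_mod"], ordinary, atol=1e-10)
        p = 2 * stats.t.sf(np.abs(ordinary), fit["df"])
        assert np.allclose(res["p"], p, atol=1e-10)

    def test_d0_infinite_recovers_z_against_prior(self, fit):
        s0sq = 0.9
        res = moderate_t(fit, d0=np.inf, s0sq=s0sq)
        z = fit["lfc"] / np.sqrt(s0sq * fit["v"])
        assert np.allclose(res["t_mod"], z, atol=1e-10)
        assert np.allclose(res["p"], 2 * stats.norm.sf(np.abs(z)), atol=1e-12)

    def test_moderation_shrinks_toward_trend(self, fit):
        res = moderate_t(fit)
        d0, s0sq = res.attrs["d0"], res.attrs["s0sq"]
        assert d0 > 0 and s0sq > 0
        # posterior variances lie between each guide's s2 and the prior
        inside = (
            np.minimum(fit["s2"], s0sq) - 1e-12 <= res["s2_post"]
        ) & (res["s2_post"] <= np.maximum(fit["s2"], s0sq) + 1e-12)
        assert inside.all()
        ordinary = fit["lfc"] / np.sqrt(fit["s2"] * fit["v"])
        rho = stats.spearmanr(np.abs(res["t_mod"]), np.abs(ordinary)).statistic
        assert rho > 0.9

    def test_null_type_one_error_calibrated(self):
        """Pure-noise 2000-guide fit: p<0.05 fraction near nominal."""
        rng = np.random.default_rng(6)
        y = _frame(rng.normal(8, 0.5, (2000, 6)))
        fit = fit_contrast(y, _unit_weights(y), DESIGN_3V3, ("treat", "ctrl"))
        res = moderate_t(fit)
        frac = (res["p"] < 0.05).mean()
        assert 0.035 < frac < 0.065

    def test_all_zero_variances_rejected(self):
        y = _frame(np.tile(np.arange(6.0), (20, 1)) * 0 + 1.0)
        fit = fit_contrast(y, _unit_weights(y), DESIGN_3V3, ("treat", "ctrl"))
        with pytest.raises(ValueError, match="zero"):
            moderate_t(fit)

    def test_fdr_column_dominates_p(self, fit):
        res = moderate_t(fit)
        assert (res["fdr"] >= res["p"] - 1e-15).all()
        assert (res["fdr"] <= 1.0).all()


class TestBhFdr:
    def test_hand_worked_step_up(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04, atol=1e-15)

    @pytest.mark.parametrize(
        "p,expected",
        [(np.ones(5), np.ones(5)), (np.array([0.2]), np.array([0.2]))],
    )
    def test_degenerate_inputs(self, p, expected):
        assert np.allclose(bh_fdr(p), expected)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=500)
        q = bh_fdr(p)
        assert (q <= 1.0).all() and (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestPipelineInvariances:
    def test_lfc_invariant_to_sample_depth_scaling(self, small_lib, small_cfg, neutral_screen):
        """Multiplying one sample's counts by a constant leaves LFCs
        essentially unchanged (depth is absorbed by CPM + TMM)."""
        res1 = gs.differential_abundance(neutral_screen, small_lib, "MEKi", "vehicle", 21)
        scaled = neutral_screen.counts.copy()
        target = scaled.columns[scaled.columns.str.contains("MEKi")][0]
        scaled[target] = scaled[target] * 3
        cm2 = gs.CountMatrix(scaled, neutral_screen.samples)
        res2 = gs.differential_abundance(cm2, small_lib, "MEKi", "vehicle", 21)
        assert np.abs(res1["lfc"] - res2["lfc"]).max() < 0.01

    def test_ntc_guides_centered_in_null_screen(self, small_lib, neutral_screen):
        res = gs.differential_abundance(neutral_screen, small_lib, "MEKi", "vehicle", 21)
        ntc = res.loc[small_lib.table["is_ntc"], "lfc"]
        assert abs(ntc.mean()) < 0.2  # small-n fixture; full bound in acceptance
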