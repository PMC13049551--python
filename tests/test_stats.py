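"""Statistical battery: hand oracles, recovery, calibration, equivalences."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gboldcsf import SimulationConfig
from gboldcsf.simulate import simulate_coupling_table
from gboldcsf.stats import (
    LongitudinalCouplingModel,
    association_model,
    baseline_group_model,
    fdr_adjust,
    holm_adjust,
    lesion_coupling_screen,
    paired_t,
    paired_t_power,
    partial_correlation,
    shapiro_wilk,
    two_sample_t_from_summary,
)


# --- independent brute-force multiplicity oracles -------------------------

def holm_brute(p):
    """Step-down Holm by direct definition, with monotonicity enforcement."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = min((m - rank) * p[idx], 1.0)
        running = max(running, val)
        adj[idx] = running
    return adj


def bh_brute(p):
    """Step-up Benjamini-Hochberg by direct definition."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        val = min(m * p[idx] / (rank + 1), 1.0)
        running = min(running, val)
        adj[idx] = running
    return adj


class TestMultiplicity:
    def test_holm_hand_case(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06], atol=1e-12
        )

    def test_bh_hand_case(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], atol=1e-12
        )

    def test_single_p_unchanged(self):
        assert holm_adjust([0.2])[0] == 0.2
        assert fdr_adjust([0.2])[0] == 0.2

    def test_all_equal_ties(self):
        p = [0.03, 0.03, 0.03]
        np.testing.assert_allclose(holm_adjust(p), np.minimum(3 * np.asarray(p), 1))

    def test_empty_passthrough(self):
        assert holm_adjust([]).size == 0
        assert fdr_adjust([]).size == 0

    def test_invalid_pvals_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.2]):
            with pytest.raises(ValueError):
                holm_adjust(bad)

    def test_brute_force_equivalence_on_all_subsets(self):
        """Holm and BH match the direct-definition oracles on every subset."""
        base = np.array([0.004, 0.019, 0.019, 0.22, 0.51, 0.97])
        for r in range(1, 7):
            for subset in itertools.combinations(base, r):
                p = np.array(subset)
                np.testing.assert_allclose(holm_adjust(p), holm_brute(p), atol=1e-12)
                np.testing.assert_allclose(fdr_adjust(p), bh_brute(p), atol=1e-12)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.uniform(0.001, 1.0, size=rng.integers(1, 9))
            assert (holm_adjust(p) >= p - 1e-15).all()
            assert (fdr_adjust(p) >= p - 1e-15).all()


class TestPairedT:
    def test_hand_computation(self):
        """Diffs {1,2,3}: mean 2, SD 1, t = 2 sqrt(3), d = 2."""
        res = paired_t([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(2 * np.sqrt(3), abs=1e-9)
        assert res.extra["cohens_d"] == pytest.approx(2.0, abs=1e-12)
        t_ref = sps.ttest_rel([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert res.p == pytest.approx(t_ref.pvalue, abs=1e-12)

    def test_constant_shift_degenerate(self):
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_mismatched_lengths(self):
        with pytest.raises(ValueError, match="matched"):
            paired_t([1.0, 2.0], [1.0])


class TestShapiro:
    def test_normal_sample_not_rejected(self):
        rng = np.random.default_rng(8)
        _, p = shapiro_wilk(rng.standard_normal(50))
        assert p > 0.05

    def test_skewed_sample_rejected(self):
        rng = np.random.default_rng(8)
        _, p = shapiro_wilk(rng.exponential(size=50))
        assert p < 0.05

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            shapiro_wilk(np.ones(10))

    def test_n_out_of_range(self):
        with pytest.raises(ValueError, match="3 <= n"):
            shapiro_wilk([1.0, 2.0])


class TestBaselineGroupModel:
    def test_recovers_generated_group_gap(self):
        cfg = SimulationConfig(seed=5)
        tab = simulate_coupling_table(cfg).query("condition in ('HC', 'PSA_pre')")
        res = baseline_group_model(
            tab["coupling"], tab["group"], tab["age"], tab["sex"]
        )
        true_gap = cfg.coupling_mean["PSA_pre"] - cfg.coupling_mean["HC"]
        assert res.estimate > 0  # patients less negative than controls
        assert res.ci_low <= true_gap <= res.ci_high or res.p < 0.05
        assert res.p < 0.05

    def test_identical_groups_null(self):
        rng = np.random.default_rng(9)
        res = baseline_group_model(
            rng.standard_normal(60),
            np.repeat(["HC", "PSA"], 30),
            rng.normal(48, 9, 60),
            rng.integers(0, 2, 60),
        )
        assert abs(res.estimate) < 0.6
        assert res.p > 0.01

    def test_small_group_rejected(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError, match=">= 5"):
            baseline_group_model(
                rng.standard_normal(7),
                ["HC"] * 4 + ["PSA"] * 3,
                rng.normal(48, 9, 7),
                rng.integers(0, 2, 7),
            )


class TestLongitudinalModel:
    def test_recovers_condition_difference(self):
        cfg = SimulationConfig(seed=13, n_hc=35, n_psa=20, n_treated=14)
        df = simulate_coupling_table(cfg)
        res = LongitudinalCouplingModel(df).fit()
        assert res.converged
        row = res.contrasts.set_index("contrast").loc["PSA_post_vs_PSA_pre"]
        true_delta = cfg.coupling_mean["PSA_post"] - cfg.coupling_mean["PSA_pre"]
        assert row.ci_low <= true_delta <= row.ci_high
        assert (res.contrasts["p_holm"] >= res.contrasts["p"] - 1e-15).all()

    def test_contrast_accessor_roundtrip(self):
        cfg = SimulationConfig(seed=14, n_hc=20, n_psa=12, n_treated=8)
        res = LongitudinalCouplingModel(simulate_coupling_table(cfg)).fit()
        mr = res.contrast("PSA_post_vs_HC")
        assert mr.adjust_method == "holm"
        assert mr.ci_low <= mr.estimate <= mr.ci_high
        assert "mixed" in res.summary().lower() or "OLS" in res.summary()


class TestAssociationModel:
    def test_recovers_target_partial_r(self):
        rng = np.random.default_rng(5)
        n, r = 200, -0.54
        z = rng.standard_normal(n)
        y = r * z + np.sqrt(1 - r**2) * rng.standard_normal(n)
        res = association_model(y, z)
        assert res.extra["partial_r"] == pytest.approx(r, abs=0.1)
        assert res.p < 0.001

    def test_null_with_covariates(self):
        rng = np.random.default_rng(6)
        res = association_model(
            rng.standard_normal(100), rng.standard_normal(100),
            age=rng.normal(50, 9, 100), baseline_score=rng.normal(40, 10, 100),
            lesion_volume=rng.lognormal(9, 0.8, 100),
        )
        assert abs(res.extra["partial_r"]) < 0.3
        assert 0 < res.p <= 1

    def test_too_small_sample_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError, match="too small"):
            association_model(rng.standard_normal(5), rng.standard_normal(5),
                              age=rng.standard_normal(5),
                              baseline_score=rng.standard_normal(5))

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(30)
        with pytest.raises(ValueError, match="collinear"):
            association_model(rng.standard_normal(30), x, age=2 * x)


class TestPartialCorrelation:
    def test_reduces_to_pearson_without_covariates(self, rng):
        x, y = rng.standard_normal(80), rng.standard_normal(80)
        r, p = partial_correlation(x, y)
        ref = sps.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_construction_recovers_masked_relation(self, rng):
        n = 200
        cov = rng.standard_normal(n)
        x = rng.standard_normal(n)
        y = x + 5.0 * cov
        r, _ = partial_correlation(x, y, cov)
        assert r == pytest.approx(1.0, abs=1e-8)

    def test_agrees_with_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        n = 60
        df = pd.DataFrame(
            {"x": rng.standard_normal(n), "y": rng.standard_normal(n),
             "c1": rng.standard_normal(n), "c2": rng.standard_normal(n)}
        )
        r, p = partial_correlation(df["x"], df["y"], df[["c1", "c2"]].to_numpy())
        ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert p == pytest.approx(float(ref[pcol].iloc[0]), abs=1e-8)


class TestPower:
    def test_monotone_in_effect_size(self):
        assert paired_t_power(0.72) > paired_t_power(1.35)

    def test_one_tailed_matches_printed_small_sample(self):
        # the d = 1.35, 80% power case: n = 6 under the one-tailed convention
        assert paired_t_power(1.35, tails=1) == 6
        assert paired_t_power(1.35, tails=2) == 7

    def test_normal_approximation_consistency(self):
        d = 0.72
        n = paired_t_power(d)
        approx = ((sps.norm.ppf(0.975) + sps.norm.ppf(0.8)) / d) ** 2
        assert approx - 1 <= n <= approx + 4

    def test_monte_carlo_power_at_returned_n(self):
        """Brute-force simulated power at the returned n brackets the target."""
        d, alpha = 1.35, 0.05
        n = paired_t_power(d, alpha=alpha, power=0.8, tails=2)
        rng = np.random.default_rng(100)
        reps = 50_000
        x = rng.standard_normal((reps, n)) + d
        t = x.mean(axis=1) / (x.std(axis=1, ddof=1) / np.sqrt(n))
        power_n = (np.abs(t) > sps.t.ppf(1 - alpha / 2, n - 1)).mean()
        assert power_n >= 0.8 - 0.02
        # and n-1 must fall short of the target
        x = rng.standard_normal((reps, n - 1)) + d
        t = x.mean(axis=1) / (x.std(axis=1, ddof=1) / np.sqrt(n - 1))
        power_n1 = (np.abs(t) > sps.t.ppf(1 - alpha / 2, n - 2)).mean()
        assert power_n1 < 0.8 + 0.02

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            paired_t_power(0.0)
        with pytest.raises(ValueError):
            paired_t_power(0.5, alpha=1.5)
        with pytest.raises(ValueError):
            paired_t_power(0.5, tails=3)


class TestSummaryT:
    def test_published_age_row(self):
        """Group age summaries reproduce the printed non-significant contrast."""
        from gboldcsf.published import AGE_SUMMARY

        m1, sd1, n1 = AGE_SUMMARY["HC"]
        m2, sd2, n2 = AGE_SUMMARY["PSA"]
        t, p = two_sample_t_from_summary(m1, sd1, n1, m2, sd2, n2)
        assert t == pytest.approx(0.578, abs=0.001)
        assert round(p, 2) == 0.57

    def test_equal_summaries(self):
        t, p = two_sample_t_from_summary(5, 1, 10, 5, 1, 10)
        assert t == 0.0 and p == 1.0

    def test_equivalence_with_direct_data(self, rng):
        """Constructing data with those exact summaries gives the same t."""
        x = rng.standard_normal(35)
        x = (x - x.mean()) / x.std(ddof=1) * 9.14 + 48.0
        y = rng.standard_normal(20)
        y = (y - y.mean()) / y.std(ddof=1) * 9.45 + 46.5
        t_direct = sps.ttest_ind(x, y, equal_var=True)
        t, p = two_sample_t_from_summary(48.0, 9.14, 35, 46.5, 9.45, 20)
        assert t == pytest.approx(t_direct.statistic, abs=1e-9)
        assert p == pytest.approx(t_direct.pvalue, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            two_sample_t_from_summary(0, 1, 1, 0, 1, 10)
        with pytest.raises(ValueError):
            two_sample_t_from_summary(0, 0, 10, 0, 1, 10)


class TestLesionScreen:
    def _table(self, rng, n=20):
        return pd.DataFrame(
            {f"coupling_{net}": rng.standard_normal(n) * 0.1 - 0.2
             for net in ("LN", "SN", "DAN", "DMN")}
        )

    def test_null_screen_shape_and_ranges(self, rng):
        tab = self._table(rng)
        out = lesion_coupling_screen(tab, rng.lognormal(9, 0.8, 20))
        assert list(out["network"]) == ["LN", "SN", "DAN", "DMN"]
        assert out["r"].between(-1, 1).all()
        assert (out["p_fdr"] >= out["p"] - 1e-15).all()

    def test_injected_effect_detected(self):
        rng = np.random.default_rng(11)
        n = 400
        vol = rng.lognormal(9, 0.8, n)
        tab = self._table(rng, n)
        tab["coupling_LN"] = 0.0004 * (vol - vol.mean()) + rng.standard_normal(n) * 0.02
        out = lesion_coupling_screen(tab, vol).set_index("network")
        assert out.loc["LN", "p"] < 0.01

    def test_constant_volume_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            lesion_coupling_screen(self._table(rng), np.full(20, 5000.0))

    def test_small_n_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 4"):
            lesion_coupling_screen(self._table(rng, 3), np.ones(3))
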