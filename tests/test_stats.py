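"""Diversity metrics and the statistical testing layer against direct
arithmetic oracles."""

import numpy as np
import pandas as pd
import pytest

from phagefmt.catalog import AbundanceMatrix, Unit
from phagefmt.model import Lifestyle, Timepoint
from phagefmt.stats import (
    bray_curtis,
    change_from_baseline,
    chisq_with_posthoc,
    fdr_adjust,
    lifestyle_totals,
    lmm_timepoint_contrast,
    pearson_test,
    shannon,
    variability_from_wk6,
    votu_stability,
    wilcoxon_rank_sum,
)


class TestShannon:
    def test_uniform_closed_form(self):
        assert shannon([1, 1, 1, 1]) == pytest.approx(np.log(4))

    def test_single_feature_zero(self):
        assert shannon([0, 5, 0]) == 0.0

    def test_all_zero_is_missing(self):
        assert np.isnan(shannon([0.0, 0.0]))

    def test_matches_direct_sum_oracle(self, rng):
        x = rng.uniform(0, 10, size=50)
        p = x / x.sum()
        oracle = -sum(pi * np.log(pi) for pi in p if pi > 0)
        assert shannon(x) == pytest.approx(oracle, abs=1e-12)

    def test_bounded_by_log_richness(self, rng):
        for _ in range(20):
            x = rng.uniform(0, 1, size=10)
            assert shannon(x) <= np.log((x > 0).sum()) + 1e-12

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            shannon([-1.0, 2.0])


class TestBrayCurtis:
    def test_identical_zero(self, rng):
        x = rng.uniform(0, 5, size=8)
        assert bray_curtis(x, x) == 0.0

    def test_disjoint_one(self):
        assert bray_curtis([1, 0, 2], [0, 3, 0]) == 1.0

    def test_hand_arithmetic(self):
        assert bray_curtis([1, 1], [1, 0]) == pytest.approx(1 / 3)

    def test_symmetry_and_bounds(self, rng):
        a, b = rng.uniform(0, 5, size=8), rng.uniform(0, 5, size=8)
        assert bray_curtis(a, b) == pytest.approx(bray_curtis(b, a))
        assert 0.0 <= bray_curtis(a, b) <= 1.0

    def test_both_empty_missing(self):
        assert np.isnan(bray_curtis([0, 0], [0, 0]))


class TestFdr:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03]) == pytest.approx([0.03])

    def test_worked_example(self):
        """BH by hand: q_(i) = min_{j>=i} p_(j) m / j."""
        p = np.array([0.01, 0.02, 0.03, 0.04])
        hand = [min(p[j] * 4 / (j + 1) for j in range(i, 4)) for i in range(4)]
        assert fdr_adjust(p) == pytest.approx(hand)
        assert fdr_adjust(p) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert fdr_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_q_dominates_p_and_nan_passthrough(self, rng):
        p = rng.uniform(0, 1, size=20)
        q = fdr_adjust(p)
        assert (q >= p - 1e-12).all()
        q2 = fdr_adjust([0.01, np.nan, 0.5])
        assert np.isnan(q2[1]) and not np.isnan(q2[0])


class TestChisq:
    def test_flat_table(self):
        res = chisq_with_posthoc(pd.DataFrame([[10, 10], [10, 10]]))
        assert res.statistic == 0.0 and res.p == 1.0

    def test_hand_formula(self):
        """sum (O-E)^2 / E with all margins 25 and E=12.5: 18.0."""
        res = chisq_with_posthoc(pd.DataFrame([[20, 5], [5, 20]]))
        assert res.statistic == pytest.approx(18.0)

    def test_residual_sign_structure(self):
        res = chisq_with_posthoc(pd.DataFrame([[20, 5], [5, 20]]))
        r = res.residuals.set_index(["row", "col"])["residual"]
        assert r[(0, 0)] > 0 and r[(0, 1)] < 0
        assert r[(1, 0)] < 0 and r[(1, 1)] > 0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chisq_with_posthoc(pd.DataFrame([[0, 0], [5, 5]]))


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(1.0, 9.0)
        assert pearson_test(x, 2 * x)[0] == pytest.approx(1.0)
        assert pearson_test(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=8)
        r_oracle = (
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        r, p = pearson_test(x, y)
        assert r == pytest.approx(r_oracle, abs=1e-12)
        from scipy import stats as sps
        t = r_oracle * np.sqrt(6 / (1 - r_oracle**2))
        assert p == pytest.approx(2 * sps.t.sf(abs(t), df=6), abs=1e-12)


class TestWilcoxon:
    def test_detects_shift(self, rng):
        x = rng.normal(3, 1, size=15)
        y = rng.normal(0, 1, size=15)
        _, p = wilcoxon_rank_sum(x, y)
        assert p < 0.01

    def test_symmetric_null(self, rng):
        x = rng.normal(size=10)
        _, p = wilcoxon_rank_sum(x, x)
        assert p > 0.9


def long_response(effect=0.0, n_per_arm=8, sd=1.0, seed=0):
    """Two-arm longitudinal response with an optional FMT shift from wk6
    onward."""
    rng = np.random.default_rng(seed)
    rows = []
    for arm in ("FMT", "placebo"):
        for s in range(n_per_arm):
            subj_eff = rng.normal(0, 0.5)
            for tp in ("wk6", "wk12", "wk26"):
                v = rng.normal(subj_eff, sd)
                if arm == "FMT":
                    v += effect
                rows.append({"subject": f"{arm}{s}", "treatment": arm,
                             "timepoint": tp, "value": v})
    return pd.DataFrame(rows)


class TestLmm:
    def test_null_contrasts_rarely_significant(self):
        sig = total = 0
        for seed in range(10):
            res = lmm_timepoint_contrast(long_response(effect=0.0, seed=seed))
            sig += int((res["q"] <= 0.05).sum())
            total += len(res)
        assert sig / total <= 0.15

    def test_two_sd_shift_detected_at_wk6(self):
        hits = 0
        for seed in range(10):
            res = lmm_timepoint_contrast(long_response(effect=2.0, seed=seed))
            wk6 = res.set_index("timepoint").loc["wk6"]
            if wk6["q"] <= 0.05:
                hits += 1
        assert hits >= 9

    def test_single_timepoint_rejected(self):
        df = long_response().query("timepoint == 'wk6'")
        with pytest.raises(ValueError):
            lmm_timepoint_contrast(df)

    def test_estimate_recovers_shift(self):
        res = lmm_timepoint_contrast(long_response(effect=2.0, n_per_arm=30, seed=3))
        assert res["estimate"].mean() == pytest.approx(2.0, abs=0.5)


class TestChangeFromBaseline:
    def test_subtracts_baseline(self):
        df = pd.DataFrame(
            [{"subject": "r", "treatment": "FMT", "timepoint": tp, "value": v}
             for tp, v in [("baseline", 1.0), ("wk6", 3.0), ("wk26", 0.5)]]
        )
        out = change_from_baseline(df).set_index("timepoint")["value"]
        assert out["wk6"] == 2.0 and out["wk26"] == -0.5


def toy_cohort_abundance():
    """4 recipients x 4 timepoints; FMT subjects churn their vOTUs after
    wk6 while placebo subjects keep a stable profile."""
    from phagefmt.model import Role, SampleRecord, Sex, Treatment

    rng = np.random.default_rng(12)
    metadata, cols = [], {}
    votus = [f"v{i}" for i in range(30)]
    for arm in ("FMT", "placebo"):
        for s in range(4):
            subj = f"{arm}{s}"
            stable = rng.choice(30, size=10, replace=False)
            for tp in ("baseline", "wk6", "wk12", "wk26"):
                sid = f"{subj}_{tp}"
                metadata.append(SampleRecord(sid, subj, Role.recipient,
                                             Treatment(arm), Sex.female,
                                             Timepoint(tp)))
                profile = np.zeros(30)
                if arm == "placebo" or tp in ("baseline", "wk6"):
                    profile[stable] = 1.0
                else:
                    churn = rng.choice(30, size=10, replace=False)
                    profile[churn] = 1.0
                cols[sid] = profile
    mat = pd.DataFrame(cols, index=votus)
    return metadata, AbundanceMatrix(mat, Unit.CPM_derived)


class TestLongitudinal:
    def test_variability_detects_fmt_churn(self):
        metadata, abund = toy_cohort_abundance()
        bc, tests = variability_from_wk6(abund, metadata)
        assert set(bc["timepoint"]) == {"wk12", "wk26"}
        med = bc.groupby("treatment")["bray_curtis"].median()
        assert med["FMT"] > med["placebo"]
        assert (tests["q"] <= 0.05).any()

    def test_identical_profiles_zero_shift(self):
        metadata, abund = toy_cohort_abundance()
        plc = [m for m in metadata if m.treatment.value == "placebo"]
        bc, _ = variability_from_wk6(abund, plc)
        assert (bc["bray_curtis"] == 0.0).all()

    def test_stability_categories(self):
        metadata, abund = toy_cohort_abundance()
        table, tests = votu_stability(abund, metadata)
        fem = table[table["sex"] == "female"].drop(columns="sex")
        # placebo vOTUs persist at all 4 timepoints; FMT churn creates
        # single-timepoint vOTUs
        assert fem.loc["placebo", "n_timepoints_4"] > 0
        assert fem.loc["FMT", "n_timepoints_1"] > fem.loc["placebo", "n_timepoints_1"]
        assert "female" in tests

    def test_generator_directional_recovery_high_fmt_novel_rate(self):
        """With a much higher novel-lineage injection rate in the FMT
        arm, FMT recipients show a larger week-6-anchored shift and an
        excess of single-timepoint vOTUs."""
        import dataclasses

        from phagefmt.benchmarks import NULL_SIM, _truth_hq_abundance
        from phagefmt.simulate import build_plan

        cfg = dataclasses.replace(NULL_SIM, seed=23, novel_rate_fmt=15.0,
                                  novel_rate_placebo=3.0)
        plan = build_plan(cfg)
        abund = _truth_hq_abundance(plan)
        bc, _ = variability_from_wk6(abund, plan.metadata)
        med = bc.groupby("treatment")["bray_curtis"].median()
        assert med["FMT"] > med["placebo"]
        table, tests = votu_stability(abund, plan.metadata)
        for sex in ("female", "male"):
            tab = table[table["sex"] == sex].drop(columns="sex")
            prop1 = tab.div(tab.sum(axis=1), axis=0)["n_timepoints_1"]
            prop4 = tab.div(tab.sum(axis=1), axis=0)["n_timepoints_4"]
            assert prop1["FMT"] > prop1["placebo"]
            assert prop4["FMT"] < prop4["placebo"]
            assert sex in tests and tests[sex].p < 0.05

    def test_lifestyle_totals_split(self):
        metadata, abund = toy_cohort_abundance()
        lifestyles = {v: (Lifestyle.temperate if i < 15 else Lifestyle.virulent)
                      for i, v in enumerate(abund.data.index)}
        totals, _ = lifestyle_totals(abund, lifestyles, metadata)
        some = totals.iloc[0]
        expected_total = abund.data[some["sample_id"]].sum()
        assert some["temperate"] + some["virulent"] == pytest.approx(expected_total)
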