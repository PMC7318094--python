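import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neofba.evaluation import (
    bootstrap_delta_r,
    classify_outcome,
    cohens_d_one_sample,
    cohens_d_two_sample,
    goodness_of_fit,
    lmm_adjusted_r,
    pad_outcome_analysis,
    tost_equivalence,
)


class TestGoodnessOfFit:
    def test_identity(self):
        pma = np.linspace(26, 36, 30)
        m = goodness_of_fit(pma, pma)
        assert m.r == pytest.approx(1.0)
        assert m.bias_weeks == 0.0
        assert m.variance_weeks == 0.0
        assert m.pct_within_1wk == 100.0
        assert m.pct_within_2wk == 100.0

    def test_constant_shift(self):
        pma = np.arange(26.0, 36.0, 0.5)  # half-steps: +1 week stays exact
        m = goodness_of_fit(pma + 1.0, pma)
        assert m.bias_weeks == pytest.approx(1.0)
        assert m.variance_weeks == pytest.approx(0.0, abs=1e-12)
        assert m.median_abs_weeks == pytest.approx(1.0)
        assert m.pct_within_1wk == 100.0

    def test_small_error_arithmetic(self):
        pma = np.array([30.0, 30.0, 30.0])
        fba = pma + np.array([0.5, -1.5, 2.5])
        m = goodness_of_fit(fba, pma + np.array([0.0, 1e-9, -1e-9]))
        assert m.median_abs_weeks == pytest.approx(1.5)
        assert m.pct_within_1wk == pytest.approx(100 / 3, abs=0.1)
        assert m.pct_within_2wk == pytest.approx(200 / 3, abs=0.1)

    def test_within_bounds_ordering_always(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            pma = rng.uniform(25, 38, 40)
            fba = pma + rng.normal(0, 2, 40)
            m = goodness_of_fit(fba, pma)
            assert m.pct_within_1wk <= m.pct_within_2wk
            assert -1 <= m.r <= 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            goodness_of_fit(np.full(5, 30.0), np.linspace(26, 36, 5))


class TestBootstrapDeltaR:
    def test_identical_models_zero_ci(self):
        rng = np.random.default_rng(2)
        pma = rng.uniform(25, 38, 50)
        preds = pma + rng.normal(0, 1, 50)
        out = bootstrap_delta_r(preds, preds, pma, n_boot=200, seed=0)
        assert out["delta_r"] == 0.0
        assert out["ci"] == (0.0, 0.0)
        assert not out["significant"]

    def test_perfect_vs_shuffled_significant(self):
        rng = np.random.default_rng(1)
        pma = rng.uniform(25, 38, 200)
        shuffled = rng.permutation(pma)
        out = bootstrap_delta_r(pma, shuffled, pma, n_boot=500, seed=1)
        assert out["ci"][0] > 0
        assert out["significant"]

    def test_ci_width_shrinks_with_smaller_noise(self):
        rng = np.random.default_rng(3)
        pma = rng.uniform(25, 38, 150)
        tight = pma + rng.normal(0, 0.2, 150)
        loose = pma + rng.normal(0, 3.0, 150)
        out = bootstrap_delta_r(tight, loose, pma, n_boot=300, seed=2)
        assert out["delta_r"] > 0
        assert out["significant"]


class TestTOST:
    def test_identical_distributions_equivalent(self):
        rng = np.random.default_rng(3)
        a = np.abs(rng.normal(1.0, 0.5, 100))
        b = np.abs(rng.normal(1.0, 0.5, 100))
        out = tost_equivalence(a, b, boundary_weeks=0.5)
        assert out["equivalent"]
        assert out["p"] < 0.001

    def test_one_week_shift_not_equivalent(self):
        rng = np.random.default_rng(4)
        a = np.abs(rng.normal(2.0, 0.5, 100))
        b = np.abs(rng.normal(1.0, 0.5, 100))
        out = tost_equivalence(a, b, boundary_weeks=0.5)
        assert not out["equivalent"]

    def test_exactly_equal_zero_variance_convention(self):
        a = np.full(10, 1.0)
        out = tost_equivalence(a, a.copy(), boundary_weeks=0.5)
        assert out["p"] == 0.0
        assert out["equivalent"]

    def test_bad_boundary(self):
        with pytest.raises(ValueError):
            tost_equivalence(np.ones(5), np.ones(5), boundary_weeks=0.0)


class TestLMMAdjustedR:
    def test_zero_between_subject_variance_falls_back_to_r(self):
        rng = np.random.default_rng(5)
        pma = np.tile(np.linspace(26, 36, 6), 4)
        subj = np.repeat([f"s{i}" for i in range(4)], 6)
        fba = pma + rng.normal(0, 0.3, len(pma))
        out = lmm_adjusted_r(fba, pma, subj, n_boot=20, seed=0)
        if out["singular"]:
            assert out["r_adjusted"] == pytest.approx(out["r_pooled"])

    def test_offset_trajectories_adjusted_above_pooled(self):
        rng = np.random.default_rng(6)
        rows_fba, rows_pma, rows_subj = [], [], []
        for i in range(10):
            offset = rng.normal(0, 3.0)  # strong per-infant intercept
            pma = np.linspace(26, 34, 4)
            fba = pma + offset + rng.normal(0, 0.2, 4)
            rows_fba.append(fba)
            rows_pma.append(pma)
            rows_subj.append([f"s{i}"] * 4)
        out = lmm_adjusted_r(np.concatenate(rows_fba), np.concatenate(rows_pma),
                             np.concatenate(rows_subj), n_boot=20, seed=1)
        assert out["r_adjusted"] > out["r_pooled"]

    def test_single_recording_per_subject_rejected(self):
        with pytest.raises(ValueError):
            lmm_adjusted_r(np.arange(4.0), np.arange(4.0),
                           np.array(["a", "b", "c", "d"]))


class TestClassifyOutcome:
    @pytest.mark.parametrize(
        "scale,indices,expected",
        [
            ("III", {"cognitive": 90, "language": 95, "motor": 100}, "normal"),
            ("III", {"cognitive": 90, "language": 95, "motor": 65}, "abnormal"),
            ("II", {"mental": 80, "psychomotor": 84}, "mildly_abnormal"),
            ("II", {"mental": 86, "psychomotor": 90}, "normal"),
            ("II", {"mental": 69, "psychomotor": 90}, "abnormal"),
            # boundary values fall to mildly_abnormal by strict inequalities
            ("III", {"cognitive": 85, "language": 95, "motor": 100}, "mildly_abnormal"),
            ("III", {"cognitive": 70, "language": 95, "motor": 100}, "mildly_abnormal"),
        ],
    )
    def test_threshold_rules(self, scale, indices, expected):
        assert classify_outcome(indices, scale) == expected

    def test_partition_is_exhaustive_and_unique(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            idx = {k: float(rng.integers(50, 120))
                   for k in ("cognitive", "language", "motor")}
            assert classify_outcome(idx, "III") in (
                "normal", "mildly_abnormal", "abnormal")

    def test_missing_index_unclassifiable(self):
        with pytest.raises(ValueError):
            classify_outcome({"cognitive": 90, "language": 95}, "III")


class TestEffectSizes:
    def test_one_sample_hedges_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        expect = np.mean(x) / np.std(x, ddof=1) * (1 - 3 / (4 * 5 - 5))
        assert cohens_d_one_sample(x) == pytest.approx(expect)

    def test_two_sample_sign_and_magnitude(self):
        rng = np.random.default_rng(8)
        x = rng.normal(1.0, 1.0, 50)
        y = rng.normal(0.0, 1.0, 50)
        d = cohens_d_two_sample(x, y)
        assert 0.5 < d < 1.6


def make_outcome_records(means, n_per=10, sd=1.0, seed=0, n_serial=3):
    rng = np.random.default_rng(seed)
    rows = []
    for g, mu in zip(("normal", "mildly_abnormal", "abnormal"), means):
        for i in range(n_per):
            rows.append({"subject_id": f"{g}{i}", "group": g,
                         "n_serial_recordings": n_serial,
                         "mean_pad_weeks": rng.normal(mu, sd)})
    return pd.DataFrame(rows)


class TestPadOutcome:
    def test_null_groups_no_significant_pairs(self):
        rec = make_outcome_records((0.0, 0.0, 0.0), n_per=10, sd=0.01, seed=1)
        rep = pad_outcome_analysis(rec)
        assert rep["anova"]["p"] > 0.05 or rep["anova"]["F"] < 1.0
        assert not any(v["significant"] for v in rep["tukey"].values())

    def test_planted_lag_detected(self):
        rec = make_outcome_records((0.0, 0.0, -2.0), n_per=10, sd=1.0, seed=5)
        rep = pad_outcome_analysis(rec)
        assert rep["anova"]["p"] < 0.05
        key = [k for k in rep["tukey"] if "abnormal" in k and "normal" in k
               and "mildly" not in k][0]
        assert rep["tukey"][key]["significant"]
        assert rep["groups"]["abnormal"]["significant_vs_zero"]
        assert rep["groups"]["abnormal"]["mean_pad"] < 0

    def test_min_serial_filter(self):
        rec = make_outcome_records((0.0, 0.0, -2.0), n_per=6, seed=2)
        rec.loc[rec.index[:3], "n_serial_recordings"] = 1
        rep = pad_outcome_analysis(rec, min_serial=3)
        assert rep["n_infants"] == len(rec) - 3

    def test_degenerate_identical_observations_flagged(self):
        rows = []
        for g in ("normal", "abnormal"):
            for i in range(2):
                rows.append({"subject_id": f"{g}{i}", "group": g,
                             "n_serial_recordings": 3, "mean_pad_weeks": 0.5})
        rep = pad_outcome_analysis(pd.DataFrame(rows))
        assert rep["levene"]["degenerate"]

    def test_single_group_rejected(self):
        rec = make_outcome_records((0.0, 0.0, 0.0), n_per=4, seed=3)
        rec = rec[rec["group"] == "normal"]
        with pytest.raises(ValueError):
            pad_outcome_analysis(rec)

    def test_anova_type_one_error_near_nominal(self):
        """Under the null (all groups same distribution) the ANOVA rejects ~5%."""
        rng = np.random.default_rng(12)
        rejections = 0
        n_reps = 1000
        for _ in range(n_reps):
            vals = [rng.normal(0, 1, 10) for _ in range(3)]
            _, p = stats.f_oneway(*vals)
            rejections += p < 0.05
        assert rejections / n_reps == pytest.approx(0.05, abs=0.02)

    def test_tukey_adjusted_p_at_least_unadjusted(self):
        """Tukey p ≥ the unadjusted p of the same pooled-SE contrast."""
        rng = np.random.default_rng(13)
        for _ in range(20):
            rec = make_outcome_records(rng.normal(0, 1, 3), n_per=8,
                                       seed=int(rng.integers(1e6)))
            rep = pad_outcome_analysis(rec)
            groups = {g: rec.loc[rec["group"] == g, "mean_pad_weeks"].to_numpy()
                      for g in rec["group"].unique()}
            n_tot = sum(len(v) for v in groups.values())
            df_w = n_tot - len(groups)
            sp2 = sum((len(v) - 1) * np.var(v, ddof=1) for v in groups.values()) / df_w
            for key, entry in rep["tukey"].items():
                if entry["p_adj"] <= 1e-3:
                    continue  # below the studentized-range table resolution
                g1, g2 = key.split("_vs_")
                a, b = groups[g1], groups[g2]
                se = np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
                t = abs(np.mean(a) - np.mean(b)) / se
                p_raw = 2 * stats.t.sf(t, df_w)
                assert entry["p_adj"] >= p_raw - 1e-9
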