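"""Cohort statistics: aggregation order, tests, coverage curves."""

import numpy as np
import pandas as pd
import pytest

from mmskin.stats import (CohortDataset, GroupComparison, coverage_curves,
                          group_comparison, normalize_by_frequency_mean,
                          paired_diff_test, subject_values, summarize,
                          normality_pvalue)


def tiny_cohort(values_by_subject, site="1F", sc_class="thin", f_hz=25e9):
    """Minimal dataset: one site, three identical repeats per subject."""
    rows = []
    for sid, v in values_by_subject.items():
        for rep in (1, 2, 3):
            rows.append({"subject_id": sid, "age_years": 30.0, "sex": "F",
                         "group": "adult", "site_code": site, "sc_class": sc_class,
                         "probe": "WR42", "f_hz": f_hz, "repeat_index": rep,
                         "s11_db": v})
    return CohortDataset(pd.DataFrame(rows))


class TestSummarize:
    def test_identical_repeats_pass_through(self):
        ds = tiny_cohort({"S0": -3.0, "S1": -4.0})
        out = summarize(ds)
        assert out.loc[0, "mean_db"] == pytest.approx(-3.5)
        assert out.loc[0, "sd_db"] == pytest.approx(0.70710678, rel=1e-6)
        assert out.loc[0, "n"] == 2

    def test_aggregation_order_repeats_then_sites_then_subjects(self):
        # two thin sites with different values: the subject value is the
        # mean of site means, not the pooled repeat mean if repeats differed
        rows = []
        for site, vals in (("1F", [-2.0, -2.0, -2.0]), ("6R", [-4.0, -4.0, -4.0])):
            for rep, v in enumerate(vals, start=1):
                rows.append({"subject_id": "S0", "age_years": 20, "sex": "M",
                             "group": "adult", "site_code": site, "sc_class": "thin",
                             "probe": "WR42", "f_hz": 25e9, "repeat_index": rep,
                             "s11_db": v})
        subj = subject_values(CohortDataset(pd.DataFrame(rows)))
        assert subj["s11_db"].iloc[0] == pytest.approx(-3.0)

    def test_strict_missing_policy_raises(self):
        ds = tiny_cohort({"S0": -3.0, "S1": -4.0})
        clipped = CohortDataset(ds.df.iloc[:-1])
        with pytest.raises(ValueError, match="repeats"):
            summarize(clipped)
        out = summarize(clipped, missing="mean")
        assert out.loc[0, "n"] == 2

    def test_shuffle_invariance(self):
        rng = np.random.default_rng(0)
        ds = tiny_cohort({f"S{i}": rng.normal(-3, 0.2) for i in range(10)})
        shuffled = CohortDataset(ds.df.sample(frac=1, random_state=1)
                                 .reset_index(drop=True))
        pd.testing.assert_frame_equal(summarize(ds), summarize(shuffled))

    def test_site_class_consistency_enforced(self):
        ds = tiny_cohort({"S0": -3.0})
        bad = ds.df.copy()
        bad["sc_class"] = "thick"  # 1F is a thin site
        with pytest.raises(ValueError, match="inconsistent"):
            CohortDataset(bad)


class TestNormality:
    def test_normal_sample_type_one_error_calibration(self):
        rng = np.random.default_rng(123)
        rejections = sum(
            normality_pvalue(rng.normal(-3.0, 0.15, 44)) < 0.05
            for _ in range(1000))
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_bimodal_mixture_rejected_with_high_power(self):
        rng = np.random.default_rng(321)
        rej = sum(
            normality_pvalue(np.where(rng.random(44) < 0.25,
                                    rng.normal(-4.0, 0.15, 44),
                                    rng.normal(-3.0, 0.15, 44))) < 0.01
            for _ in range(200))
        assert rej / 200 > 0.90

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            normality_pvalue([1.0, 2.0])
        with pytest.raises(ValueError):
            normality_pvalue([1.0] * 10)


class TestPairedDiff:
    def test_identical_vectors(self):
        r = paired_diff_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.mean_diff_db == 0.0
        assert r.p == 1.0

    def test_constant_difference_degenerate_ci(self):
        r = paired_diff_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert r.mean_diff_db == 1.0
        assert r.ci95_lo == r.ci95_hi == 1.0
        assert r.p == 0.0

    def test_matches_hand_computed_t(self):
        # pairs (1.0, 0.5), (2.0, 1.2), (3.0, 2.4): d = (0.5, 0.8, 0.6),
        # mean 0.63333, sd 0.152753, t = mean/(sd/sqrt(3)) = 7.181325
        r = paired_diff_test([1.0, 2.0, 3.0], [0.5, 1.2, 2.4])
        assert r.t == pytest.approx(7.181325, rel=1e-6)
        assert r.mean_diff_db == pytest.approx(0.633333, rel=1e-5)
        assert r.p == pytest.approx(0.0188442, rel=1e-4)

    def test_pair_order_permutation_invariance(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(-3, 0.2, 20), rng.normal(-3.6, 0.3, 20)
        perm = rng.permutation(20)
        r1, r2 = paired_diff_test(a, b), paired_diff_test(a[perm], b[perm])
        assert r1.p == pytest.approx(r2.p)
        assert r1.mean_diff_db == pytest.approx(r2.mean_diff_db)

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_diff_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestNormalizationAndGroups:
    def _subject_table(self, offsets):
        rows = []
        for sid, off in offsets.items():
            for f in (20e9, 25e9):
                rows.append({"subject_id": sid, "sc_class": "thin", "probe": "WR42",
                             "f_hz": f, "s11_db": -3.0 - f / 1e10 + off,
                             "age_years": 30, "sex": "F", "group": "adult"})
        return pd.DataFrame(rows)

    def test_residual_means_are_zero_and_idempotent(self):
        tab = self._subject_table({"S0": 0.1, "S1": -0.1, "S2": 0.0})
        out = normalize_by_frequency_mean(tab)
        means = out.groupby("f_hz")["resid_db"].mean()
        assert np.allclose(means, 0.0, atol=1e-12)
        again = normalize_by_frequency_mean(out.assign(s11_db=out["resid_db"]))
        assert np.allclose(out["resid_db"], again["resid_db"], atol=1e-12)

    def test_group_shift_survives_normalization(self):
        # a +0.2 dB offset for half the subjects is frequency-independent
        # and must appear unchanged in the residual group difference
        offsets = {f"S{i}": (0.2 if i < 3 else 0.0) for i in range(6)}
        out = normalize_by_frequency_mean(self._subject_table(offsets))
        shifted = out[out.subject_id.isin(["S0", "S1", "S2"])]["resid_db"]
        rest = out[~out.subject_id.isin(["S0", "S1", "S2"])]["resid_db"]
        assert shifted.mean() - rest.mean() == pytest.approx(0.2, abs=1e-12)

    def test_group_comparison_detects_unequal_variance(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 0.1, 30)
        b = rng.normal(0, 0.5, 30)
        res = group_comparison(a, b)
        assert isinstance(res, GroupComparison)
        assert res.bartlett_p < 0.01

    def test_identical_groups_are_unremarkable(self):
        a = np.array([0.1, -0.1, 0.2, -0.2, 0.0])
        res = group_comparison(a, a.copy())
        assert res.t_p == pytest.approx(1.0)
        assert res.bartlett_p == pytest.approx(1.0)


class TestCoverageCurves:
    def _summary(self):
        return pd.DataFrame({
            "sc_class": ["thin"] * 3, "probe": ["WR42"] * 3,
            "f_hz": [20e9, 25e9, 27.5e9],
            "mean_db": [-2.8, -3.0, -3.2], "sd_db": [0.1, 0.2, 0.0],
            "n": [44] * 3})

    def test_zero_k_returns_mean(self):
        out = coverage_curves(self._summary(), 0)
        assert np.allclose(out["coverage_db"], out["mean_db"])
        assert out["label"].iloc[0] == "mean"

    def test_zero_sd_collapses_all_k(self):
        s = self._summary()
        row = s[s.sd_db == 0].index[0]
        for k in (1, 2):
            out = coverage_curves(s, k)
            assert out.loc[row, "coverage_db"] == s.loc[row, "mean_db"]

    def test_k2_one_sided_empirical_coverage_is_about_97_7(self):
        # mean - 2 sd bounds ~97.7% of a normal population from below
        # (the conventional "95% coverage" label is two-sided language)
        rng = np.random.default_rng(17)
        vals = rng.normal(-3.0, 0.2, 200000)
        bound = vals.mean() - 2 * vals.std(ddof=1)
        frac = (vals > bound).mean()
        assert frac == pytest.approx(0.9772, abs=0.003)
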