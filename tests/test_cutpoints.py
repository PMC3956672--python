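"""Cut-point candidates, stratified splitting, and internal cross-validation."""

import numpy as np
import pandas as pd
import pytest

from igfsurv.cutpoints import (
    decile_scan,
    internal_cross_validation,
    quantile_candidates,
    stratified_split,
    validate_candidate,
)
from igfsurv.scoring import score_cohort


class TestQuantileCandidates:
    def test_even_n_median_averages(self):
        cs = quantile_candidates([1, 2, 3, 4], marker="m")
        named = dict(cs.candidates)
        assert named["median"] == 2.5
        assert named["Q1"] == 1  # lower interpolation: attainable value
        assert named["Q3"] == 3

    def test_matches_sorting_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 10, size=201).astype(float)
        cs = quantile_candidates(x)
        named = dict(cs.candidates)
        s = np.sort(x)
        assert named["median"] == s[100]          # odd n: middle order statistic
        assert named["Q1"] == s[int(np.floor(0.25 * 200))]
        assert named["Q3"] == s[int(np.floor(0.75 * 200))]

    def test_collapsed_distribution_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            cs = quantile_candidates([0, 0, 0, 9])
        assert cs.degenerate

    def test_missing_scores_ignored(self):
        cs = quantile_candidates([1, 2, np.nan, 3, 4, np.nan])
        assert dict(cs.candidates)["median"] == 2.5

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            quantile_candidates([1, 2, 3])


class TestDecileScan:
    @staticmethod
    def _endpoints(rng, n, x, beta):
        t = rng.exponential(scale=60.0 * np.exp(-beta * (x >= 4)))
        c = rng.uniform(10, 150, size=n)
        return {"dfs": (np.minimum(t, c), (t <= c).astype(int))}

    def test_constant_scores_all_missing(self):
        rng = np.random.default_rng(61)
        n = 50
        x = np.full(n, 2.0)
        scan = decile_scan(x, self._endpoints(rng, n, x, 0.0))
        assert scan.deciles["p_dfs"].isna().all()
        assert scan.argmin_dfs is None

    def test_argmin_near_true_change_point(self):
        # hazard changes at score >= 4; the best decile cut should be near 4
        rng = np.random.default_rng(67)
        n = 600
        x = rng.integers(0, 10, size=n).astype(float)
        scan = decile_scan(x, self._endpoints(rng, n, x, 1.5))
        best_cut = float(
            scan.deciles.loc[scan.deciles["decile"] == scan.argmin_dfs, "cut"].iloc[0]
        )
        assert abs(best_cut - 4.0) <= 1.0

    def test_nine_rows_and_no_autoselection(self):
        rng = np.random.default_rng(71)
        n = 100
        x = rng.integers(0, 10, size=n).astype(float)
        scan = decile_scan(x, self._endpoints(rng, n, x, 0.5))
        assert len(scan.deciles) == 9
        assert "multiplicity" in scan.note


class TestStratifiedSplit:
    def test_partition_is_exact(self, default_cohort):
        df = default_cohort.cohort.df
        tr, va = stratified_split(df, 0.5, ["nodes", "surgery"], seed=5)
        assert len(tr) + len(va) == len(df)
        assert len(np.intersect1d(tr, va)) == 0

    def test_per_cell_balance_within_one(self, default_cohort):
        df = default_cohort.cohort.df
        strata = ["nodes", "surgery", "taxane"]
        keys = df[strata].astype(str).agg("|".join, axis=1)
        for seed in range(5):
            tr, _ = stratified_split(df, 0.5, strata, seed=seed)
            in_train = np.zeros(len(df), dtype=bool)
            in_train[tr] = True
            for _, cell in pd.Series(np.arange(len(df))).groupby(keys.to_numpy()):
                k = in_train[cell.to_numpy()].sum()
                assert abs(k - 0.5 * len(cell)) < 1.0

    def test_deterministic_given_seed(self, default_cohort):
        df = default_cohort.cohort.df
        a = stratified_split(df, 0.5, ["nodes"], seed=9)
        b = stratified_split(df, 0.5, ["nodes"], seed=9)
        np.testing.assert_array_equal(a[0], b[0])

    def test_bad_ratio_rejected(self, default_cohort):
        with pytest.raises(ValueError, match="ratio"):
            stratified_split(default_cohort.cohort.df, 1.0, [], seed=0)

    def test_unknown_stratum_rejected(self, default_cohort):
        with pytest.raises(ValueError, match="strata columns"):
            stratified_split(default_cohort.cohort.df, 0.5, ["hair"], seed=0)


class TestInternalCrossValidation:
    def test_deterministic_given_seed(self, default_cohort):
        cohort = default_cohort.cohort
        scores = score_cohort(cohort)["IGF1Ra_IRS"].astype(float)
        kwargs = dict(
            endpoint_time=cohort.df["dfs_months"],
            endpoint_event=cohort.df["dfs_event"],
            marker="IGF1Ra",
            endpoint="dfs",
            n_replications=10,
            strata=["nodes", "surgery"],
            seed=123,
        )
        a = internal_cross_validation(cohort, scores, **kwargs)
        b = internal_cross_validation(cohort, scores, **kwargs)
        pd.testing.assert_frame_equal(a.replications, b.replications)
        assert a.final_cutoff == b.final_cutoff

    def test_final_cutoff_is_median_of_training_medians(self, default_cohort):
        cohort = default_cohort.cohort
        scores = score_cohort(cohort)["IGF1Ra_IRS"].astype(float)
        report = internal_cross_validation(
            cohort,
            scores,
            cohort.df["dfs_months"],
            cohort.df["dfs_event"],
            n_replications=15,
            strata=["nodes"],
            seed=7,
            fit_models=False,
        )
        assert report.final_cutoff == float(np.median(report.replications["cutoff"]))
        # every training cutoff is a plausible marker quantile
        assert report.replications["cutoff"].between(0, 9).all()

    def test_fit_models_false_skips_hazard_ratios(self, default_cohort):
        cohort = default_cohort.cohort
        scores = score_cohort(cohort)["IGF2R_IRS"].astype(float)
        report = internal_cross_validation(
            cohort,
            scores,
            cohort.df["os_months"],
            cohort.df["os_event"],
            n_replications=5,
            seed=1,
            fit_models=False,
        )
        assert "hr_valid" not in report.replications.columns
        assert np.isnan(report.pct_valid_ci_crossing_1)

    def test_validate_candidate_rejects_oscillating_null(self):
        # synthetic report: every validation CI crosses 1, median HR near 1
        reps = pd.DataFrame(
            {
                "replication": range(20),
                "cutoff": [2.0] * 20,
                "hr_train": np.linspace(0.9, 1.1, 20),
                "ci_low_train": 0.7,
                "ci_high_train": 1.4,
                "hr_valid": np.linspace(0.9, 1.1, 20),
                "ci_low_valid": 0.7,
                "ci_high_valid": 1.4,
            }
        )
        from igfsurv.cutpoints import CutoffCVReport

        report = CutoffCVReport(
            marker="m",
            endpoint="dfs",
            quantile=0.5,
            n_replications=20,
            replications=reps,
            final_cutoff=2.0,
            pct_valid_ci_crossing_1=100.0,
        )
        decision = validate_candidate(report)
        assert not decision.accepted
        assert "oscillates" in decision.rationale

    def test_validate_candidate_accepts_stable_effect(self):
        reps = pd.DataFrame(
            {
                "replication": range(20),
                "cutoff": [2.0] * 20,
                "hr_train": 0.5,
                "ci_low_train": 0.35,
                "ci_high_train": 0.7,
                "hr_valid": 0.55,
                "ci_low_valid": 0.38,
                "ci_high_valid": 0.8,
            }
        )
        from igfsurv.cutpoints import CutoffCVReport

        report = CutoffCVReport(
            marker="m",
            endpoint="dfs",
            quantile=0.5,
            n_replications=20,
            replications=reps,
            final_cutoff=2.0,
            pct_valid_ci_crossing_1=0.0,
        )
        assert validate_candidate(report).accepted

    def test_validate_candidate_no_fits_rejected(self):
        from igfsurv.cutpoints import CutoffCVReport

        reps = pd.DataFrame(
            {"replication": [0], "cutoff": [2.0], "hr_valid": [np.nan]}
        )
        report = CutoffCVReport(
            marker="m", endpoint="dfs", quantile=0.5, n_replications=1,
            replications=reps,
        )
        with pytest.raises(ValueError, match="no convergent validation fits"):
            validate_candidate(report)
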