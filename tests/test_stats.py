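"""Statistical layer: Box-Cox MLE behaviour, the mixed-effects pairwise
screen (including its missing-data accounting and two-stage oracle),
cross-validated predictive power, and single-linkage clustering."""

import numpy as np
import pandas as pd
import pytest

from mpmr import stats


def _grouped_data(rng, n_groups=5, n_per=100, beta=0.0, slope_sd=0.0,
                  intercept_sd=0.5, noise_sd=1.0):
    rows = []
    for g in range(n_groups):
        b0 = rng.normal(0, intercept_sd)
        b1 = beta + rng.normal(0, slope_sd)
        x = rng.normal(0, 1, n_per)
        y = b0 + b1 * x + rng.normal(0, noise_sd, n_per)
        rows.append(pd.DataFrame({"tumour_id": g + 1, "x": x, "y": y}))
    return pd.concat(rows, ignore_index=True)


class TestBoxCox:
    def test_lognormal_lambda_near_zero(self):
        rng = np.random.default_rng(0)
        _, lam = stats.boxcox_normalize(np.exp(rng.normal(0, 1, 1000)))
        assert abs(lam) < 0.15

    def test_normal_lambda_near_one(self):
        rng = np.random.default_rng(1)
        _, lam = stats.boxcox_normalize(rng.normal(10, 1, 1000))
        assert abs(lam - 1) < 0.3

    def test_constant_input_warns_identity(self):
        with pytest.warns(UserWarning):
            out, lam = stats.boxcox_normalize(np.full(20, 3.0))
        assert lam == 1.0 and np.all(out == 3.0)

    def test_nonpositive_values_shifted(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 200)  # includes negatives
        out, _ = stats.boxcox_normalize(x)
        assert np.all(np.isfinite(out))


class TestPairwiseMixed:
    def test_perfect_linear_relation(self):
        rng = np.random.default_rng(3)
        data = _grouped_data(rng, beta=1.0, intercept_sd=0.0, noise_sd=1e-12)
        data["y"] = data["x"]
        res = stats.fit_pairwise_mixed(data, "x", "y", transform="none")
        assert res.r == pytest.approx(1.0, abs=1e-6)
        assert res.p < 1e-10 and res.significant

    def test_n_equals_complete_cases(self):
        rng = np.random.default_rng(4)
        data = _grouped_data(rng, beta=0.5)
        data.loc[data.sample(60, random_state=0).index, "x"] = np.nan
        data.loc[data.sample(40, random_state=1).index, "y"] = np.nan
        res = stats.fit_pairwise_mixed(data, "x", "y")
        assert res.n == len(data[["x", "y"]].dropna())

    def test_two_stage_oracle_random_intercept_data(self):
        """On random-intercept-only data the mixed-model fixed slope agrees
        with the average of per-tumour OLS slopes within its standard error."""
        rng = np.random.default_rng(5)
        data = _grouped_data(rng, n_per=200, beta=0.4, slope_sd=0.0,
                             intercept_sd=1.0, noise_sd=0.5)
        res = stats.fit_pairwise_mixed(data, "x", "y", transform="none")
        slopes = [np.polyfit(sub["x"], sub["y"], 1)[0]
                  for _, sub in data.groupby("tumour_id")]
        # compare on the standardized scale used by the model
        sx = data["x"].std(ddof=1)
        sy = data["y"].std(ddof=1)
        assert res.r == pytest.approx(np.mean(slopes) * sx / sy, abs=2 * res.se)

    def test_too_few_groups_rejected(self):
        rng = np.random.default_rng(6)
        data = _grouped_data(rng, n_groups=1)
        with pytest.raises(ValueError):
            stats.fit_pairwise_mixed(data, "x", "y")

    def test_null_data_rarely_significant(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(25):
            data = _grouped_data(rng, n_per=100, beta=0.0)
            res = stats.fit_pairwise_mixed(data, "x", "y", transform="none")
            hits += res.significant
        assert hits == 0  # threshold 5e-4 on null data


class TestPredictivePower:
    def test_exact_linear_near_zero_error(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 100)
        df = pd.DataFrame({"tumour_id": 1, "x": x, "y": 3.0 + 2.0 * x})
        pp = stats.predictive_power_cv(df, "x", "y", seed=0)
        assert pp.npmse < 1e-20

    def test_uninformative_predictor_closed_form(self):
        # y = mu + eps with x useless: npmse ~ sigma^2 / mu^2
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"tumour_id": 1, "x": rng.normal(0, 1, 200),
                           "y": 10.0 + rng.normal(0, 1.0, 200)})
        pp = stats.predictive_power_cv(df, "x", "y", seed=1)
        assert pp.npmse == pytest.approx(0.01, rel=0.3)

    def test_seed_determinism_and_row_order_stability(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame({"tumour_id": 1, "x": rng.normal(0, 1, 200),
                           "y": 10.0 + rng.normal(0, 1.0, 200)})
        a = stats.predictive_power_cv(df, "x", "y", seed=5)
        b = stats.predictive_power_cv(df, "x", "y", seed=5)
        assert a.npmse == b.npmse
        shuffled = df.sample(frac=1.0, random_state=2).reset_index(drop=True)
        c = stats.predictive_power_cv(shuffled, "x", "y", seed=5)
        assert abs(c.npmse - a.npmse) / a.npmse < 0.05

    def test_too_few_observations_returns_none(self):
        df = pd.DataFrame({"tumour_id": 1, "x": [1, 2, 3], "y": [1, 2, 3]})
        assert stats.predictive_power_cv(df, "x", "y", k=5, seed=0) is None


class TestClustering:
    def test_duplicated_column_merges_first_at_zero(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({"a": rng.normal(10, 1, 100)})
        df["b"] = df["a"]
        df["c"] = rng.normal(10, 1, 100)
        df["d"] = rng.normal(10, 1, 100)
        tree = stats.cluster_parameters(df, ["a", "b", "c", "d"])
        first = tree.merges[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-8)

    def test_derived_enhancement_features_cluster_together(self):
        # CER = SEmax + 1 carries identical information: the pair must merge
        # before joining anything else
        rng = np.random.default_rng(12)
        df = pd.DataFrame({
            "SEmax": np.exp(rng.normal(0, 0.4, 200)),
            "T1": rng.normal(1500, 200, 200),
            "D": rng.normal(1.0, 0.2, 200),
        })
        df["CER"] = df["SEmax"] + 1.0
        tree = stats.cluster_parameters(df, ["SEmax", "CER", "T1", "D"])
        names = tree.leaf_names
        first = {names[int(tree.merges[0][0])], names[int(tree.merges[0][1])]}
        assert first == {"SEmax", "CER"}

    def test_exchangeable_noise_columns_merge_at_similar_heights(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame(rng.normal(0, 1, (500, 3)), columns=list("abc"))
        tree = stats.cluster_parameters(df, ["a", "b", "c"], transform="none")
        heights = tree.merges[:, 2]
        assert heights.max() / heights.min() < 1.1

    def test_monotone_distance_invariance_of_merge_order(self):
        # single linkage merge order depends only on distance ranks: scaling
        # all variables by a constant preserves the tree topology
        rng = np.random.default_rng(14)
        df = pd.DataFrame(rng.normal(0, 1, (100, 4)), columns=list("abcd"))
        t1 = stats.cluster_parameters(df, list("abcd"), transform="none")
        t2 = stats.cluster_parameters(df * 3.0, list("abcd"), transform="none")
        assert np.array_equal(t1.merges[:, :2], t2.merges[:, :2])

    def test_too_few_rows_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0], "c": [0.0, 1.0]})
        with pytest.raises(ValueError):
            stats.cluster_parameters(df, ["a", "b", "c"])
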