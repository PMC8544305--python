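"""Clock construction: splits, the three families, prediction, evaluation."""

import numpy as np
import pytest

from methylaging.clocks import (
    ClockFit,
    ElasticNetClock,
    LinearTopKClock,
    PCAClock,
    compare_groups,
    compare_overfit,
    evaluate,
    split_train_test,
)

from conftest import make_dataset

GROUP_SIZES = {"61d": 7, "122d": 6, "152d": 6, "183d": 8, "274d": 6, "365d": 8, "426d": 6}


def cohort(n_sites=60, noise=0.0, seed=0, log_sites=False):
    """47-sample cohort; site percent is affine in age (or log10 age)."""
    rng = np.random.default_rng(seed)
    ages = np.concatenate([[float(a[:-1])] * n for a, n in GROUP_SIZES.items()])
    groups = np.concatenate([[a] * n for a, n in GROUP_SIZES.items()])
    x = np.log10(ages) if log_sites else ages
    x01 = (x - x.min()) / (x.max() - x.min())
    slopes = rng.uniform(-60, 60, n_sites)
    inter = rng.uniform(20, 60, n_sites)
    pct = np.clip(inter[:, None] + slopes[:, None] * x01[None, :], 0, 100)
    pct += rng.normal(0, noise, pct.shape)
    pct = np.clip(pct, 0, 100)
    return make_dataset(pct, ages=ages, groups=list(groups), coverage=1000)


class TestSplit:
    def test_study_shape_gives_37_10(self):
        ds = cohort()
        train, test = split_train_test(ds, 10, seed=4)
        assert len(train) == 37 and len(test) == 10

    def test_deterministic_under_seed(self):
        ds = cohort()
        assert split_train_test(ds, 10, seed=9) == split_train_test(ds, 10, seed=9)

    def test_partition_of_samples(self):
        ds = cohort()
        train, test = split_train_test(ds, 10, seed=1)
        assert sorted(train + test) == sorted(ds.sample_ids)
        assert not set(train) & set(test)

    def test_one_or_two_per_group(self):
        ds = cohort()
        _, test = split_train_test(ds, 10, seed=2)
        groups = ds.samples.set_index("sample_id")["group"]
        counts = groups.loc[test].value_counts()
        assert set(counts.index) == set(GROUP_SIZES)
        assert counts.between(1, 2).all()

    def test_infeasible_test_size_rejected(self):
        ds = cohort()
        with pytest.raises(ValueError):
            split_train_test(ds, 20, seed=0)


class TestLinearTopK:
    def test_spacing_rule_skips_close_site(self):
        import pandas as pd

        from methylaging.dataset import MethylationDataset

        ages = np.array([61.0, 122, 183, 244, 305, 366])
        # r ranking: A > B > C; B within 100 bp of A on the same chromosome
        a = (ages - 61) / 305 * 50 + 10
        b = a * 0.98 + np.array([0.5, -0.4, 0.3, -0.2, 0.1, -0.3])
        c = a * 0.9 + np.array([2, -2, 1.5, -1, 0.5, -1.5])
        sites = pd.DataFrame(
            {"chrom": ["chr1", "chr1", "chr2"], "pos": [100, 150, 5000], "strand": "+"}
        )
        samples = pd.DataFrame(
            {
                "sample_id": [f"s{j}" for j in range(6)],
                "age_days": ages,
                "batch": "b1",
                "dose": np.nan,
                "group": [f"g{j}" for j in range(6)],
            }
        )
        pct = np.vstack([a, b, c])
        ds = MethylationDataset(sites, samples, pct, 100 - pct)
        fit = LinearTopKClock(ds, k=2).fit()
        assert set(fit.site_keys) == {"chr1:100:+", "chr2:5000:+"}

    def test_exact_ols_recovery(self):
        # age = 2 * percent(site1) + 10, other sites pure noise
        ages = np.linspace(70, 170, 12)
        s1 = (ages - 10) / 2.0
        rng = np.random.default_rng(0)
        noise = rng.uniform(0, 100, (3, 12))
        ds = make_dataset(np.vstack([s1, noise]), ages=ages, coverage=1000)
        fit = LinearTopKClock(ds, k=1).fit()
        assert fit.site_keys == ["chr1:1000:+"]
        assert fit.weights[0] == pytest.approx(2.0, abs=1e-8)
        assert fit.intercept == pytest.approx(10.0, abs=1e-6)

    def test_too_few_sites_after_spacing(self):
        ds = cohort(n_sites=3)
        ds.sites["pos"] = [100, 150, 180]  # all within 100 bp on chr1
        with pytest.raises(ValueError):
            LinearTopKClock(ds, k=2).fit()


class TestElasticNet:
    def test_lambda_zero_matches_ols(self):
        ds = cohort(n_sites=5, noise=1.0, seed=3)
        fit = ElasticNetClock(ds, lambda_=0).fit()
        # closed-form OLS oracle on [1, X]
        y = np.log10(ds.ages())
        X = np.column_stack([np.ones(ds.n_samples), ds.percent.T])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        pred_ols = 10 ** (X @ beta)
        np.testing.assert_allclose(fit.predict(ds), pred_ols, atol=1e-6)

    def test_lambda_infinity_all_weights_zero(self):
        ds = cohort(n_sites=20, noise=1.0, seed=4)
        fit = ElasticNetClock(ds, lambda_=1e6).fit()
        assert len(fit.weights) == 0
        np.testing.assert_allclose(
            fit.predict(ds), 10 ** np.mean(np.log10(ds.ages())), rtol=1e-12
        )

    def test_predictions_backtransformed_to_days(self):
        ds = cohort(n_sites=10, seed=5)
        fit = ElasticNetClock(ds, lambda_=0.01).fit()
        assert fit.age_transform == "log10"
        preds = fit.predict(ds)
        assert preds.min() > 0
        assert 20 < np.median(preds) < 600  # day scale, not log scale

    def test_loo_cv_deterministic(self):
        ds = cohort(n_sites=30, noise=2.0, seed=6)
        f1 = ElasticNetClock(ds).fit()
        f2 = ElasticNetClock(ds).fit()
        assert f1.extras["lambda"] == f2.extras["lambda"]
        assert f1.extras["cv_mse"] == f2.extras["cv_mse"]

    def test_constant_response_rejected(self):
        ds = cohort(n_sites=5)
        ds.samples["age_days"] = 100.0
        with pytest.raises(ValueError):
            ElasticNetClock(ds).fit()


class TestPCAClock:
    def test_perfect_sites_give_perfect_predictions(self):
        ages = np.linspace(61, 426, 12)
        pct = np.vstack([ages / 5.0] * 6)  # every site proportional to age
        pct += np.arange(6)[:, None]  # distinct offsets, same shape
        ds = make_dataset(pct, ages=ages, coverage=1000)
        fit = PCAClock(ds).fit()
        assert fit.extras["pc1_variance_explained"] == pytest.approx(1.0)
        np.testing.assert_allclose(fit.predict(ds), ages, atol=1e-8)

    def test_orientation_invariance(self):
        ds = cohort(n_sites=25, noise=1.0, seed=8)
        fit = PCAClock(ds).fit()
        flipped = ClockFit(
            family="pca",
            site_keys=fit.site_keys,
            weights=fit.weights,
            intercept=fit.intercept,
            age_transform=fit.age_transform,
        )
        # the stored flattened form already absorbs the orientation; loadings
        # sign cannot change predictions
        np.testing.assert_allclose(flipped.predict(ds), fit.predict(ds))
        assert np.corrcoef(fit.predict(ds), ds.ages())[0, 1] > 0

    def test_variance_explained_matches_eigendecomposition(self):
        ds = cohort(n_sites=15, noise=3.0, seed=9)
        fit = PCAClock(ds).fit()
        pct = ds.percent
        rows = [i for i, k in enumerate(ds.site_keys()) if k in set(fit.site_keys)]
        X = pct[rows].T
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        evals = np.linalg.eigvalsh(np.cov(Z.T, ddof=1) * (len(X) - 1))
        expected = evals[-1] / evals.sum()
        assert fit.extras["pc1_variance_explained"] == pytest.approx(expected, rel=1e-9)

    def test_too_few_selected_rejected(self):
        ds = cohort(n_sites=5, noise=40.0, seed=10)
        with pytest.raises(ValueError):
            PCAClock(ds, rho_threshold=0.999).fit()


class TestPredictAndSerialize:
    def test_training_predictions_reproduced(self):
        ds = cohort(n_sites=12, noise=1.0, seed=11)
        fit = LinearTopKClock(ds, k=5).fit()
        np.testing.assert_allclose(fit.predict(ds), fit.train_predictions)

    def test_all_sites_absent_gives_intercept(self):
        ds = cohort(n_sites=12, noise=1.0, seed=12)
        fit = LinearTopKClock(ds, k=5).fit()
        other = cohort(n_sites=4, seed=13)
        other.sites["chrom"] = "chrZ"
        other = type(other)(other.sites, other.samples, other.meth, other.unmeth)
        np.testing.assert_allclose(fit.predict(other), fit.intercept)

    def test_removing_one_site_shifts_linearly(self):
        ds = cohort(n_sites=12, noise=1.0, seed=14)
        fit = LinearTopKClock(ds, k=5).fit()
        key = fit.site_keys[2]
        w = fit.weights[2]
        keys = list(ds.site_keys())
        i = keys.index(key)
        v = ds.percent[i, 0]
        ds2 = ds.subset_sites(np.array([j for j in range(ds.n_sites) if j != i]))
        delta = fit.predict(ds)[0] - fit.predict(ds2)[0]
        assert delta == pytest.approx(w * v, rel=1e-9)

    def test_json_roundtrip_bit_identical(self, tmp_path):
        ds = cohort(n_sites=30, noise=2.0, seed=15)
        for model in (LinearTopKClock(ds, k=5), ElasticNetClock(ds, lambda_=0.01), PCAClock(ds)):
            fit = model.fit()
            path = tmp_path / f"{fit.family}.json"
            fit.to_json(path)
            back = ClockFit.from_json(path)
            np.testing.assert_array_equal(back.predict(ds), fit.predict(ds))


class TestEvaluation:
    def test_perfect_predictions(self):
        ev = evaluate([61, 122, 183], [61, 122, 183])
        assert ev.mae == 0.0 and ev.r2 == 1.0

    def test_mae_worked_example(self):
        ev = evaluate([100, 200], [110, 190])
        assert ev.mae == pytest.approx(10.0)

    def test_compare_overfit_detects_gap(self):
        rng = np.random.default_rng(16)
        truth = np.linspace(61, 426, 30)
        train = evaluate(truth + rng.normal(0, 1, 30), truth, "train")
        test = evaluate(truth + rng.normal(0, 80, 30), truth, "test")
        res = compare_overfit(train, test)
        assert res["p"] < 0.01 and res["test_mae"] > res["train_mae"]

    def test_anova_distinguishes_shifted_groups(self):
        rng = np.random.default_rng(17)
        groups = np.repeat(["a", "b", "c"], 20)
        preds = rng.normal(200, 5, 60) + np.repeat([0, 0, 50], 20)
        res = compare_groups(preds, groups)
        assert res["p"] < 1e-6

    def test_anova_requires_two_groups(self):
        with pytest.raises(ValueError):
            compare_groups(np.ones(5), np.array(["a"] * 5))


class TestNoiselessLinearAging:
    def test_all_families_reach_two_percent_mae(self):
        """On noiseless synthetic linear aging every family nails the test set."""
        ds = cohort(n_sites=40, noise=0.0, seed=18)
        train_ids, test_ids = split_train_test(ds, 10, seed=18)
        train, test = ds.subset_samples(train_ids), ds.subset_samples(test_ids)
        age_range = ds.ages().max() - ds.ages().min()
        for model in (
            LinearTopKClock(train, k=5),
            ElasticNetClock(train),
            PCAClock(train),
        ):
            fit = model.fit()
            assert fit.evaluate(test).mae < 0.02 * age_range, fit.family
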