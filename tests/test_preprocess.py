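"""The preprocessing chain: filter, normalize, unite, impute, variance drop."""

import numpy as np
import pandas as pd
import pytest

from methylaging.dataset import MethylationDataset
from methylaging.preprocess import (
    drop_near_zero_variance,
    filter_by_coverage,
    impute_knn,
    normalize_coverage,
    preprocess_chain,
    unite_sites,
)

from conftest import make_dataset


def dataset_with_coverage(coverages, percents=50.0):
    """One site per row of ``coverages`` (n_sites x n_samples total coverage)."""
    cov = np.asarray(coverages, dtype=float)
    pct = np.broadcast_to(np.asarray(percents, dtype=float), cov.shape)
    meth = np.round(cov * pct / 100.0)
    sites = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(1, cov.shape[0] + 1) * 10, "strand": "+"}
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{j}" for j in range(cov.shape[1])],
            "age_days": 100.0,
            "batch": "b1",
            "dose": np.nan,
            "group": "g",
        }
    )
    return MethylationDataset(sites, samples, meth, cov - meth)


class TestCoverageFilter:
    @pytest.mark.parametrize(
        "cov,kept", [(4, False), (5, True), (50, True), (100, True), (101, False)]
    )
    def test_inclusive_bounds(self, cov, kept):
        ds = dataset_with_coverage([[cov, 50]])
        out = filter_by_coverage(ds)
        if kept:
            assert np.isfinite(out.percent[0, 0])
        else:
            assert np.isnan(out.percent[0, 0])

    def test_uniform_mid_coverage_unchanged(self):
        ds = dataset_with_coverage(np.full((5, 4), 50))
        out = filter_by_coverage(ds)
        np.testing.assert_array_equal(out.meth, ds.meth)

    def test_site_below_threshold_everywhere_removed(self):
        ds = dataset_with_coverage([[4, 4, 4], [50, 50, 50]])
        out = filter_by_coverage(ds)
        assert out.n_sites == 1

    def test_inverted_bounds_rejected(self):
        ds = dataset_with_coverage([[50]])
        with pytest.raises(ValueError):
            filter_by_coverage(ds, min_cov=10, max_cov=5)


class TestNormalizeCoverage:
    def test_identical_distributions_unchanged(self):
        ds = dataset_with_coverage(np.tile([[10], [20], [30]], (1, 4)))
        out = normalize_coverage(ds)
        np.testing.assert_array_equal(out.coverage, ds.coverage)

    def test_median_scaling_factors(self):
        # sample medians 10 and 40 -> reference 25 -> factors 2.5 and 0.625
        cov = np.array([[10, 40], [10, 40], [10, 40]])
        ds = dataset_with_coverage(cov, percents=50.0)
        out = normalize_coverage(ds)
        np.testing.assert_array_equal(out.coverage[:, 0], [25, 25, 25])
        np.testing.assert_array_equal(out.coverage[:, 1], [25, 25, 25])

    def test_fraction_preserved_within_rounding(self, aging_small):
        ds, _ = aging_small
        f = filter_by_coverage(ds)
        out = normalize_coverage(f)
        before = f.percent / 100.0
        after = out.percent / 100.0
        cov = out.coverage
        ok = np.isfinite(before) & np.isfinite(after) & (cov > 0)
        assert np.all(np.abs(before[ok] - after[ok]) <= 1.0 / (2 * cov[ok]) + 1e-12)

    def test_per_sample_medians_match_reference(self, aging_small):
        ds, _ = aging_small
        out = normalize_coverage(filter_by_coverage(ds))
        medians = np.nanmedian(out.coverage, axis=0)
        assert np.all(np.abs(medians - np.median(medians)) <= 1.0)

    def test_zero_median_rejected(self):
        cov = np.array([[0, 10], [0, 10]])
        ds = dataset_with_coverage(cov)
        ds.meth[:, 0] = np.nan
        ds.unmeth[:, 0] = np.nan
        with pytest.raises(ValueError):
            normalize_coverage(ds)


class TestUniteSites:
    def _dataset(self, observed_per_group):
        """7 samples in each of two groups; per site, mask cells to leave the
        requested number observed in each group."""
        n_sites = len(observed_per_group)
        cov = np.full((n_sites, 14), 50.0)
        ds = dataset_with_coverage(cov)
        ds.samples["group"] = ["g1"] * 7 + ["g2"] * 7
        for i, (n1, n2) in enumerate(observed_per_group):
            ds.meth[i, n1:7] = np.nan
            ds.unmeth[i, n1:7] = np.nan
            ds.meth[i, 7 + n2 :] = np.nan
            ds.unmeth[i, 7 + n2 :] = np.nan
        return ds

    def test_boundary_five_of_seven_kept(self):
        out = unite_sites(self._dataset([(5, 5)]), min_per_group=5)
        assert out.n_sites == 1

    def test_four_in_one_group_dropped(self):
        out = unite_sites(self._dataset([(4, 7), (7, 7)]), min_per_group=5)
        assert out.n_sites == 1

    def test_small_group_unsatisfiable(self):
        ds = self._dataset([(5, 5)])
        ds.samples["group"] = ["g1"] * 3 + ["g2"] * 11
        with pytest.raises(ValueError, match="unsatisfiable"):
            unite_sites(ds, min_per_group=5)

    def test_surviving_counts_unaltered(self):
        ds = self._dataset([(5, 5), (7, 7)])
        out = unite_sites(ds, min_per_group=5)
        obs = np.isfinite(out.meth)
        np.testing.assert_array_equal(out.meth[obs], ds.meth[np.isfinite(ds.meth)])


class TestImputeKnn:
    def test_four_identical_neighbours(self):
        pct = np.full((6, 5), 50.0)
        pct[0] = [10, 10, 10, 10, 10]  # distant site
        ds = make_dataset(pct, ages=[1, 2, 3, 4, 5])
        ds.meth[2, 1] = np.nan
        ds.unmeth[2, 1] = np.nan
        out = impute_knn(ds, k=4)
        assert out.percent[2, 1] == 50.0

    def test_no_missing_is_identity(self):
        pct = np.random.default_rng(1).uniform(0, 100, (8, 5))
        ds = make_dataset(pct, ages=[1, 2, 3, 4, 5], coverage=100)
        out = impute_knn(ds, k=3)
        np.testing.assert_allclose(out.percent, ds.percent)

    def test_k1_matches_bruteforce_nearest(self):
        rng = np.random.default_rng(7)
        pct = rng.uniform(0, 100, (30, 6))
        ds = make_dataset(pct, ages=[1, 2, 3, 4, 5, 6], coverage=100)
        miss = rng.random(pct.shape) < 0.1
        ds.meth[miss] = np.nan
        ds.unmeth[miss] = np.nan
        obs = np.isfinite(ds.percent)
        if not obs.all(axis=1).all():
            pass
        out = impute_knn(ds, k=1)
        pobs = ds.percent
        for i in range(ds.n_sites):
            for s in np.flatnonzero(~obs[i]):
                best = None
                for j in range(ds.n_sites):
                    if j == i:
                        continue
                    common = obs[i] & obs[j]
                    if not common.any() or not obs[j, s]:
                        continue
                    dist = float(np.sqrt(((pobs[i, common] - pobs[j, common]) ** 2).sum()))
                    if best is None or dist < best[0]:
                        best = (dist, j)
                assert out.percent[i, s] == pobs[best[1], s]

    def test_too_few_sites_rejected(self):
        ds = make_dataset(np.full((3, 4), 50.0), ages=[1, 2, 3, 4])
        with pytest.raises(ValueError):
            impute_knn(ds, k=4)


class TestNearZeroVariance:
    def _from_values(self, values):
        pct = np.array([values], dtype=float)
        return make_dataset(pct, ages=np.arange(pct.shape[1]) + 1.0, coverage=100)

    def test_constant_site_dropped(self):
        ds = self._from_values([50.0] * 47)
        assert drop_near_zero_variance(ds).n_sites == 0

    def test_all_distinct_site_kept(self):
        ds = self._from_values(list(np.linspace(1, 99, 47)))
        assert drop_near_zero_variance(ds).n_sites == 1

    def test_frequency_ratio_exactly_19_kept(self):
        # 38 copies of one value, 2 of another: ratio 19 is not > 19
        values = [50.0] * 38 + [60.0] * 2
        ds = self._from_values(values)
        assert drop_near_zero_variance(ds).n_sites == 1

    def test_frequency_ratio_above_19_and_low_uniqueness_dropped(self):
        values = [50.0] * 39 + [60.0] * 2  # ratio 19.5, 2/41 distinct
        ds = self._from_values(values)
        assert drop_near_zero_variance(ds).n_sites == 0


class TestChain:
    def test_idempotent_from_second_application(self, aging_small):
        ds, _ = aging_small
        once = preprocess_chain(ds)
        twice = preprocess_chain(once)
        assert twice.n_sites == once.n_sites
        np.testing.assert_allclose(twice.percent, once.percent)

    def test_sample_order_preserved(self, preprocessed_small, aging_small):
        ds, _ = aging_small
        assert preprocessed_small.sample_ids == ds.sample_ids
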