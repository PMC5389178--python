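"""Site intersection, normalization, age transform, elastic net, calibration."""

import numpy as np
import pandas as pd
import pytest

from epiclock import (ClockModel, fit_calibration, intersect_usable_sites,
                      inverse_transform_age, quantile_normalize, standardize,
                      train_elastic_net, transform_age)
from epiclock.clock_train import DEFAULT_ALPHA_GRID
from epiclock.io_rrbs import CpGSite
from conftest import make_matrix


class TestIntersectUsableSites:
    def test_one_low_sample_excludes_site(self):
        total = np.array([[5, 5, 4], [5, 6, 7]])
        m = make_matrix(np.zeros_like(total), total)
        idx = intersect_usable_sites([m])
        assert len(idx) == 1 and idx[0][1] == 110

    def test_sex_and_mito_chroms_excluded(self):
        sites = [CpGSite("chrX", 10), CpGSite("chrY", 10), CpGSite("chrM", 10),
                 CpGSite("chr1", 10)]
        total = np.full((4, 2), 30)
        m = make_matrix(np.zeros_like(total), total, sites=sites)
        idx = intersect_usable_sites([m])
        assert [c for c, _ in idx] == ["chr1"]

    def test_empty_result_names_most_restrictive_sample(self):
        total = np.array([[5, 0], [5, 0]])
        m = make_matrix(np.zeros_like(total), total)
        with pytest.raises(ValueError, match="s2"):
            intersect_usable_sites([m])

    def test_random_tensor_vs_brute_force(self, rng):
        from conftest import random_matrix
        mats = [random_matrix(np.random.default_rng(s), n_sites=40, n_samples=3,
                              prefix=f"d{s}_") for s in (5, 6)]
        common = set(mats[0].sites) & set(mats[1].sites)
        expected = set()
        for s in common:
            ok = all(all(m.total.loc[(s.chrom, s.pos)] >= 5) for m in mats)
            if ok and s.chrom not in ("chrX", "chrY", "chrM"):
                expected.add(s)
        # restrict both matrices to the union so intersection is well-defined
        idx = intersect_usable_sites(
            [m.subset_sites(sorted(common)) for m in mats]) if expected else None
        if expected:
            assert {CpGSite(c, int(p)) for c, p in idx} == expected


class TestQuantileNormalize:
    def test_hand_computed_reference(self):
        df = pd.DataFrame({"a": [0.0, 0.5, 1.0], "b": [0.2, 0.4, 0.6]})
        out, ref = quantile_normalize(df)
        assert list(ref) == pytest.approx([0.1, 0.45, 0.8])
        assert list(out["a"]) == pytest.approx([0.1, 0.45, 0.8])
        assert list(out["b"]) == pytest.approx([0.1, 0.45, 0.8])

    def test_idempotent_when_columns_share_multiset(self):
        df = pd.DataFrame({"a": [0.3, 0.1, 0.2], "b": [0.1, 0.2, 0.3]})
        out, _ = quantile_normalize(df)
        pd.testing.assert_frame_equal(out, df, check_exact=False)

    def test_ties_get_mean_of_tied_reference_values(self):
        df = pd.DataFrame({"a": [0.5, 0.5, 0.9], "b": [0.0, 0.4, 0.8]})
        out, ref = quantile_normalize(df)
        assert out["a"][0] == pytest.approx((ref[0] + ref[1]) / 2)
        assert out["a"][1] == pytest.approx((ref[0] + ref[1]) / 2)

    def test_columns_identical_distributions_afterwards(self, rng):
        df = pd.DataFrame(rng.random((50, 6)))
        out, ref = quantile_normalize(df)
        for c in out.columns:
            assert np.allclose(np.sort(out[c].to_numpy()), ref)

    def test_missing_cells_rejected(self):
        df = pd.DataFrame({"a": [0.1, np.nan], "b": [0.2, 0.3]})
        with pytest.raises(ValueError, match="missing"):
            quantile_normalize(df)


class TestStandardize:
    def test_two_sample_hand_computation(self):
        df = pd.DataFrame({"a": [0.0], "b": [1.0]})
        z, means, sds = standardize(df)
        # sample sd with n-1: sd = 0.7071..., z = -/+ 1/sqrt(2)
        assert list(z.iloc[0]) == pytest.approx([-0.70710678, 0.70710678])
        assert means[0] == pytest.approx(0.5)
        assert sds[0] == pytest.approx(np.sqrt(0.5))

    def test_idempotent_on_standardized_input(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 8)))
        z1, _, _ = standardize(df)
        z2, _, _ = standardize(z1)
        assert np.allclose(z1.to_numpy(), z2.to_numpy())
        assert np.allclose(z1.to_numpy().mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z1.to_numpy().std(axis=1, ddof=1), 1)

    def test_constant_site_rejected_with_listing(self):
        df = pd.DataFrame({"a": [0.5, 0.1], "b": [0.5, 0.9]},
                          index=pd.MultiIndex.from_tuples([("chr1", 7), ("chr1", 8)]))
        with pytest.raises(ValueError, match="chr1"):
            standardize(df)


class TestTransformAge:
    def test_newborn_is_ln3(self):
        assert transform_age(0.0) == pytest.approx(np.log(3.0))

    def test_round_trip(self, rng):
        ages = rng.uniform(-2.9, 100, size=20)
        assert np.allclose(inverse_transform_age(transform_age(ages)), ages)

    def test_at_or_below_negative_offset_rejected(self):
        with pytest.raises(ValueError):
            transform_age(-3.0)


class TestTrainElasticNet:
    def _planted(self, rng, n=80, p=300, k=5, noise=0.0):
        X = rng.normal(size=(n, p))
        beta = np.zeros(p)
        beta[:k] = [1.0, -1.0, 0.8, -0.6, 0.5][:k]
        y = X @ beta + noise * rng.normal(size=n)
        Xz = (X - X.mean(0)) / X.std(0, ddof=1)
        sites = pd.MultiIndex.from_tuples([("chr1", i + 1) for i in range(p)])
        return pd.DataFrame(Xz.T, index=sites), y

    def test_noise_free_planted_predictors_recovered(self, rng):
        z, y = self._planted(rng)
        w, alpha, lam, report = train_elastic_net(
            z, y, alpha_grid=[0.5, 1.0], n_folds=5, seed=1, outer_folds=3)
        assert set(np.where(w[:5] != 0)[0]) == {0, 1, 2, 3, 4}
        assert np.mean(report.outer_mse) < 0.05

    def test_pure_noise_gives_near_null_model(self, rng):
        z, _ = self._planted(rng, k=0)
        y = rng.normal(size=z.shape[1])
        w, alpha, lam, report = train_elastic_net(
            z, y, alpha_grid=[0.5], n_folds=5, seed=1, outer_folds=3)
        # held out, the model does no better than predicting the mean
        assert np.mean(report.outer_mse) > 0.7 * np.var(y)

    def test_ridge_alpha_zero_is_dense(self, rng):
        z, y = self._planted(rng, n=40, p=60)
        w, alpha, lam, _ = train_elastic_net(z, y, alpha_grid=[0.0], n_folds=5,
                                             seed=1, outer_folds=2)
        assert alpha == 0.0
        assert np.count_nonzero(w) == 60

    def test_deterministic_given_seed(self, rng):
        z, y = self._planted(rng, n=40, p=80, noise=0.3)
        out1 = train_elastic_net(z, y, alpha_grid=[0.2, 0.8], n_folds=4, seed=9, outer_folds=2)
        out2 = train_elastic_net(z, y, alpha_grid=[0.2, 0.8], n_folds=4, seed=9, outer_folds=2)
        assert np.array_equal(out1[0], out2[0])
        assert out1[1:3] == out2[1:3]

    def test_nonfinite_rejected(self, rng):
        z, y = self._planted(rng, n=40, p=20)
        y[0] = np.nan
        with pytest.raises(ValueError):
            train_elastic_net(z, y, alpha_grid=[0.5], n_folds=4, seed=0, outer_folds=2)

    def test_default_alpha_grid_matches_documented_spacing(self):
        assert len(DEFAULT_ALPHA_GRID) == 21
        assert DEFAULT_ALPHA_GRID[0] == 0.0 and DEFAULT_ALPHA_GRID[-1] == 1.0


class TestFitCalibration:
    def test_exact_quadratic_recovery(self, rng):
        x = rng.normal(size=50)
        y = 0.1 * x ** 2 + 1.2 * x + 2.5
        a, b, c = fit_calibration(x, y)
        assert (a, b, c) == pytest.approx((0.1, 1.2, 2.5), abs=1e-8)

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration(np.ones(10), np.arange(10.0))


class TestClockModelSerialization:
    def _model(self):
        return ClockModel(
            sites=[CpGSite("chr1", 100), CpGSite("chr2", 50)],
            weights=np.array([0.5, -0.2]),
            reference_quantiles=np.linspace(0, 1, 20),
            site_means=np.array([0.4, 0.6]),
            site_sds=np.array([0.1, 0.2]),
            calibration=(0.1, 1.2, 2.5),
        )

    def test_json_round_trip_identical(self, tmp_path):
        m = self._model()
        path = tmp_path / "model.json"
        m.to_json(path)
        back = ClockModel.from_json(path)
        assert back.sites == m.sites
        assert np.array_equal(back.weights, m.weights)
        assert back.calibration == m.calibration
        # byte-stable serialization
        assert back.to_json() == m.to_json()

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="sex"):
            ClockModel(sites=[CpGSite("chrX", 1)], weights=[1.0],
                       reference_quantiles=[0, 1], site_means=[0.5], site_sds=[1.0],
                       calibration=(0, 1, 0))
        with pytest.raises(ValueError, match="positive"):
            ClockModel(sites=[CpGSite("chr1", 1)], weights=[1.0],
                       reference_quantiles=[0, 1], site_means=[0.5], site_sds=[0.0],
                       calibration=(0, 1, 0))

    def test_from_site_table(self):
        table = pd.DataFrame({"chrom": ["chr1", "chr2"], "pos": [10, 20],
                              "weight": [0.3, -0.1]})
        m = ClockModel.from_site_table(table, calibration=(0.1207, 1.2424, 2.5440))
        assert m.n_sites == 2
        assert m.calibrate(0.0) == pytest.approx(2.5440)
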