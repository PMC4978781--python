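import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from irtlink import (
    LinearLink,
    MeanMeanLink,
    MeanSigmaLink,
    PrecisionWeightedLink,
    StockingLordLink,
    apply_link_frame,
    delta_se_per_item,
    log_mean_mean,
    mean_mean,
    mean_sigma,
    per_item_links,
    pool_precision_weighted,
    sequential_se_curve,
    stocking_lord,
)

TRUE_LINK = LinearLink(1.4, -0.6)


@pytest.fixture()
def noise_free_pair(calib_tables):
    """A source table and its exact image under a known link."""
    source = calib_tables[0]
    return source, apply_link_frame(source, TRUE_LINK)


def zero_cov(item_ids):
    return pd.DataFrame(
        {"item_id": item_ids, "var_a": 0.0, "var_b": 0.0, "var_c": 0.0,
         "cov_ab": 0.0, "cov_ac": 0.0, "cov_bc": 0.0}
    )


class TestPerItemLinks:
    def test_worked_example_values(self, calib_tables):
        source, target, _, _ = calib_tables
        per = per_item_links(source, target)
        assert len(per) == 20
        row11 = per[per["item_id"] == 11].iloc[0]
        assert round(row11["u"], 3) == 1.372

    def test_identical_tables(self, calib_tables):
        source = calib_tables[0]
        per = per_item_links(source, source)
        assert np.allclose(per["u"], 1.0) and np.allclose(per["v"], 0.0)

    def test_noise_free_recovery(self, noise_free_pair):
        source, target = noise_free_pair
        per = per_item_links(source, target)
        assert np.allclose(per["u"], TRUE_LINK.u, atol=1e-12)
        assert np.allclose(per["v"], TRUE_LINK.v, atol=1e-12)

    def test_unmatched_ids_listed(self, calib_tables):
        source, target = calib_tables[0], calib_tables[1].copy()
        target.loc[0, "item_id"] = 99
        with pytest.raises(ValueError, match="99"):
            per_item_links(source, target)


class TestDeltaSE:
    def test_worked_example_item1(self, calib_tables):
        source, target, cs, ct = calib_tables
        per = delta_se_per_item(per_item_links(source, target),
                                source, target, cs, ct)
        row = per[per["item_id"] == 1].iloc[0]
        assert abs(row["se_u"] - 0.105) <= 0.002
        assert abs(row["se_v"] - 0.104) <= 0.003

    def test_zero_covariance_zero_se(self, calib_tables):
        source, target, _, _ = calib_tables
        z = zero_cov(source["item_id"])
        per = delta_se_per_item(per_item_links(source, target),
                                source, target, z, z)
        assert (per["se_u"] == 0).all() and (per["se_v"] == 0).all()

    def test_against_monte_carlo(self, calib_tables):
        # parametric draws at the worked example's item-1 covariance
        # magnitudes (moderate estimator cv, where the first-order
        # approximation is accurate)
        source, target, cs, ct = calib_tables
        keep = source["item_id"] == 1
        src, tgt = source[keep], target[keep]
        per = delta_se_per_item(per_item_links(src, tgt), src, tgt, cs, ct)
        rng = np.random.default_rng(7)
        n = 100_000
        c1 = cs[cs["item_id"] == 1].iloc[0]
        c2 = ct[ct["item_id"] == 1].iloc[0]
        m1 = np.array([[c1["var_a"], c1["cov_ab"]], [c1["cov_ab"], c1["var_b"]]])
        m2 = np.array([[c2["var_a"], c2["cov_ab"]], [c2["cov_ab"], c2["var_b"]]])
        d1 = rng.multivariate_normal([src["a"].iloc[0], src["b"].iloc[0]], m1, n)
        d2 = rng.multivariate_normal([tgt["a"].iloc[0], tgt["b"].iloc[0]], m2, n)
        u = d1[:, 0] / d2[:, 0]
        v = d2[:, 1] - u * d1[:, 1]
        assert per["se_u"].iloc[0] == pytest.approx(u.std(), rel=0.05)
        assert per["se_v"].iloc[0] == pytest.approx(v.std(), rel=0.05)


class TestPrecisionWeighted:
    def test_worked_example_pooled(self, calib_tables):
        source, target, cs, ct = calib_tables
        per = delta_se_per_item(per_item_links(source, target),
                                source, target, cs, ct)
        pooled = pool_precision_weighted(per)
        assert round(pooled.u, 3) == 1.226
        assert abs(pooled.se_u - 0.026) <= 0.002
        assert abs(pooled.se_v - 0.023) <= 0.002

    def test_single_item(self):
        per = pd.DataFrame({"item_id": [1], "u": [1.2], "v": [-0.5],
                            "se_u": [0.1], "se_v": [0.2]})
        pooled = pool_precision_weighted(per)
        assert (pooled.u, pooled.v) == (1.2, -0.5)
        assert (pooled.se_u, pooled.se_v) == (0.1, 0.2)

    def test_equal_ses_give_plain_mean(self):
        per = pd.DataFrame({"item_id": [1, 2, 3], "u": [1.0, 1.2, 1.7],
                            "v": [0.1, -0.2, 0.4],
                            "se_u": [0.1] * 3, "se_v": [0.2] * 3})
        pooled = pool_precision_weighted(per)
        assert pooled.u == pytest.approx(np.mean([1.0, 1.2, 1.7]), abs=1e-14)

    def test_pooled_se_below_every_item(self, calib_tables):
        source, target, cs, ct = calib_tables
        per = delta_se_per_item(per_item_links(source, target),
                                source, target, cs, ct)
        pooled = pool_precision_weighted(per)
        assert pooled.se_u <= per["se_u"].min()
        assert pooled.se_v <= per["se_v"].min()

    def test_zero_se_rejected(self):
        per = pd.DataFrame({"item_id": [1], "u": [1.0], "v": [0.0],
                            "se_u": [0.0], "se_v": [0.1]})
        with pytest.raises(ValueError):
            pool_precision_weighted(per)


class TestMomentMethods:
    def test_mean_mean_worked_example(self, calib_tables):
        source, target, cs, ct = calib_tables
        pooled = mean_mean(source, target, cs, ct)
        assert round(pooled.u, 3) == 1.237
        assert abs(pooled.se_u - 0.027) <= 0.002
        assert round(pooled.v, 3) == -0.706

    def test_mean_sigma_worked_example(self, calib_tables):
        source, target, cs, ct = calib_tables
        pooled = mean_sigma(source, target, cs, ct)
        assert round(pooled.u, 3) == 1.197
        assert abs(pooled.se_u - 0.118) <= 0.002
        assert round(pooled.v, 3) == -0.696

    @pytest.mark.parametrize("fn", [mean_mean, log_mean_mean, mean_sigma])
    def test_identical_tables(self, fn, calib_tables):
        source = calib_tables[0]
        pooled = fn(source, source)
        assert pooled.u == pytest.approx(1.0, abs=1e-12)
        assert pooled.v == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("fn", [mean_mean, log_mean_mean, mean_sigma])
    def test_noise_free_recovery(self, fn, noise_free_pair):
        source, target = noise_free_pair
        pooled = fn(source, target)
        assert pooled.u == pytest.approx(TRUE_LINK.u, abs=1e-12)
        assert pooled.v == pytest.approx(TRUE_LINK.v, abs=1e-12)

    def test_mean_sigma_affine_response(self, calib_tables):
        source = calib_tables[0]
        target = source.copy()
        target["b"] = 2.0 * source["b"] + 0.3
        pooled = mean_sigma(source, target)
        assert pooled.u == pytest.approx(2.0, abs=1e-12)
        assert pooled.v == pytest.approx(0.3, abs=1e-12)

    def test_log_mean_mean_equal_as(self):
        source = pd.DataFrame({"item_id": [1, 2], "a": [1.3, 1.3],
                               "b": [0.0, 1.0], "c": [0.2, 0.2]})
        target = pd.DataFrame({"item_id": [1, 2], "a": [0.9, 0.9],
                               "b": [0.5, 1.5], "c": [0.2, 0.2]})
        assert log_mean_mean(source, target).u == pytest.approx(
            mean_mean(source, target).u, abs=1e-12)

    def test_zero_dispersion_rejected(self):
        flat = pd.DataFrame({"item_id": [1, 2], "a": [1.0, 1.0],
                             "b": [0.5, 0.5], "c": [0.0, 0.0]})
        with pytest.raises(ValueError):
            mean_sigma(flat, flat)


class TestResponseFunctionMethods:
    def test_noise_free_recovery(self, noise_free_pair):
        source, target = noise_free_pair
        pooled = stocking_lord(source, target)
        assert pooled.u == pytest.approx(TRUE_LINK.u, abs=1e-6)
        assert pooled.v == pytest.approx(TRUE_LINK.v, abs=1e-6)

    def test_haebara_noise_free_recovery(self, noise_free_pair):
        source, target = noise_free_pair
        pooled = stocking_lord(source, target, criterion="haebara")
        assert pooled.u == pytest.approx(TRUE_LINK.u, abs=1e-6)
        assert pooled.v == pytest.approx(TRUE_LINK.v, abs=1e-6)

    def test_identical_tables(self, calib_tables):
        source = calib_tables[0]
        pooled = stocking_lord(source, source)
        assert pooled.u == pytest.approx(1.0, abs=1e-6)
        assert pooled.v == pytest.approx(0.0, abs=1e-6)

    def test_c_error_confounds_response_methods_only(self, noise_free_pair, rng):
        # perturbing the target c's moves the response-function estimate away
        # from the truth while the per-item identification is untouched
        source, target = noise_free_pair
        noisy = target.copy()
        noisy["c"] = np.clip(
            noisy["c"] + rng.normal(0.0, 0.05, size=len(noisy)), 0.0, 0.45
        )
        sl = stocking_lord(source, noisy)
        drift = max(abs(sl.u - TRUE_LINK.u), abs(sl.v - TRUE_LINK.v))
        assert drift > 1e-4
        per = per_item_links(source, noisy)
        assert np.allclose(per["u"], TRUE_LINK.u, atol=1e-12)
        assert np.allclose(per["v"], TRUE_LINK.v, atol=1e-12)


class TestSequentialCurve:
    def test_first_row_matches_single_item(self, calib_tables):
        source, target, cs, ct = calib_tables
        curve = sequential_se_curve(source, target, cs, ct)
        per = delta_se_per_item(per_item_links(source, target),
                                source, target, cs, ct)
        first = curve[(curve["n_items"] == 1)
                      & (curve["method"] == "precision_weighted")].iloc[0]
        assert first["u"] == pytest.approx(per["u"].iloc[0], abs=1e-12)
        assert first["se_u"] == pytest.approx(per["se_u"].iloc[0], abs=1e-12)

    def test_endpoint_matches_full_pool(self, calib_tables):
        source, target, cs, ct = calib_tables
        curve = sequential_se_curve(source, target, cs, ct)
        last = curve[(curve["n_items"] == 20)
                     & (curve["method"] == "precision_weighted")].iloc[0]
        assert abs(last["se_u"] - 0.026) <= 0.002
        assert abs(last["se_v"] - 0.023) <= 0.002

    def test_precision_weighted_monotone_and_order_invariant(self, calib_tables):
        source, target, cs, ct = calib_tables
        rng = np.random.default_rng(3)
        ids = list(source["item_id"])
        shuffled = list(rng.permutation(ids))
        c1 = sequential_se_curve(source, target, cs, ct, order=ids)
        c2 = sequential_se_curve(source, target, cs, ct, order=shuffled)
        for curve in (c1, c2):
            pw = curve[curve["method"] == "precision_weighted"]
            assert (np.diff(pw["se_u"]) <= 1e-15).all()
            assert (np.diff(pw["se_v"]) <= 1e-15).all()
        e1 = c1[(c1["n_items"] == 20) & (c1["method"] == "precision_weighted")]
        e2 = c2[(c2["n_items"] == 20) & (c2["method"] == "precision_weighted")]
        for col in ("u", "se_u", "v", "se_v"):
            assert e1[col].iloc[0] == pytest.approx(e2[col].iloc[0], abs=1e-12)

    def test_duplicate_order_rejected(self, calib_tables):
        source, target, cs, ct = calib_tables
        with pytest.raises(ValueError):
            sequential_se_curve(source, target, cs, ct,
                                order=[1] * len(source))


class TestEstimatorClasses:
    def test_precision_weighted_estimator(self, calib_tables):
        source, target, cs, ct = calib_tables
        est = PrecisionWeightedLink().fit(source, target, cs, ct)
        assert round(est.u_, 3) == 1.226
        assert est.link_.u == est.u_
        assert len(est.per_item_) == 20
        moved = est.transform(source)
        assert np.allclose(moved["a"], source["a"] / est.u_)

    def test_requires_covariances(self, calib_tables):
        source, target, _, _ = calib_tables
        with pytest.raises(ValueError):
            PrecisionWeightedLink().fit(source, target)

    def test_unfitted_transform_raises(self, calib_tables):
        with pytest.raises(AttributeError):
            MeanMeanLink().transform(calib_tables[0])

    @pytest.mark.parametrize(
        "est", [MeanMeanLink(), MeanMeanLink(geometric=True),
                MeanSigmaLink(), StockingLordLink()]
    )
    def test_sklearn_protocol(self, est, noise_free_pair):
        source, target = noise_free_pair
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        cloned.fit(source, target)
        assert cloned.u_ == pytest.approx(TRUE_LINK.u, abs=1e-6)
        assert cloned.v_ == pytest.approx(TRUE_LINK.v, abs=1e-6)
        back = cloned.transform_theta(np.array([0.0, 1.0]))
        assert back[1] - back[0] == pytest.approx(cloned.u_, abs=1e-9)
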