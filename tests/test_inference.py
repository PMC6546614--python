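"""Multivariate period-effect and moderation tests against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from termtide import (
    close,
    irsd_tertiles,
    moderation_test,
    paired_differences,
    pivot_basis,
    pmm_impute,
    time_effect_test,
)
from termtide.coda import IlrBasis, ilr
from termtide.composite import PairedProfile


def hotelling_oracle(X):
    """Step-by-step paired Hotelling T² from the textbook definitions."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    dbar = X.sum(axis=0) / n
    S = np.zeros((p, p))
    for row in X:
        dev = row - dbar
        S += np.outer(dev, dev)
    S /= n - 1
    t2 = n * dbar @ np.linalg.inv(S) @ dbar
    F = t2 * (n - p) / (p * (n - 1))
    return t2, F


def wilks_oracle(X, labels):
    """Brute-force Wilks lambda from within/total scatter determinants."""
    X = np.asarray(X, dtype=float)
    grand = X.mean(axis=0)
    T = np.zeros((X.shape[1], X.shape[1]))
    for row in X:
        T += np.outer(row - grand, row - grand)
    W = np.zeros_like(T)
    for g in np.unique(labels):
        sub = X[np.asarray(labels) == g]
        mu = sub.mean(axis=0)
        for row in sub:
            W += np.outer(row - mu, row - mu)
    return np.linalg.det(W) / np.linalg.det(T)


def random_profiles(rng, n, shift=0.3):
    basis = pivot_basis(8)
    profiles = []
    for i in range(n):
        z = rng.normal(0, 0.4, 7)
        interm = np.exp(basis.V @ z)
        holiday = np.exp(basis.V @ (z + rng.normal(shift, 0.2, 7)))
        profiles.append(
            PairedProfile(
                f"c{i}",
                close(interm, 1440),
                close(holiday, 1440),
            )
        )
    return profiles


class TestPairedDifferences:
    def test_identical_pair_gives_zero_row(self):
        c = close([3, 1, 4, 1, 5, 9, 2, 6], 1440)
        profiles = [PairedProfile("a", c, c), PairedProfile("b", c, c)]
        Dm = paired_differences(profiles)
        assert np.allclose(Dm.to_numpy(), 0.0, atol=1e-12)

    def test_three_part_hand_ilr(self):
        # pivot coords: z1 = sqrt(2/3) ln(x1/sqrt(x2 x3)), z2 = sqrt(1/2) ln(x2/x3)
        interm = close([2.0, 1.0, 1.0], 1440)
        holiday = close([1.0, 2.0, 1.0], 1440)
        profiles = [
            PairedProfile("a", interm, holiday),
            PairedProfile("b", interm, holiday),
        ]
        Dm = paired_differences(profiles)

        def hand_ilr(x):
            return np.array(
                [
                    np.sqrt(2 / 3) * np.log(x[0] / np.sqrt(x[1] * x[2])),
                    np.sqrt(1 / 2) * np.log(x[1] / x[2]),
                ]
            )

        expected = hand_ilr(holiday.values) - hand_ilr(interm.values)
        assert np.allclose(Dm.iloc[0].to_numpy(), expected, atol=1e-12)

    def test_norms_invariant_under_basis_rotation(self):
        rng = np.random.default_rng(2)
        profiles = random_profiles(rng, 10)
        base = pivot_basis(8)
        Q, _ = np.linalg.qr(rng.standard_normal((7, 7)))
        rotated = IlrBasis(base.V @ Q)
        d1 = paired_differences(profiles, base).to_numpy()
        d2 = paired_differences(profiles, rotated).to_numpy()
        assert np.allclose(
            np.linalg.norm(d1, axis=1), np.linalg.norm(d2, axis=1), atol=1e-10
        )


class TestTimeEffectTest:
    def test_all_zero_matrix(self):
        res = time_effect_test(np.zeros((10, 3)))
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0.3, 1.0, size=(10, 2))
        res = time_effect_test(X)
        t2, F = hotelling_oracle(X)
        assert res.statistic == pytest.approx(t2, abs=1e-8)
        assert res.F == pytest.approx(F, abs=1e-8)
        assert res.df1 == 2 and res.df2 == 8

    def test_interaction_only_ignores_uniform_change(self):
        rng = np.random.default_rng(6)
        shift = rng.normal(0, 0.5, size=(20, 1))
        X = np.repeat(shift, 5, axis=1)  # same change on every coordinate
        res = time_effect_test(X, mode="interaction_only")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_interaction_only_detects_nonuniform_change(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 0.1, size=(40, 4)) + np.array([1.0, -1.0, 1.0, -1.0])
        res = time_effect_test(X, mode="interaction_only")
        assert res.p < 1e-6

    def test_affine_invariance(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0.2, 1.0, size=(30, 5))
        a = time_effect_test(X)
        b = time_effect_test(3.7 * X)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-10)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="n > p"):
            time_effect_test(np.random.default_rng(0).normal(size=(5, 7)))


class TestModerationTest:
    def test_identical_group_means_give_null(self):
        base = np.array([[1.0, 2.0], [3.0, 0.0], [-1.0, 1.0], [1.0, -1.0]])
        X = np.vstack([base, base])  # two groups with identical rows
        res = moderation_test(X, ["a"] * 4 + ["b"] * 4)
        assert res.statistic == pytest.approx(1.0)
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_equal_two_sample_hotelling(self):
        rng = np.random.default_rng(9)
        X = np.vstack(
            [rng.normal(0, 1, size=(12, 3)), rng.normal(0.8, 1, size=(10, 3))]
        )
        labels = ["a"] * 12 + ["b"] * 10
        res = moderation_test(X, labels)
        # independent two-sample Hotelling route
        a, b = X[:12], X[12:]
        n1, n2, p = 12, 10, 3
        Sp = ((n1 - 1) * np.cov(a, rowvar=False) + (n2 - 1) * np.cov(b, rowvar=False)) / (
            n1 + n2 - 2
        )
        d = a.mean(axis=0) - b.mean(axis=0)
        t2 = (n1 * n2 / (n1 + n2)) * d @ np.linalg.inv(Sp) @ d
        F = t2 * (n1 + n2 - p - 1) / ((n1 + n2 - 2) * p)
        assert res.F == pytest.approx(F, abs=1e-8)

    def test_matches_determinant_oracle(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(12, 2)) + np.repeat(
            np.array([[0.0, 0.0], [0.5, -0.5], [1.0, 0.3]]), 4, axis=0
        )
        labels = [0] * 4 + [1] * 4 + [2] * 4
        res = moderation_test(X, labels)
        lam = wilks_oracle(X, labels)
        assert res.statistic == pytest.approx(lam, abs=1e-8)
        # Rao F recomputed independently for n=12, p=2, g=3
        t = np.sqrt((4 * 4 - 4) / (4 + 4 - 5))
        m = 12 - 1 - (2 + 3) / 2
        df1, df2 = 4, m * t - 2 + 1
        F = (1 - lam ** (1 / t)) / lam ** (1 / t) * df2 / df1
        assert res.F == pytest.approx(F, abs=1e-8)

    def test_matches_statsmodels_manova(self):
        sm_manova = pytest.importorskip("statsmodels.multivariate.manova")
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 3)) + np.repeat(
            np.array([[0.0, 0, 0], [0.7, 0, -0.4], [0.2, 0.9, 0.0]]), 10, axis=0
        )
        labels = np.repeat(["u", "p", "h"], 10)
        res = moderation_test(X, labels)
        df = pd.DataFrame(X, columns=["y1", "y2", "y3"])
        df["g"] = labels
        fit = sm_manova.MANOVA.from_formula("y1 + y2 + y3 ~ g", data=df)
        table = fit.mv_test().results["g"]["stat"]
        assert res.statistic == pytest.approx(
            float(table.loc["Wilks' lambda", "Value"]), abs=1e-8
        )
        assert res.F == pytest.approx(
            float(table.loc["Wilks' lambda", "F Value"]), rel=1e-6
        )

    def test_small_group_rejected(self):
        X = np.random.default_rng(1).normal(size=(10, 2))
        with pytest.raises(ValueError, match="at least two members"):
            moderation_test(X, ["a"] * 9 + ["b"])


class TestBasisInvariance:
    def test_statistics_identical_under_any_orthonormal_basis(self):
        rng = np.random.default_rng(12)
        profiles = random_profiles(rng, 25)
        groups = rng.choice(["u", "p", "h"], size=25)
        while min((groups == g).sum() for g in "uph") < 2:
            groups = rng.choice(["u", "p", "h"], size=25)
        base = pivot_basis(8)
        res_t = time_effect_test(paired_differences(profiles, base))
        res_m = moderation_test(paired_differences(profiles, base), groups)
        for seed in (1, 2, 3):
            Q, _ = np.linalg.qr(np.random.default_rng(seed).standard_normal((7, 7)))
            other = IlrBasis(base.V @ Q)
            alt_t = time_effect_test(paired_differences(profiles, other))
            alt_m = moderation_test(paired_differences(profiles, other), groups)
            assert alt_t.statistic == pytest.approx(res_t.statistic, abs=1e-8)
            assert alt_t.p == pytest.approx(res_t.p, abs=1e-10)
            assert alt_m.statistic == pytest.approx(res_m.statistic, abs=1e-8)
            assert alt_m.F == pytest.approx(res_m.F, abs=1e-8)


class TestPmmImpute:
    def test_no_missing_returns_input(self):
        y = np.array([1.0, 2.0, 3.0])
        out = pmm_impute(y, np.arange(3.0), k_donors=2)
        assert np.array_equal(out, y)

    def test_constant_targets(self):
        y = np.array([5.0, 5.0, 5.0, 5.0, np.nan])
        out = pmm_impute(y, np.arange(5.0), k_donors=3, seed=1)
        assert out[-1] == 5.0

    def test_single_donor_is_nearest_prediction(self):
        x = np.arange(10.0)
        y = 2 * x + 1
        y_miss = y.copy()
        y_miss[4] = np.nan
        out = pmm_impute(y_miss, x, k_donors=1, seed=3)
        # exhaustive check: donor 4 is absent, predictions are monotone in x,
        # so the nearest observed prediction belongs to x=3 or x=5
        fitted_dist = {i: abs(i - 4) for i in range(10) if i != 4}
        nearest = min(fitted_dist, key=fitted_dist.get)
        assert out[4] == y[nearest]

    def test_imputed_values_are_observed_values(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=50)
        y[rng.choice(50, 8, replace=False)] = np.nan
        X = rng.normal(size=(50, 2))
        out = pmm_impute(y, X, k_donors=5, seed=9)
        observed = set(y[~np.isnan(y)])
        assert all(v in observed for v in out[np.isnan(y)])

    def test_too_few_complete_cases(self):
        y = np.array([1.0, np.nan, np.nan, np.nan])
        with pytest.raises(ValueError, match="complete cases"):
            pmm_impute(y, np.arange(4.0), k_donors=3)


class TestIrsdTertiles:
    def test_ties_go_to_lower_tertile(self):
        x = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0, 3.0, 3.0, 3.0])
        groups = irsd_tertiles(x)
        assert list(groups) == [1, 1, 1, 2, 2, 2, 3, 3, 3]

    def test_missing_rejected(self):
        with pytest.raises(ValueError, match="complete"):
            irsd_tertiles([1.0, np.nan])
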