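"""Compositional geometry: closure, zero replacement, ilr, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from termtide import coda

positive_vectors = st.lists(
    st.floats(0.01, 1000.0), min_size=2, max_size=10
).map(np.array)


class TestClosure:
    def test_simple_rescale(self):
        c = coda.close([1, 1, 2], 1440)
        assert np.allclose(c.values, [360, 360, 720])
        assert c.total == 1440

    def test_idempotent(self):
        c = coda.close([360, 360, 720], 1440)
        again = coda.close(c.values, 1440)
        assert np.allclose(c.values, again.values)

    @settings(max_examples=50, deadline=None)
    @given(positive_vectors)
    def test_sums_to_kappa(self, x):
        assert np.isclose(coda.closure(x, 1440).sum(), 1440, atol=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            coda.closure(np.zeros(3))
        with pytest.raises(ValueError, match="non-negative"):
            coda.closure(np.array([1.0, -0.5, 2.0]))


class TestReplaceZeros:
    def test_no_zeros_unchanged(self):
        c = coda.close([100, 200, 1140], 1440)
        out = coda.replace_zeros(c)
        assert np.allclose(out.values, c.values)

    def test_multiplicative_arithmetic(self):
        # zero part -> delta*DL = 0.65*5 = 3.25; others scaled by 1 - 3.25/1440
        c = coda.Composition(("A", "B", "C"), np.array([1435.0, 5.0, 0.0]), 1440)
        out = coda.replace_zeros(c, delta=0.65, dl=5.0)
        scale = 1 - 3.25 / 1440
        assert out["C"] == pytest.approx(3.25)
        assert out["A"] == pytest.approx(1435 * scale)
        assert out["B"] == pytest.approx(5 * scale)
        assert out.values.sum() == pytest.approx(1440)

    def test_nonzero_ratios_preserved(self):
        c = coda.Composition(("A", "B", "C", "D"), np.array([720.0, 360.0, 360.0, 0.0]), 1440)
        out = coda.replace_zeros(c)
        assert out["A"] / out["B"] == pytest.approx(2.0, abs=1e-12)
        assert out["B"] / out["C"] == pytest.approx(1.0, abs=1e-12)

    def test_infeasible_imputation(self):
        x = np.array([[1.0] + [0.0] * 500])
        with pytest.raises(ValueError, match="imputed total"):
            coda.multiplicative_replacement(x, kappa=100.0, dl=5.0, delta=0.65)

    def test_matches_skbio_multiplicative(self):
        skbio_comp = pytest.importorskip("skbio.stats.composition")
        x = np.array([[0.3, 0.0, 0.5, 0.2], [0.1, 0.2, 0.0, 0.7]])
        delta_frac = 0.65 * 5.0 / 1440.0  # imputed proportion of the total
        ours = coda.multiplicative_replacement(1440 * x, 1440.0) / 1440.0
        theirs = skbio_comp.multi_replace(x, delta=delta_frac)
        assert np.allclose(ours, theirs, atol=1e-12)


class TestPivotBasis:
    def test_two_part_closed_form(self):
        V = coda.pivot_basis(2).V
        assert np.allclose(V[:, 0], [1 / np.sqrt(2), -1 / np.sqrt(2)])

    @pytest.mark.parametrize("D", [2, 3, 8, 12])
    def test_orthonormal_contrasts(self, D):
        V = coda.pivot_basis(D).V
        assert np.allclose(V.T @ V, np.eye(D - 1), atol=1e-10)
        assert np.allclose(V.sum(axis=0), 0.0, atol=1e-10)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            coda.pivot_basis(1)


class TestIlr:
    def test_uniform_maps_to_origin(self):
        basis = coda.pivot_basis(8)
        c = coda.close(np.ones(8), 1440)
        assert np.allclose(coda.ilr_transform(c, basis), 0.0, atol=1e-12)

    def test_two_part_closed_form(self):
        basis = coda.pivot_basis(2)
        ratio = np.exp(np.sqrt(2.0))
        c = coda.close([ratio, 1.0], 1440)
        z = coda.ilr_transform(c, basis)
        assert z[0] == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.05, 500.0), min_size=3, max_size=9).map(np.array))
    def test_round_trip(self, x):
        D = len(x)
        basis = coda.pivot_basis(D)
        c = coda.close(x, 1440)
        back = coda.ilr_inverse(coda.ilr_transform(c, basis), basis, 1440)
        assert np.allclose(back.values, c.values, atol=1e-9)

    def test_zero_vector_inverts_to_uniform(self):
        basis = coda.pivot_basis(5)
        c = coda.ilr_inverse(np.zeros(4), basis, 1440)
        assert np.allclose(c.values, 288.0)

    def test_isometry_matches_aitchison_distance(self):
        rng = np.random.default_rng(42)
        basis = coda.pivot_basis(8)
        for _ in range(20):
            x = coda.closure(rng.uniform(0.1, 10, 8), 1440)
            y = coda.closure(rng.uniform(0.1, 10, 8), 1440)
            dz = np.linalg.norm(coda.ilr(x, basis.V) - coda.ilr(y, basis.V))
            assert dz == pytest.approx(coda.aitchison_distance(x, y), abs=1e-9)

    def test_matches_skbio_with_same_basis(self):
        skbio_comp = pytest.importorskip("skbio.stats.composition")
        rng = np.random.default_rng(1)
        x = coda.closure(rng.uniform(0.1, 10, (5, 8)), 1.0)
        V = coda.pivot_basis(8).V
        ours = coda.ilr(x, V)
        theirs = skbio_comp.ilr(x, basis=V.T)
        assert np.allclose(ours, theirs, atol=1e-10)

    def test_positive_parts_required(self):
        basis = coda.pivot_basis(3)
        c = coda.Composition(("a", "b", "c"), np.array([1440.0, 0.0, 0.0]), 1440)
        with pytest.raises(ValueError, match="replace_zeros"):
            coda.ilr_transform(c, basis)


class TestCompositionalMean:
    def test_single_composition(self):
        c = coda.close([3, 4, 5], 1440)
        assert np.allclose(coda.compositional_mean([c]).values, c.values)

    def test_symmetric_pair_gives_uniform(self):
        basis = coda.pivot_basis(4)
        z = np.array([0.3, -0.2, 0.7])
        a = coda.ilr_inverse(z, basis, 1440)
        b = coda.ilr_inverse(-z, basis, 1440)
        m = coda.compositional_mean([a, b])
        assert np.allclose(m.values, 360.0, atol=1e-9)

    def test_agrees_with_ilr_average_any_basis(self):
        rng = np.random.default_rng(3)
        comps = [coda.close(rng.uniform(0.1, 10, 6), 1440) for _ in range(12)]
        m = coda.compositional_mean(comps)
        # random orthonormal ilr basis obtained by rotating the pivot basis
        Q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        V = coda.pivot_basis(6).V @ Q
        basis = coda.IlrBasis(V)
        zbar = np.mean([coda.ilr_transform(c, basis) for c in comps], axis=0)
        assert np.allclose(m.values, coda.ilr_inverse(zbar, basis, 1440).values, atol=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            coda.compositional_mean([])


class TestDifferenceTable:
    def test_two_child_hand_values(self):
        df = pd.DataFrame(
            {
                "child_id": ["a", "a", "b", "b"],
                "period": ["interm", "holiday", "interm", "holiday"],
                "X": [100.0, 140.0, 200.0, 160.0],
                "Y": [50.0, 50.0, 70.0, 90.0],
            }
        )
        out = coda.difference_table(df)
        assert out.loc["X", "interm_mean"] == pytest.approx(150.0)
        assert out.loc["X", "holiday_mean"] == pytest.approx(150.0)
        assert out.loc["X", "difference"] == pytest.approx(0.0)
        assert out.loc["Y", "difference"] == pytest.approx(10.0)
        assert out.loc["Y", "interm_sd"] == pytest.approx(np.std([50, 70], ddof=1))

    def test_unknown_period_label_rejected(self):
        df = pd.DataFrame(
            {"child_id": ["a", "a"], "period": ["interm", "summer"], "X": [1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="period"):
            coda.difference_table(df)


class TestPctDecrement:
    def test_published_pair(self):
        assert coda.pct_decrement(2405, 2282) == 5.4

    def test_equal_inputs(self):
        assert coda.pct_decrement(2000, 2000) == 0.0

    def test_reversed_pair_sign(self):
        assert coda.pct_decrement(2282, 2405) == -5.1

    def test_interm_denominator_variant(self):
        assert coda.pct_decrement(2405, 2282, denominator="interm") == pytest.approx(
            round(100 * 123 / 2405, 1)
        )

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            coda.pct_decrement(0, 100)
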