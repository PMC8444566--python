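import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from timecoda import (
    DEFAULT_LABELS,
    Composition,
    aitchison_distance,
    canonical_basis,
    close,
    compositional_mean,
    ilr_inverse,
    ilr_transform,
    pivot_bases,
    replace_zeros,
    ternary_density,
    variation_matrix,
)
from timecoda.composition import IlrBasis

from conftest import TABLE1_MIN, TABLE1_PCT

positive_parts = st.lists(
    st.floats(min_value=1e-3, max_value=1e4, allow_nan=False),
    min_size=4, max_size=4,
)


class TestClose:
    def test_percent_to_minutes_matches_published_day(self):
        """Closing the percent-scale geometric mean to 1440 min reproduces
        the published minutes/day for all four behaviors."""
        c = close(TABLE1_PCT, total=1440.0)
        assert np.allclose(c.parts, TABLE1_MIN, atol=0.01)

    @pytest.mark.parametrize(
        "parts,total,expected",
        [
            ((360, 360, 360, 360), 100, (25, 25, 25, 25)),
            ((1, 2, 3, 4), 1, (0.1, 0.2, 0.3, 0.4)),
        ],
    )
    def test_symmetry_and_proportionality(self, parts, total, expected):
        assert np.allclose(close(parts, total=total).parts, expected)

    def test_zero_part_error_names_the_part(self):
        with pytest.raises(ValueError, match="LPA"):
            close((400, 800, 0.0, 40))
        with pytest.raises(ValueError, match="MVPA"):
            close((400, 800, 100, -5))

    @given(parts=positive_parts)
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_closure_idempotent(self, parts):
        once = close(parts, total=1440.0)
        twice = close(once.parts, total=1440.0)
        assert np.array_equal(once.parts, twice.parts)

    def test_composition_invariants(self):
        c = close((1, 2, 3, 4), total=100.0)
        assert c.parts.sum() == pytest.approx(100.0, rel=1e-12)
        with pytest.raises(ValueError, match="unique"):
            Composition(np.array([50.0, 50.0]), ("a", "a"), 100.0)


class TestCompositionalMean:
    def test_single_composition_is_its_own_center(self):
        c = close((470, 780, 140, 50))
        m = compositional_mean([c])
        assert np.allclose(m.parts, c.parts, rtol=1e-12)

    def test_equal_part_compositions(self):
        m = compositional_mean(np.array([[1, 1, 1, 1], [4, 4, 4, 4.0]]),
                               total=100.0)
        assert np.allclose(m.parts, 25.0)

    def test_recovers_logistic_normal_center(self, table1_mean):
        """The geometric mean of logistic-normal draws converges to the
        generating center (checked at Monte-Carlo precision)."""
        rng = np.random.default_rng(5)
        mu = ilr_transform(table1_mean)
        z = mu + rng.normal(0, 0.2, size=(1000, 3))
        x = ilr_inverse(z)
        m = compositional_mean(x)
        # geometric mean in ilr space is the sample mean of z: compare there
        assert np.allclose(ilr_transform(m), z.mean(axis=0), atol=1e-9)
        assert np.allclose(m.parts, table1_mean.parts,
                           rtol=3 * 0.2 / np.sqrt(1000) * 3)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            compositional_mean([])


class TestVariationMatrix:
    def test_proportional_rows_give_zero_matrix(self):
        base = np.array([470.0, 780.0, 140.0, 50.0])
        comps = np.vstack([base, 2 * base, 0.5 * base])
        T = variation_matrix(comps)
        assert np.allclose(T.to_numpy(), 0.0, atol=1e-24)

    def test_two_row_hand_oracle(self):
        # var over {ln(1/2), ln(2/2)} with ddof=1 is (ln 2)^2 / 2
        T = variation_matrix(np.array([[1, 2, 4, 8], [2, 2, 4, 8.0]]))
        expected = np.log(2) ** 2 / 2
        assert T.iloc[0, 1] == pytest.approx(expected, rel=1e-12)
        # parts 2..4 are common to both rows: their ratios do not vary
        assert T.iloc[1, 2] == 0.0 and T.iloc[2, 3] == 0.0

    def test_symmetric_zero_diagonal_and_closure_invariant(self):
        rng = np.random.default_rng(11)
        x = rng.lognormal(size=(40, 4))
        T = variation_matrix(x).to_numpy()
        assert np.allclose(T, T.T)
        assert np.allclose(np.diag(T), 0.0)
        assert (T >= 0).all()
        closed = x / x.sum(axis=1, keepdims=True) * 1440
        assert np.allclose(variation_matrix(closed).to_numpy(), T, atol=1e-12)

    def test_needs_two_rows(self):
        with pytest.raises(ValueError):
            variation_matrix(np.array([[1, 2, 3, 4.0]]))


class TestIlr:
    def test_equal_composition_maps_to_origin(self):
        z = ilr_transform(close((25, 25, 25, 25), total=100.0))
        assert np.allclose(z, 0.0, atol=1e-15)

    def test_third_coordinate_direct_arithmetic(self, table1_mean):
        """z3 = sqrt(1/2) ln(LPA/MVPA) at the published mean composition."""
        z = ilr_transform(table1_mean)
        assert z[2] == pytest.approx(np.sqrt(0.5) * np.log(143.28 / 47.52),
                                     abs=1e-12)
        assert z[2] == pytest.approx(0.7805, abs=5e-4)

    def test_all_coordinates_match_printed_formulas(self, table1_mean):
        sleep, sb, lpa, mvpa = table1_mean.parts
        z = ilr_transform(table1_mean)
        assert z[0] == pytest.approx(
            np.sqrt(3 / 4) * np.log(sleep / (sb * lpa * mvpa) ** (1 / 3)),
            abs=1e-12)
        assert z[1] == pytest.approx(
            np.sqrt(2 / 3) * np.log(sb / np.sqrt(lpa * mvpa)), abs=1e-12)

    def test_scale_invariance(self, table1_mean):
        z_min = ilr_transform(table1_mean)
        z_pct = ilr_transform(table1_mean.reclose(100.0))
        assert np.allclose(z_min, z_pct, atol=1e-12)

    def test_roundtrip_property(self):
        rng = np.random.default_rng(17)
        x = rng.dirichlet(np.ones(4) * 2, size=100) * 1440
        z = ilr_transform(x)
        back = ilr_inverse(z)
        assert np.max(np.abs(back - x) / x) < 1e-9

    def test_inverse_of_origin_is_equal_split(self):
        c = ilr_inverse(np.zeros(3), total=1440.0)
        assert np.allclose(c.parts, 360.0, atol=1e-9)

    def test_inverse_recovers_published_mean(self, table1_mean):
        back = ilr_inverse(ilr_transform(table1_mean), total=1440.0)
        assert np.allclose(back.parts, TABLE1_MIN, atol=0.01)

    def test_isometry_with_aitchison_distance(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            a, b = rng.dirichlet(np.ones(4), size=2)
            d_ilr = np.linalg.norm(ilr_transform(a * 1440) - ilr_transform(b * 1440))
            assert d_ilr == pytest.approx(aitchison_distance(a, b), abs=1e-9)

    def test_non_finite_coordinates_rejected(self):
        with pytest.raises(ValueError):
            ilr_inverse(np.array([np.inf, 0.0, 0.0]))


class TestPivotBases:
    def test_four_bases_of_dimension_three(self):
        bases = pivot_bases(DEFAULT_LABELS)
        assert len(bases) == 4
        assert all(b.dimension == 3 for b in bases)
        assert [b.pivot for b in bases] == list(DEFAULT_LABELS)

    def test_first_basis_is_the_canonical_order(self):
        assert pivot_bases()[0].part_order == DEFAULT_LABELS
        assert canonical_basis().part_order == DEFAULT_LABELS

    def test_remainder_keeps_canonical_order(self):
        b_lpa = pivot_bases()[2]
        assert b_lpa.part_order == ("LPA", "Sleep", "SB", "MVPA")

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            pivot_bases(("a", "a", "b"))
        with pytest.raises(ValueError):
            IlrBasis(("Sleep", "Sleep", "LPA", "MVPA"))

    def test_bases_related_by_orthogonal_rotation(self):
        rng = np.random.default_rng(31)
        x = rng.dirichlet(np.ones(4), size=50) * 1440
        bases = pivot_bases()
        z_ref = ilr_transform(x, bases[0])
        for b in bases[1:]:
            z_b = ilr_transform(x, b)
            R, *_ = np.linalg.lstsq(z_ref, z_b, rcond=None)
            assert np.allclose(R.T @ R, np.eye(3), atol=1e-9)
            assert np.allclose(z_ref @ R, z_b, atol=1e-9)

    def test_contrast_matrix_is_orthonormal(self):
        for b in pivot_bases():
            V = b.contrast_matrix()
            assert np.allclose(V.T @ V, np.eye(3), atol=1e-12)
            assert np.allclose(V.sum(axis=0), 0.0, atol=1e-12)


class TestTernaryDensity:
    def test_identical_points_single_bin(self):
        x = np.tile([470.0, 780.0, 140.0, 50.0], (25, 1))
        grid = ternary_density(x, ("Sleep", "SB", "LPA"), resolution=10)
        nonzero = grid[grid["count"] > 0]
        assert len(nonzero) == 1
        assert nonzero["frequency"].iloc[0] == 1.0

    def test_frequencies_sum_to_one_and_zeros_kept(self):
        rng = np.random.default_rng(41)
        x = rng.dirichlet(np.ones(4), size=200) * 1440
        grid = ternary_density(x, ("Sleep", "LPA", "MVPA"), resolution=8)
        assert grid["frequency"].sum() == pytest.approx(1.0)
        assert len(grid) == 8 * 8  # all equal-area cells, empties included

    def test_uniform_sample_is_roughly_uniform(self):
        """Uniform simplex draws land uniformly across the equal-area
        triangular cells (chi-square sanity check)."""
        rng = np.random.default_rng(43)
        n, R = 20000, 5
        x = rng.dirichlet(np.ones(3), size=n)
        grid = ternary_density(x, ("a", "b", "c"), resolution=R,
                               labels=("a", "b", "c"))
        counts = grid["count"].to_numpy()
        expected = n / (R * R)
        chi2 = ((counts - expected) ** 2 / expected).sum()
        # df = 24; mean 24, sd ~ 7; allow a wide band
        assert chi2 < 24 + 6 * np.sqrt(48)

    def test_four_triples_for_four_parts(self):
        from itertools import combinations

        x = np.random.default_rng(47).dirichlet(np.ones(4), size=30) * 1440
        triples = list(combinations(DEFAULT_LABELS, 3))
        assert len(triples) == 4
        for t in triples:
            g = ternary_density(x, t, resolution=6)
            assert g["frequency"].sum() == pytest.approx(1.0)

    def test_unknown_labels_rejected(self):
        x = np.ones((5, 4))
        with pytest.raises(ValueError, match="not among"):
            ternary_density(x, ("Sleep", "SB", "Napping"))


def test_replace_zeros_multiplicative():
    out = replace_zeros(np.array([0.0, 600.0, 200.0, 40.0]),
                        detection_limit=2.0)
    assert out[0] == pytest.approx(1.3)
    # non-zero parts shrink multiplicatively, total preserved
    assert out.sum() == pytest.approx(840.0)
    assert out[1] / out[2] == pytest.approx(3.0)
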