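import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antnet.errors import ConfigError, DataFormatError, DegenerateGroupError
from antnet.metrics import (
    HexGrid,
    division_of_labour,
    home_range_90,
    maturity_distribution_stats,
    node_entropy,
    strength_maturity_association,
    z_normalize,
)
from antnet.synthetic import generate_maturity_profile


class TestEntropy:
    def test_single_partner(self):
        assert node_entropy([5, 0, 0]) == 0.0

    def test_uniform(self):
        assert node_entropy([1, 1, 1, 1]) == pytest.approx(np.log(4), abs=1e-12)

    def test_direct_formula(self):
        expected = -(0.5 * np.log(0.5) + 2 * 0.25 * np.log(0.25))
        assert node_entropy([2, 1, 1]) == pytest.approx(expected, abs=1e-12)
        assert node_entropy([2, 1, 1]) == pytest.approx(1.0397, abs=1e-4)

    def test_all_zero_isolated(self):
        assert node_entropy([0, 0, 0]) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(DataFormatError):
            node_entropy([1, -1])

    def test_base_option(self):
        assert node_entropy([1, 1], base=2) == pytest.approx(1.0)

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.integers(0, 50), min_size=2, max_size=30))
    def test_bounds(self, v):
        h = node_entropy(v)
        assert 0.0 <= h <= np.log(len(v)) + 1e-12
        if sum(v) > 0:
            # maximum iff uniform over all partners
            uniform = len(set(v)) == 1 and v[0] > 0
            assert (abs(h - np.log(len(v))) < 1e-12) == uniform

    def test_permutation_invariance(self):
        v = [3, 0, 7, 1, 1]
        assert node_entropy(v) == pytest.approx(node_entropy(v[::-1]), abs=1e-12)


class TestZNormalize:
    def test_simple(self):
        assert np.allclose(z_normalize([1.0, 2.0, 3.0]), [-1, 0, 1])

    def test_constant_rejected(self):
        with pytest.raises(DegenerateGroupError):
            z_normalize([2.0, 2.0, 2.0])

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(3, 5, size=40)
        z = z_normalize(x)
        assert np.mean(z) == pytest.approx(0.0, abs=1e-12)
        assert np.std(z, ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_grouped(self):
        x = pd.Series([1.0, 2.0, 3.0, 10.0, 20.0, 30.0])
        g = ["a", "a", "a", "b", "b", "b"]
        z = z_normalize(x, group=g)
        assert np.allclose(z[:3], [-1, 0, 1])
        assert np.allclose(z[3:], [-1, 0, 1])


class TestDivisionOfLabour:
    def test_equal_foragers(self):
        assert division_of_labour([0.3, 0.3, 0.3]) == 0.0

    def test_two_points(self):
        assert division_of_labour([0.0, 1.0]) == pytest.approx(0.70710678, abs=1e-8)

    def test_needs_two(self):
        with pytest.raises(DegenerateGroupError):
            division_of_labour([0.5])

    def test_order_invariant_and_scaling(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 0.5, size=20)
        assert division_of_labour(x) == pytest.approx(
            division_of_labour(x[::-1]), abs=1e-12
        )
        assert division_of_labour(2 * x) == pytest.approx(
            2 * division_of_labour(x), abs=1e-12
        )


class TestMaturityStats:
    def test_all_extremal(self):
        stats = maturity_distribution_stats([0.0, 1.0, 0.95, 0.05])
        assert stats["intermediate_fraction"] == 0.0

    def test_even_split_p_near_one(self):
        v = [0.5] * 50 + [0.0] * 25 + [1.0] * 25
        stats = maturity_distribution_stats(v)
        assert stats["proportion_test_p"] == pytest.approx(1.0, abs=0.05)

    def test_generator_roundtrip(self):
        v = generate_maturity_profile(100, 0.20, seed=7)
        stats = maturity_distribution_stats(v)
        assert stats["intermediate_fraction"] == pytest.approx(0.20)
        assert stats["n_intermediate"] == 20

    def test_imbalance_missing_when_no_low(self):
        stats = maturity_distribution_stats([0.95, 0.97, 0.5, 0.99])
        assert stats["high_low_imbalance"] is None

    def test_matches_r_prop_test(self):
        # R oracle: prop.test(30, 100, p=0.5, correct=TRUE)$p.value
        stats = maturity_distribution_stats([0.5] * 30 + [0.0] * 70)
        assert stats["proportion_test_p"] == pytest.approx(9.619268804e-05, rel=1e-8)

    def test_out_of_range_rejected(self):
        with pytest.raises(DataFormatError):
            maturity_distribution_stats([1.5])


class TestHexGrid:
    grid = HexGrid(width=20.0, height=15.0, body_length=1.0)

    def test_circumradius_default(self):
        assert self.grid.circumradius == 2.0

    def test_origin_maps_to_zero(self):
        assert self.grid.hex_index(0.0, 0.0) == (0, 0)

    def test_centres_map_to_own_index(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            q, r = int(rng.integers(0, 5)), int(rng.integers(0, 4))
            cx, cy = self.grid.center(q, r)
            assert self.grid.hex_index(cx, cy, clamp=False) == (q, r)

    def test_matches_nearest_centre_oracle(self):
        rng = np.random.default_rng(3)
        candidates = [(q, r) for q in range(-4, 12) for r in range(-4, 10)]
        centres = np.array([self.grid.center(q, r) for q, r in candidates])
        for _ in range(50):
            x = rng.uniform(0, 20)
            y = rng.uniform(0, 15)
            d = np.hypot(centres[:, 0] - x, centres[:, 1] - y)
            assert self.grid.hex_index(x, y) == candidates[int(np.argmin(d))]

    def test_out_of_bounds_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            idx = self.grid.hex_index(-5.0, 7.0)
        assert idx == self.grid.hex_index(0.0, 7.0)

    def test_n_hex_positive_and_stable(self):
        assert self.grid.n_hex >= 1
        assert self.grid.n_hex == self.grid.n_hex  # cached

    def test_every_in_bounds_point_covered(self):
        rng = np.random.default_rng(4)
        cover = set(self.grid._covering())
        for _ in range(100):
            x, y = rng.uniform(0, 20), rng.uniform(0, 15)
            assert self.grid.hex_index(x, y) in cover

    def test_invalid_dims(self):
        with pytest.raises(ConfigError):
            HexGrid(width=-1.0, height=5.0)


def _hr_oracle_size(counts: dict, coverage: float = 0.9) -> int:
    """Prefix oracle: smallest number of ranked hexes reaching coverage."""
    ranked = sorted(counts.values(), reverse=True)
    total = sum(ranked)
    acc = 0
    for i, c in enumerate(ranked, start=1):
        acc += c
        if acc >= coverage * total:
            return i
    return len(ranked)


class TestHomeRange:
    grid = HexGrid(width=30.0, height=30.0, body_length=1.0)

    def test_single_hexagon(self):
        pts = np.tile([[5.0, 5.0]], (12, 1))
        hr = home_range_90(pts, self.grid)
        assert len(hr.hexes) == 1
        assert hr.proportion_of_arena == pytest.approx(1 / self.grid.n_hex)

    def test_ten_equal_hexagons_need_nine(self):
        centres = [self.grid.center(q, r) for q in range(5) for r in range(2)]
        pts = np.repeat(np.array(centres), 4, axis=0)
        hr = home_range_90(pts, self.grid)
        assert len(hr.hexes) == 9

    def test_matches_prefix_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            hexes = [(q, r) for q in range(6) for r in range(5)]
            weights = rng.multinomial(200, np.ones(30) / 30)
            pts = []
            for (q, r), w in zip(hexes, weights):
                pts.extend([self.grid.center(q, r)] * w)
            counts = {h: w for h, w in zip(hexes, weights) if w}
            hr = home_range_90(np.array(pts), self.grid)
            assert len(hr.hexes) == _hr_oracle_size(counts)
            assert hr.covered >= 0.9 * hr.total

    def test_nest_only_filter(self):
        df = pd.DataFrame(
            {
                "x": [1.0, 1.0, 25.0],
                "y": [1.0, 1.0, 25.0],
                "arena": ["nest", "nest", "forage"],
            }
        )
        hr = home_range_90(df, self.grid)
        assert hr.total == 2

    def test_empty_rejected(self):
        with pytest.raises(DataFormatError):
            home_range_90(np.empty((0, 2)), self.grid)


class TestAssociation:
    def test_perfect_anti(self):
        x = np.linspace(0, 1, 10)
        res = strength_maturity_association(x, -2 * x + 1)
        assert res.r == pytest.approx(-1.0, abs=1e-12)
        assert res.slope == pytest.approx(-2.0, abs=1e-12)

    def test_constant_maturity_flagged(self):
        res = strength_maturity_association([0.5] * 5, [1, 2, 3, 4, 5])
        assert not res.valid

    def test_needs_three(self):
        with pytest.raises(DataFormatError):
            strength_maturity_association([0.1, 0.9], [1.0, 2.0])
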