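"""Smooth fractionator arrangement and PPS systematic sampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import proportionator as pp

from conftest import make_tiles


def is_unimodal(seq):
    seq = list(seq)
    peak = seq.index(max(seq))
    rising = seq[:peak + 1]
    falling = seq[peak:]
    return (all(a <= b for a, b in zip(rising, rising[1:]))
            and all(a >= b for a, b in zip(falling, falling[1:])))


def brute_force_draw(weights, n, u):
    """Independent oracle: scan cumulative (c_prev, c] intervals per line."""
    cum, c = [], 0.0
    for w in weights:
        cum.append((c, c + w))
        c += w
    T = c / n
    hits = []
    for k in range(n):
        line = u + k * T
        for i, (lo, hi) in enumerate(cum):
            if lo < line <= hi:
                hits.append(i)
                break
    return hits, T


class TestSmoothOrder:
    def test_three_weights_example(self):
        order = pp.smooth_order(make_tiles([3, 1, 2]))
        assert list(order.weights) == [1, 3, 2]

    def test_single_tile(self):
        order = pp.smooth_order(make_tiles([5]))
        assert list(order.weights) == [5]

    def test_equal_weights_deterministic_spatial_tiebreak(self):
        a = pp.smooth_order(make_tiles([4, 4, 4, 4]))
        b = pp.smooth_order(make_tiles([4, 4, 4, 4]))
        assert list(a.tiles["tile_id"]) == list(b.tiles["tile_id"])
        assert is_unimodal(a.weights)

    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=1,
                    max_size=40))
    def test_unimodal_permutation(self, weights):
        order = pp.smooth_order(make_tiles(weights))
        assert is_unimodal(order.weights)
        assert sorted(order.tiles["tile_id"]) == list(range(len(weights)))


class TestPPSDraw:
    def test_worked_probability(self):
        # one tile of 17 px when T_z = 343 px: p = 0.0496
        weights = [17, 343 * 2 - 17]
        order = pp.smooth_order(make_tiles(weights))
        rep = pp.pps_systematic_draw(order, n=2, u=10.0)
        p = dict(zip(rep.hits["weight_px"], rep.hits["p"]))
        assert p[17] == pytest.approx(17 / 343, abs=1e-10)
        assert p[17] == pytest.approx(0.0496, abs=1e-4)

    def test_equal_weights_reduce_to_uniform_systematic(self):
        order = pp.smooth_order(make_tiles([5] * 12))
        rep = pp.pps_systematic_draw(order, n=4, u=order.weights[0] * 3.0)
        assert list(rep.hits["order_index"]) == [2, 5, 8, 11]
        assert np.all(rep.hits["multiplicity"] == 1)

    def test_zero_weight_tiles_never_hit(self):
        tiles = make_tiles([0, 3, 0, 1, 0, 2])
        order = pp.smooth_order(tiles)
        zero_ids = set(tiles.loc[tiles["weight_px"] == 0, "tile_id"])
        for u in np.linspace(0.01, 1.0, 25):
            rep = pp.pps_systematic_draw(order, n=6, u=u * 1.0)
            assert not (set(rep.hits["tile_id"]) & zero_ids)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            weights = rng.integers(0, 9, size=rng.integers(3, 15))
            if weights.sum() == 0:
                continue
            tiles = make_tiles(weights)
            order = pp.smooth_order(tiles)
            n = int(rng.integers(1, 5))
            T = weights.sum() / n
            u = float(rng.uniform(1e-9, T))
            rep = pp.pps_systematic_draw(order, n, u)
            oracle, _ = brute_force_draw(list(order.weights), n, u)
            got = np.repeat(rep.hits["order_index"].to_numpy(),
                            rep.hits["multiplicity"].to_numpy())
            assert sorted(got) == sorted(oracle)

    def test_inclusion_expectations_sum_to_sample_size(self):
        # sum over tiles of min(z, T_z)/T_z <= n, equality when all z < T_z
        w = np.array([1, 2, 3, 4, 5, 9], dtype=float)
        n = 2
        T = w.sum() / n
        assert np.sum(np.minimum(w, T) / T) <= n + 1e-12
        w_small = np.array([1, 2, 3], dtype=float)
        T = w_small.sum() / n
        assert np.sum(np.minimum(w_small, T) / T) == pytest.approx(n)

    def test_no_signal_raises(self):
        order = pp.smooth_order(make_tiles([0, 0]))
        with pytest.raises(pp.NoSignalError):
            pp.pps_systematic_draw(order, n=2, u=0.5)

    def test_bad_start_rejected(self):
        order = pp.smooth_order(make_tiles([1, 2, 3]))
        with pytest.raises(pp.InvalidConfigError):
            pp.pps_systematic_draw(order, n=2, u=3.5)   # T_z = 3
        with pytest.raises(pp.InvalidConfigError):
            pp.pps_systematic_draw(order, n=2, u=0.0)


class TestEnumerationOracle:
    def test_ht_total_averaged_over_all_integer_starts_is_exact(self):
        """With integer weights and T_z = Z/n integer, the HT total averaged
        over the T_z possible integer starts equals the true supersection
        count exactly, whenever counts imply positive weight."""
        rng = np.random.default_rng(13)
        for _ in range(10):
            m = int(rng.integers(3, 12))
            weights = rng.integers(0, 7, size=m)
            n = int(rng.integers(1, 4))
            pad = (-weights.sum()) % n
            weights[int(rng.integers(m))] += pad          # make n | Z
            counts = np.where(weights > 0, rng.integers(0, 3, size=m), 0)
            if weights.sum() == 0:
                continue
            tiles = make_tiles(weights, counts)
            order = pp.smooth_order(tiles)
            T = weights.sum() // n
            totals = []
            for u in range(1, T + 1):
                rep = pp.pps_systematic_draw(order, n, float(u))
                hits = rep.hits.merge(tiles[["tile_id", "count", "usable"]],
                                      on="tile_id")
                hits = hits.rename(columns={"count": "x"})
                totals.append(pp.repetition_total(hits))
            assert np.mean(totals) == pytest.approx(counts.sum(), rel=1e-12)

    def test_smooth_order_does_not_increase_variance(self):
        """Enumerated over all starts, the HT-total variance under the
        smooth arrangement is no larger than under a shuffled arrangement
        (averaged over shuffles)."""
        rng = np.random.default_rng(3)
        weights = np.array([6, 1, 0, 3, 2, 4, 1, 7])
        counts = np.array([2, 1, 0, 1, 1, 2, 0, 3])
        n = 2
        weights[0] += (-weights.sum()) % n
        T = weights.sum() // n

        def enum_var(tiles_df, ordered):
            totals = []
            for u in range(1, T + 1):
                rep = pp.pps_systematic_draw(ordered, n, float(u))
                hits = rep.hits.merge(tiles_df[["tile_id", "count", "usable"]],
                                      on="tile_id").rename(columns={"count": "x"})
                totals.append(pp.repetition_total(hits))
            return np.var(totals)

        tiles = make_tiles(weights, counts)
        smooth_var = enum_var(tiles, pp.smooth_order(tiles))
        shuffled_vars = []
        for _ in range(30):
            perm = rng.permutation(len(weights))
            shuffled = pp.SmoothOrder(tiles.iloc[perm].reset_index(drop=True))
            shuffled_vars.append(enum_var(tiles, shuffled))
        assert smooth_var <= np.mean(shuffled_vars) + 1e-9


class TestTripartite:
    def test_22_per_sampling_presents_66_lines(self):
        rng = np.random.default_rng(1)
        tiles = make_tiles(rng.integers(0, 10, 500))
        reps = pp.tripartite_sample(pp.smooth_order(tiles), 22, seed=5)
        assert len(reps) == 3
        assert sum(int(r.hits["multiplicity"].sum()) for r in reps) == 66

    def test_60_by_3_presents_180(self):
        rng = np.random.default_rng(2)
        tiles = make_tiles(rng.integers(0, 10, 2000))
        reps = pp.tripartite_sample(pp.smooth_order(tiles), 60, seed=5)
        assert sum(int(r.hits["multiplicity"].sum()) for r in reps) == 180

    def test_same_seed_identical_repetitions(self):
        tiles = make_tiles(np.arange(50))
        a = pp.tripartite_sample(pp.smooth_order(tiles), 10, seed=3)
        b = pp.tripartite_sample(pp.smooth_order(tiles), 10, seed=3)
        for ra, rb in zip(a, b):
            assert ra.u == rb.u
            assert ra.hits.equals(rb.hits)


class TestSubsample:
    def test_fraction_one_is_identity(self):
        tiles = make_tiles([1, 2, 3])
        out, frac = pp.subsample_tiles(tiles, 1.0)
        assert out.equals(tiles)
        assert frac == 1.0

    def test_half_of_5000_keeps_2500_and_warns_sparse(self, caplog):
        tiles = make_tiles(np.ones(5000, dtype=int))
        with caplog.at_level("WARNING", logger="proportionator.smooth"):
            out, frac = pp.subsample_tiles(tiles, 0.5, seed=0)
        assert len(out) == 2500
        assert frac == 0.5
        assert any("10000" in m or "10,000" in m for m in caplog.messages)

    def test_tenth_of_100_is_deterministic(self):
        tiles = make_tiles(np.arange(100))
        a, frac = pp.subsample_tiles(tiles, 0.1, seed=7)
        b, _ = pp.subsample_tiles(tiles, 0.1, seed=7)
        assert len(a) == 10
        assert frac == 0.1
        assert a.equals(b)

    def test_bad_fraction_rejected(self):
        with pytest.raises(pp.InvalidConfigError):
            pp.subsample_tiles(make_tiles([1]), 0.0)
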