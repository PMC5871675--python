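"""Smooth-fractionator arrangement and PPS systematic sampling of tiles.

All tiles of all sampled section pairs form one *supersection*.  Tiles are
arranged by the smooth fractionator -- increasing then decreasing weight, a
unimodal sequence -- and systematic samples are drawn on the cumulative
weight axis: with total weight ``Z`` and sample size ``n`` the axis is cut
into ``n`` intervals of length ``T_z = Z / n``; one line per interval at
``u + k*T_z`` (``0 < u <= T_z``) hits the tile whose cumulative-weight
interval contains it.  A tile is therefore sampled with probability
``p_i = z_i / T_z`` (per line), proportional to its weight; zero-weight
tiles are never sampled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, NoSignalError

logger = logging.getLogger(__name__)

__all__ = [
    "Supersection",
    "SmoothOrder",
    "SamplingRepetition",
    "smooth_order",
    "pps_systematic_draw",
    "tripartite_sample",
    "subsample_tiles",
]

#: sparse populations should keep at least this many tiles after subsampling
MIN_TILES_SPARSE = 10_000


@dataclass(frozen=True)
class Supersection:
    """All tiles of all sampled section pairs of one subject."""

    tiles: pd.DataFrame            # tile_id, pair_id, x_um, y_um, frame_um,
                                   # weight_px, count, usable
    tile_fraction: float = 1.0

    def __post_init__(self) -> None:
        required = {"tile_id", "pair_id", "x_um", "y_um", "frame_um",
                    "weight_px", "count", "usable"}
        missing = required - set(self.tiles.columns)
        if missing:
            raise InvalidConfigError(f"tile table missing columns: {sorted(missing)}")
        if (self.tiles["weight_px"] < 0).any():
            raise InvalidConfigError("negative tile weight")

    @property
    def Z(self) -> float:
        """Total specific pixels over the supersection."""
        return float(self.tiles["weight_px"].sum())

    @property
    def sum_a_um2(self) -> float:
        return float((self.tiles["frame_um"] ** 2).sum())

    @property
    def sparseness(self) -> float:
        """Total tiles per count-bearing tile (raw, not rounded)."""
        n_with = int((self.tiles["count"] > 0).sum())
        if n_with == 0:
            raise NoSignalError("no tile bears a count; sparseness undefined")
        return len(self.tiles) / n_with


@dataclass(frozen=True)
class SmoothOrder:
    """Smooth-fractionator permutation of a tile table.

    ``tiles`` is the reordered table; its weight column is unimodal
    (non-decreasing then non-increasing).
    """

    tiles: pd.DataFrame

    @property
    def weights(self) -> np.ndarray:
        return self.tiles["weight_px"].to_numpy(dtype=float)


@dataclass(frozen=True)
class SamplingRepetition:
    """One PPS systematic draw from a smooth order.

    ``hits`` has one row per distinct sampled tile with its line
    multiplicity and per-line sampling probability ``p = z / T_z``.
    """

    n: int
    T_z: float
    u: float
    hits: pd.DataFrame             # tile_id, order_index, multiplicity, weight_px, p

    def __post_init__(self) -> None:
        if int(self.hits["multiplicity"].sum()) != self.n:
            raise InvalidConfigError("hit multiplicities must sum to n")


def smooth_order(tiles: pd.DataFrame) -> SmoothOrder:
    """Arrange tiles by increasing-then-decreasing weight.

    Tiles are first sorted by ``(weight, pair_id, y, x)`` (the spatial keys
    break ties deterministically); odd ranks form the ascending limb and even
    ranks, reversed, the descending limb, yielding a unimodal, symmetric
    weight profile.
    """
    if len(tiles) == 0:
        raise InvalidConfigError("cannot smooth an empty tile table")
    s = tiles.sort_values(["weight_px", "pair_id", "y_um", "x_um"],
                          kind="stable").reset_index(drop=True)
    asc = s.iloc[0::2]
    desc = s.iloc[1::2].iloc[::-1]
    return SmoothOrder(pd.concat([asc, desc], ignore_index=True))


def pps_systematic_draw(order: SmoothOrder, n: int, u: float) -> SamplingRepetition:
    """Systematic PPS draw: ``n`` lines at ``u + k*T_z`` on the cumulative
    weight axis, ``0 < u <= T_z = Z/n``.

    A line in the half-open cumulative interval ``(c_{i-1}, c_i]`` samples
    tile i, so boundary lines hit exactly one tile and zero-weight tiles
    (empty intervals) are never sampled.  Tiles heavier than ``T_z`` can be
    hit by several lines; each line carries one multiplicity.
    """
    w = order.weights
    Z = float(w.sum())
    if Z <= 0:
        raise NoSignalError("supersection has no specific pixels (Z == 0)")
    if n < 1:
        raise InvalidConfigError("sample size n must be >= 1")
    T_z = Z / n
    if not (0.0 < u <= T_z):
        raise InvalidConfigError(f"random start u={u} outside (0, T_z={T_z}]")
    cum = np.cumsum(w)
    lines = u + T_z * np.arange(n)
    idx = np.searchsorted(cum, lines, side="left")
    # float roundoff can push the last line a hair past cum[-1] == Z; clamp
    # to the last positive-weight tile so zero-weight tiles stay unsampled
    idx = np.minimum(idx, int(np.nonzero(w > 0)[0][-1]))
    uniq, mult = np.unique(idx, return_counts=True)
    hits = pd.DataFrame({
        "tile_id": order.tiles["tile_id"].to_numpy()[uniq],
        "order_index": uniq,
        "multiplicity": mult,
        "weight_px": w[uniq],
        "p": w[uniq] / T_z,
    })
    return SamplingRepetition(n=n, T_z=T_z, u=float(u), hits=hits)


def tripartite_sample(
    order: SmoothOrder, n: int, seed: int | None = None, n_repetitions: int = 3
) -> list[SamplingRepetition]:
    """Draw independent repetitions (default 3) with independent random
    starts from one seeded stream.

    The three repetitions make the estimator's precision directly and
    unbiasedly estimable; their combined hit list (``n`` lines each) is what
    gets presented for counting.
    """
    if n_repetitions < 1:
        raise InvalidConfigError("need at least one repetition")
    Z = float(order.weights.sum())
    if Z <= 0:
        raise NoSignalError("supersection has no specific pixels (Z == 0)")
    T_z = Z / n
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_repetitions):
        u = T_z * (1.0 - rng.random())          # uniform on (0, T_z]
        reps.append(pps_systematic_draw(order, n, u))
    return reps


def subsample_tiles(
    tiles: pd.DataFrame, tile_fraction: float, seed: int | None = None
) -> tuple[pd.DataFrame, float]:
    """Systematic uniform subsample of the tile tessellation, applied before
    weighting when the number of tiles is exorbitant.

    Returns the subsampled table and the fraction actually realised
    (``1/round(1/tile_fraction)``), which must be carried into the final
    estimate.  Warns when fewer than 10,000 tiles remain, which is below the
    recommended floor for sparse populations.
    """
    if not (0.0 < tile_fraction <= 1.0):
        raise InvalidConfigError("tile fraction must be in (0, 1]")
    if tile_fraction == 1.0:
        return tiles, 1.0
    k = max(1, round(1.0 / tile_fraction))
    rng = np.random.default_rng(seed)
    phase = int(rng.integers(k))
    out = tiles.iloc[phase::k].reset_index(drop=True)
    if len(out) < MIN_TILES_SPARSE:
        logger.warning("tile subsample keeps %d tiles (< %d recommended for "
                       "sparse populations)", len(out), MIN_TILES_SPARSE)
    return out, 1.0 / k
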