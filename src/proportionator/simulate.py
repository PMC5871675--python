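"""End-to-end simulation pipeline: organ -> fractionator sections -> tiles
with stain weights and ground-truth disector counts.

This is the synthetic stand-in for scanning and weighting real slides: it
produces the same tile table the estimator consumes from real data
(tile_id, pair_id, position, weight, count, usable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .disector import count_pair
from .errors import InvalidConfigError
from .fractionator import FractionatorDesign, plan_design, sample_pairs
from .synthetic import (OrganTruth, StainModel, assign_weights, generate_organ,
                       section_organ, tessellate_tiles)

__all__ = ["SimulatedAnimal", "build_supersection", "default_organ_params",
           "TILE_COLUMNS"]

TILE_COLUMNS = ["tile_id", "pair_id", "x_um", "y_um", "frame_um",
                "weight_px", "count", "usable"]


def default_organ_params() -> dict:
    """Default virtual organ: ~3 mm tall, ~1e7 um^2 cross section, 50
    sparse cells clustered toward the two end faces."""
    return {
        "height_um": 3000.0,
        "cross_section_w_um": 3200.0,
        "cross_section_d_um": 3200.0,
        "n_cells": 50,
    }


@dataclass(frozen=True)
class SimulatedAnimal:
    """One simulated subject: its organ truth, the fractionator sample taken
    from it, and the resulting supersection tile table."""

    organ: OrganTruth
    design: FractionatorDesign
    pairs: list[tuple[int, int]]
    tiles: pd.DataFrame
    t_um: float
    frame_um: float

    @property
    def sf(self) -> float:
        return self.design.sf

    @property
    def sparseness(self) -> float:
        n_with = int((self.tiles["count"] > 0).sum())
        return len(self.tiles) / n_with if n_with else float("inf")


def build_supersection(
    organ: OrganTruth,
    stain: StainModel,
    t_um: float,
    ns: int,
    frame_um: float,
    seed: int | None = None,
    R: int | None = None,
) -> SimulatedAnimal:
    """Section the organ, draw the fractionator sample of pairs, tessellate
    each pair into tiles and assign stain weights and true disector counts.

    ``seed`` drives both the random start R (when not given) and the stain
    noise; the same seed reproduces the tile table bit for bit.
    """
    slabs = section_organ(organ, t_um)
    design = plan_design(organ.height_um, t_um, ns)
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed if seed is not None else 0)
    s_start, s_stain = ss.spawn(2)
    if R is None:
        R = int(np.random.default_rng(s_start).integers(1, design.si + 1))
    design, pairs = sample_pairs(design, R=R)
    tess = tessellate_tiles(organ.cross_section_w_um,
                            organ.cross_section_d_um, frame_um)
    rng = np.random.default_rng(s_stain)
    m = len(tess)
    weights, counts, pair_ids = [], [], []
    for section, _lookup in pairs:
        k = section - 1                         # 0-based counting slab
        weights.append(assign_weights(tess, frame_um, organ, k, t_um, stain, rng))
        qf, qb = count_pair(tess, frame_um, organ, k, t_um)
        counts.append(qf + qb)
        pair_ids.append(np.full(m, section))
    npairs = len(pairs)
    tiles = pd.DataFrame({
        "tile_id": np.arange(npairs * m),
        "pair_id": np.concatenate(pair_ids),
        "x_um": np.tile(tess[:, 0], npairs),
        "y_um": np.tile(tess[:, 1], npairs),
        "frame_um": frame_um,
        "weight_px": np.concatenate(weights),
        "count": np.concatenate(counts),
        "usable": 1,
    })
    # deterministic row order: pair, then y, then x
    tiles = tiles.sort_values(["pair_id", "y_um", "x_um"],
                              kind="stable").reset_index(drop=True)
    return SimulatedAnimal(organ=organ, design=design, pairs=pairs,
                           tiles=tiles, t_um=t_um, frame_um=frame_um)
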