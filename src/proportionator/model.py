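"""Model objects: the proportionator estimator and the uniform baseline.

`Proportionator` is constructed from a supersection tile table (simulated or
read from CSV) plus the sampling design, and `fit()` performs the smooth
arrangement, the tripartite PPS draw, Horvitz-Thompson estimation and the
tripartite CE, returning a results object with a `summary()` table.
`FractionatorBaseline` is the classical uniform estimator on the same tile
table, for efficiency comparisons.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .disector import POLICIES, apply_nonusable_policy
from .errors import InvalidConfigError, UndefinedCEError
from .estimation import AnimalEstimate, animal_estimate, repetition_total
from .fractionator import BaselineEstimate
from .smooth import (SamplingRepetition, SmoothOrder, Supersection,
                     pps_systematic_draw, smooth_order, tripartite_sample)

__all__ = ["Proportionator", "ProportionatorResults", "FractionatorBaseline",
           "FractionatorResults"]


class Proportionator:
    """Proportionator estimator of total number over a supersection.

    Parameters
    ----------
    tiles
        Tile table with columns tile_id, pair_id, x_um, y_um, frame_um,
        weight_px, count, usable.  ``count`` is the bidirectional disector
        count x_i (simulated or user-supplied); weights z_i are the
        specific-stain pixel counts.
    sf
        Section sampling fraction of the fractionator design (e.g. 1/6).
    n_per_repetition
        Tiles sampled per independent repetition (22-30 typical; 60 in the
        mouse pilot).
    repetitions
        Independent samplings; 3 recommended for a stable CE, >= 2 required.
    tile_fraction
        Fraction of the tessellation that was weighted, when subsampled.
    units_per_animal
        Anatomical units pooled per subject (e.g. 3 vertebrae), a plain
        divisor of the final estimate.
    policy
        Non-useable-tile policy, ``exclude_rescale`` or ``impute_ratio``.
    """

    def __init__(
        self,
        tiles: pd.DataFrame,
        sf: float,
        *,
        n_per_repetition: int = 22,
        repetitions: int = 3,
        tile_fraction: float = 1.0,
        units_per_animal: float = 1.0,
        policy: str = "exclude_rescale",
    ) -> None:
        if sf <= 0:
            raise InvalidConfigError("sf must be positive")
        if repetitions < 2:
            raise InvalidConfigError("CE needs at least 2 repetitions; 3 are "
                                     "recommended")
        if n_per_repetition < 1:
            raise InvalidConfigError("n_per_repetition must be >= 1")
        if policy not in POLICIES:
            raise InvalidConfigError(f"unknown policy {policy!r}")
        self.supersection = Supersection(tiles, tile_fraction=tile_fraction)
        self.tiles = self.supersection.tiles
        self.sf = float(sf)
        self.n_per_repetition = int(n_per_repetition)
        self.repetitions = int(repetitions)
        self.tile_fraction = float(tile_fraction)
        self.units_per_animal = float(units_per_animal)
        self.policy = policy
        self._order: SmoothOrder | None = None

    @property
    def order(self) -> SmoothOrder:
        """Smooth-fractionator arrangement of the tiles (computed once)."""
        if self._order is None:
            self._order = smooth_order(self.tiles)
        return self._order

    @classmethod
    def from_dataframe(cls, tiles: pd.DataFrame, sf: float, **kwargs
                       ) -> "Proportionator":
        return cls(tiles, sf, **kwargs)

    @classmethod
    def from_csv(cls, path, sf: float, **kwargs) -> "Proportionator":
        return cls(pd.read_csv(path), sf, **kwargs)

    def sample(self, seed: int | None = None) -> list[SamplingRepetition]:
        """Draw the tripartite PPS sample without estimating (the tiles a
        user would be presented for counting)."""
        return tripartite_sample(self.order, self.n_per_repetition, seed,
                                 self.repetitions)

    def fit(self, seed: int | None = None,
            us: list[float] | None = None) -> "ProportionatorResults":
        """Run the estimator: smooth order, tripartite draw, HT totals, CE.

        ``us`` may fix the random starts explicitly (one per repetition);
        otherwise they come from ``seed``.
        """
        order = self.order
        if us is not None:
            if len(us) != self.repetitions:
                raise InvalidConfigError("need one random start per repetition")
            reps = [pps_systematic_draw(order, self.n_per_repetition, u)
                    for u in us]
        else:
            reps = tripartite_sample(order, self.n_per_repetition, seed,
                                     self.repetitions)
        lookup = self.tiles.set_index("tile_id")
        X, hit_frames, infos = [], [], []
        for r, rep in enumerate(reps, start=1):
            hits = rep.hits.copy()
            hits["x"] = lookup.loc[hits["tile_id"], "count"].to_numpy(dtype=float)
            hits["usable"] = lookup.loc[hits["tile_id"], "usable"].to_numpy(dtype=bool)
            hits, info = apply_nonusable_policy(hits, self.policy)
            X.append(repetition_total(hits, scale=info["scale"]))
            hits.insert(1, "repetition", r)
            hit_frames.append(hits)
            infos.append(info)
        est = animal_estimate(X, self.sf, self.tile_fraction,
                              self.units_per_animal)
        return ProportionatorResults(
            model=self, estimate=est, repetitions=reps,
            hits=pd.concat(hit_frames, ignore_index=True),
            policy_info=infos, seed=seed)


@dataclass(frozen=True)
class ProportionatorResults:
    """Fitted proportionator estimate for one subject."""

    model: Proportionator
    estimate: AnimalEstimate
    repetitions: list[SamplingRepetition]
    hits: pd.DataFrame
    policy_info: list[dict]
    seed: int | None = None

    @property
    def X(self) -> tuple[float, ...]:
        """Per-repetition Horvitz-Thompson totals for the supersection."""
        return self.estimate.X

    @property
    def mean_X(self) -> float:
        return self.estimate.mean_X

    @property
    def n_hat(self) -> float:
        return self.estimate.n_hat

    @property
    def ce(self) -> float:
        return self.estimate.ce

    @property
    def Z(self) -> float:
        return self.model.supersection.Z

    @property
    def T_z(self) -> float:
        return self.Z / self.model.n_per_repetition

    @property
    def us(self) -> list[float]:
        return [rep.u for rep in self.repetitions]

    def to_dict(self) -> dict:
        try:
            ce = self.ce
        except UndefinedCEError:
            ce = None
        return {
            "schema": "proportionator-results/1",
            "X": list(self.X),
            "mean_X": self.mean_X,
            "sf": self.model.sf,
            "tile_fraction": self.model.tile_fraction,
            "units_per_animal": self.model.units_per_animal,
            "n_hat": self.n_hat,
            "ce": ce,
            "Z": self.Z,
            "T_z": self.T_z,
            "us": self.us,
            "n_per_repetition": self.model.n_per_repetition,
            "repetitions": self.model.repetitions,
            "policy": self.model.policy,
            "seed": self.seed,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def summary(self) -> str:
        try:
            ce_txt = f"{self.ce:.3f}"
        except UndefinedCEError:
            ce_txt = "undefined (all repetition totals zero)"
        rows = [
            "Proportionator estimate",
            "-----------------------",
            f"tiles in supersection:   {len(self.model.tiles)}",
            f"total weight Z (px):     {self.Z:.0f}",
            f"T_z = Z/n (px):          {self.T_z:.1f}",
            f"repetition totals X_r:   "
            + ", ".join(f"{x:.1f}" for x in self.X),
            f"mean(X):                 {self.mean_X:.1f}",
            f"sf (sections):           {self.model.sf:.6g}",
            f"tile fraction:           {self.model.tile_fraction:.6g}",
            f"units per animal:        {self.model.units_per_animal:.6g}",
            f"N_hat = mean(X)/(2*sf):  {self.n_hat:.1f}",
            f"CE (tripartite):         {ce_txt}",
        ]
        return "\n".join(rows)


class FractionatorBaseline:
    """Classical uniform estimator over the same supersection tile table.

    Reads every tile (or the given uniformly sampled tile fraction) and
    estimates ``N_hat = (sum x_i / 2) / (sf * tile_fraction)`` with
    ``CE = 1/sqrt(sum x_i)``.
    """

    def __init__(self, tiles: pd.DataFrame, sf: float, *,
                 tile_fraction: float = 1.0,
                 units_per_animal: float = 1.0) -> None:
        if sf <= 0:
            raise InvalidConfigError("sf must be positive")
        self.supersection = Supersection(tiles, tile_fraction=tile_fraction)
        self.tiles = self.supersection.tiles
        self.sf = float(sf)
        self.tile_fraction = float(tile_fraction)
        self.units_per_animal = float(units_per_animal)

    def fit(self) -> "FractionatorResults":
        total_raw = float(self.tiles["count"].sum())
        est = BaselineEstimate(total_raw=total_raw, sf=self.sf,
                               tile_fraction=self.tile_fraction,
                               units_per_animal=self.units_per_animal)
        return FractionatorResults(model=self, estimate=est)


@dataclass(frozen=True)
class FractionatorResults:
    model: FractionatorBaseline
    estimate: BaselineEstimate

    @property
    def n_hat(self) -> float:
        return self.estimate.n_hat

    @property
    def total_raw(self) -> float:
        return self.estimate.total_raw

    @property
    def ce(self) -> float:
        return self.estimate.ce

    def to_dict(self) -> dict:
        try:
            ce = self.ce
        except UndefinedCEError:
            ce = None
        return {
            "schema": "fractionator-results/1",
            "total_raw": self.total_raw,
            "total_count": self.estimate.total_count,
            "sf": self.model.sf,
            "tile_fraction": self.model.tile_fraction,
            "n_hat": self.n_hat,
            "ce": ce,
        }

    def summary(self) -> str:
        try:
            ce_txt = f"{self.ce:.3f}"
        except UndefinedCEError:
            ce_txt = "undefined (zero count)"
        return "\n".join([
            "Fractionator (uniform) estimate",
            "-------------------------------",
            f"tiles examined:        {len(self.model.tiles)}",
            f"raw count (both dir):  {self.total_raw:.0f}",
            f"halved count:          {self.estimate.total_count:.1f}",
            f"sf * tile fraction:    {self.model.sf * self.model.tile_fraction:.6g}",
            f"N_hat:                 {self.n_hat:.1f}",
            f"CE = 1/sqrt(count):    {ce_txt}",
        ])
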