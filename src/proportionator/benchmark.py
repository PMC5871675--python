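"""Monte-Carlo benchmark: proportionator vs classical fractionator at a
matched tiles-examined budget.

Each replicate re-runs the full synthetic pipeline on a fixed organ (fresh
stain noise, fresh random start R), fits the proportionator with its
``repetitions x n`` tile budget, and gives the uniform baseline the same
number of tiles as a systematic uniform subsample of the tessellation.  For
a sparse population the uniform arm usually examines only empty tiles --
the "hopeless case" -- while the proportionator concentrates its budget on
the count-bearing tiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, UndefinedCEError
from .model import FractionatorBaseline, Proportionator
from .simulate import build_supersection
from .synthetic import OrganTruth, StainModel

__all__ = ["BenchmarkResult", "run_benchmark"]


@dataclass(frozen=True)
class BenchmarkResult:
    """Per-replicate table plus summary statistics of the comparison."""

    table: pd.DataFrame
    n_true: int
    tile_budget: int

    def summarize(self) -> dict:
        t = self.table
        prop_ce = t["prop_ce"].dropna()
        fract_ce = t["fract_ce"].dropna()
        out = {
            "replicates": len(t),
            "n_true": self.n_true,
            "tile_budget": self.tile_budget,
            "prop_mean_nhat": float(t["prop_nhat"].mean()),
            "prop_bias": float(t["prop_nhat"].mean()) - self.n_true,
            "prop_empirical_cv": float(t["prop_nhat"].std(ddof=1)
                                       / t["prop_nhat"].mean()),
            "prop_mean_ce": float(np.sqrt((prop_ce ** 2).mean()))
            if len(prop_ce) else None,
            "fract_mean_nhat": float(t["fract_nhat"].mean()),
            "fract_bias": float(t["fract_nhat"].mean()) - self.n_true,
            "fract_empirical_cv": float(t["fract_nhat"].std(ddof=1)
                                        / t["fract_nhat"].mean())
            if t["fract_nhat"].mean() > 0 else None,
            "fract_mean_ce": float(np.sqrt((fract_ce ** 2).mean()))
            if len(fract_ce) else None,
            "fract_ce_undefined_fraction": float(t["fract_ce"].isna().mean()),
            "prop_empty_tiles_per_count": _ratio(t["prop_empty_tiles"].sum(),
                                                 t["prop_counts"].sum()),
            "fract_empty_tiles_per_count": _ratio(t["fract_empty_tiles"].sum(),
                                                  t["fract_counts"].sum()),
            "prop_wins_ce_fraction": float(t["prop_wins"].mean()),
            "mean_sparseness": float(t["sparseness"].replace(
                [np.inf], np.nan).dropna().mean()),
        }
        return out

    def summary(self) -> str:
        s = self.summarize()
        lines = ["Proportionator vs fractionator benchmark",
                 "----------------------------------------"]
        for k, v in s.items():
            lines.append(f"{k:32s} {v if v is not None else 'n/a'}")
        return "\n".join(lines)


def _ratio(a: float, b: float) -> float | None:
    return float(a / b) if b > 0 else None


def _uniform_tile_sample(tiles: pd.DataFrame, budget: int,
                         rng: np.random.Generator) -> tuple[pd.DataFrame, float]:
    """Systematic uniform sample of ~budget tiles; returns (tiles, fraction)."""
    k = max(1, round(len(tiles) / budget))
    phase = int(rng.integers(k))
    return tiles.iloc[phase::k], 1.0 / k


def run_benchmark(
    organ: OrganTruth,
    stain: StainModel,
    t_um: float,
    ns: int,
    frame_um: float,
    n_per_repetition: int,
    n_replicates: int,
    seed: int | None = None,
    repetitions: int = 3,
) -> BenchmarkResult:
    """Run the paired comparison over ``n_replicates`` simulated studies.

    The proportionator examines ``repetitions * n_per_repetition`` tiles; the
    fractionator arm examines the same number, drawn uniformly.  An
    undefined CE (zero count, or all repetition totals zero) is recorded as
    NaN; the per-replicate ``prop_wins`` flag is true only when the
    proportionator CE is defined and smaller than the fractionator's (an
    undefined fractionator CE counts as larger).
    """
    if n_replicates < 10:
        raise InvalidConfigError("benchmark needs at least 10 replicates")
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    budget = repetitions * n_per_repetition
    rows = []
    for rep_seed in ss.spawn(n_replicates):
        child = rep_seed.spawn(3)
        sim = build_supersection(organ, stain, t_um, ns, frame_um,
                                 seed=child[0])
        model = Proportionator(sim.tiles, sim.sf,
                               n_per_repetition=n_per_repetition,
                               repetitions=repetitions)
        res = model.fit(seed=child[1])
        try:
            prop_ce = res.ce
        except UndefinedCEError:
            prop_ce = math.nan
        presented = res.hits
        prop_counts = float((presented["multiplicity"] * presented["x"]).sum())
        prop_empty = int((presented["x"] == 0).sum())

        rng = np.random.default_rng(child[2])
        ftiles, tf = _uniform_tile_sample(sim.tiles, budget, rng)
        fres = FractionatorBaseline(ftiles, sim.sf, tile_fraction=tf).fit()
        fract_raw = fres.total_raw
        fract_ce = 1.0 / math.sqrt(fract_raw) if fract_raw > 0 else math.nan

        wins = (not math.isnan(prop_ce)
                and (math.isnan(fract_ce) or prop_ce < fract_ce))
        rows.append({
            "prop_wins": wins,
            "prop_nhat": res.n_hat,
            "prop_ce": prop_ce,
            "prop_counts": prop_counts,
            "prop_empty_tiles": prop_empty,
            "fract_nhat": fres.n_hat,
            "fract_ce": fract_ce,
            "fract_counts": fract_raw,
            "fract_empty_tiles": int((ftiles["count"] == 0).sum()),
            "sparseness": sim.sparseness,
            "R": sim.design.R,
        })
    return BenchmarkResult(table=pd.DataFrame(rows), n_true=organ.n_true,
                           tile_budget=budget)
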