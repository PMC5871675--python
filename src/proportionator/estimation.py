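"""Horvitz-Thompson estimation, tripartite CE, group statistics and PROBE.

The Horvitz-Thompson theorem gives the contribution of a counted tile to the
supersection total as count over sampling probability, ``X_i = x_i / p_i``;
summing over one repetition's hits gives one estimate ``X_r`` of the total
in the supersection.  Three independent repetitions give the estimator's
precision for free: ``CE = SEM(X1, X2, X3) / mean(X)``.  The animal-level
total is ``mean(X) / (2 * sf)`` (the 2 compensates bidirectional disector
counting), optionally divided by the number of anatomical units pooled per
animal.

Pilot-study diagnostics follow the PROBE rule: with observed between-animal
variation CV_obs and mean estimator imprecision CE_mean, the design is
optimally balanced when ``2 < CV_obs^2 / CE_mean^2 < 4``; above 4 the
estimator is more precise than the biology warrants (reduce effort), below
2 the sampling should be intensified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (EstimationImpossibleError, InvalidConfigError,
                     UndefinedCEError)

__all__ = [
    "AnimalEstimate",
    "GroupSummary",
    "ProbeResult",
    "ht_contribution",
    "repetition_total",
    "animal_estimate",
    "group_mean_ce",
    "group_cv",
    "cv_animal",
    "probe",
    "sparseness_index",
]

PROBE_LOW = 2.0
PROBE_HIGH = 4.0

_PROBE_ADVICE = {
    "reduce_effort":
        "Estimator precision may exceed the purpose; if convenient, reduce "
        "the workload where it is heaviest (fewer sections or fewer tiles). "
        "Scale changes by a proportion less than the PROBE number relative "
        "to the PROBE limit.",
    "adequate": "Precision is adequate for the purpose.",
    "increase_sampling":
        "Estimator imprecision is too large. If the organ is inhomogeneous "
        "at the scale of sections, increase the number of sections; if "
        "sections are inhomogeneous at the scale of tiles or the total "
        "count is too small, increase the frame size to its maximum and the "
        "number of sampled tiles. Scale changes by a proportion less than "
        "the PROBE number relative to the PROBE limit.",
}


def ht_contribution(x: float, p: float) -> float:
    """Horvitz-Thompson contribution ``X_i = x_i / p_i`` of one sampled tile.

    A count of 2 in a tile sampled with probability 0.0496 contributes
    2/0.0496 = 40.3 cells to the supersection total.
    """
    if p <= 0:
        raise InvalidConfigError(f"invalid sampling probability p={p}")
    if x < 0:
        raise InvalidConfigError("count must be >= 0")
    return x / p


def repetition_total(hits: pd.DataFrame, scale: float = 1.0) -> float:
    """One repetition's estimate ``X_r = sum multiplicity * x_i / p_i``.

    Tiles heavier than T_z may carry several lines; each line contributes one
    ``x_i/p_i`` term (multiplicity).  ``scale`` carries the
    exclude-and-rescale factor of the non-useable-tile policy.
    """
    if hits["x"].isna().any():
        raise EstimationImpossibleError("hit without a count (or imputed value)")
    x = hits["x"].to_numpy(dtype=float)
    p = hits["p"].to_numpy(dtype=float)
    m = hits["multiplicity"].to_numpy(dtype=float)
    if (p[x > 0] <= 0).any() or (p <= 0).any():
        raise InvalidConfigError("sampled hit with non-positive probability")
    return float(np.sum(m * x / p)) * scale


@dataclass(frozen=True)
class AnimalEstimate:
    """Per-animal proportionator estimate from the repetition totals."""

    X: tuple[float, ...]
    sf: float
    tile_fraction: float = 1.0
    units_per_animal: float = 1.0

    @property
    def mean_X(self) -> float:
        return float(np.mean(self.X))

    @property
    def n_hat(self) -> float:
        """Total number per unit: ``mean(X) / (2 * sf * tf) / units``."""
        return self.mean_X / (2.0 * self.sf * self.tile_fraction) / self.units_per_animal

    @property
    def ce(self) -> float:
        """Tripartite coefficient of error ``SEM(X_r) / mean(X)``."""
        if len(self.X) < 2:
            raise UndefinedCEError("CE needs at least two repetitions")
        if self.mean_X == 0:
            raise UndefinedCEError("CE undefined: all repetition totals are zero")
        sem = float(np.std(self.X, ddof=1)) / math.sqrt(len(self.X))
        return sem / self.mean_X


def animal_estimate(
    X: Sequence[float],
    sf: float,
    tile_fraction: float = 1.0,
    units_per_animal: float = 1.0,
) -> AnimalEstimate:
    """Bundle repetition totals into an :class:`AnimalEstimate`.

    With the worked repetition totals (224, 124, 214): mean 187.3,
    CE = 31.8/187.3 = 0.17.
    """
    if sf <= 0:
        raise InvalidConfigError("section sampling fraction must be positive")
    if len(X) < 2:
        raise InvalidConfigError("need at least two repetition totals")
    return AnimalEstimate(X=tuple(float(v) for v in X), sf=sf,
                          tile_fraction=tile_fraction,
                          units_per_animal=units_per_animal)


def group_mean_ce(ces: Sequence[float]) -> float:
    """Group mean CE: root mean square of the per-animal CEs,
    ``sqrt(sum CE_i^2 / k)`` (squares average because variances add)."""
    ces = np.asarray(ces, dtype=float)
    if ces.size == 0:
        raise InvalidConfigError("empty CE list")
    return float(np.sqrt(np.mean(ces ** 2)))


def group_cv(estimates: Sequence[float]) -> float:
    """Observed between-animal CV: sample SD (n-1) over the mean."""
    est = np.asarray(estimates, dtype=float)
    if est.size < 2:
        raise InvalidConfigError("CV needs at least two estimates")
    mean = est.mean()
    if mean == 0:
        raise UndefinedCEError("CV undefined at zero mean")
    return float(est.std(ddof=1) / mean)


def cv_animal(cv_obs: float, ce_mean: float) -> tuple[float, bool]:
    """Biological variation: ``CV_ani = sqrt(max(CV_obs^2 - CE^2, 0))``.

    The estimator imprecision inflates the observed variation; subtracting
    the variances recovers the biological component.  Returns the value and
    a flag marking the degenerate (clamped-to-zero) case.
    """
    if cv_obs < 0 or ce_mean < 0:
        raise InvalidConfigError("cv_obs and ce_mean must be >= 0")
    diff = cv_obs ** 2 - ce_mean ** 2
    if diff < 0:
        return 0.0, True
    return math.sqrt(diff), False


@dataclass(frozen=True)
class ProbeResult:
    ratio: float
    recommendation: str
    advice: str


def probe(cv_obs: float, ce_mean: float) -> ProbeResult:
    """PROBE diagnostic: ratio ``CV_obs^2 / CE_mean^2`` and its verdict.

    Above 4: reduce effort; 2-4: adequate; below 2: increase sampling.
    """
    if ce_mean <= 0:
        raise UndefinedCEError("PROBE undefined for zero mean CE")
    if cv_obs < 0:
        raise InvalidConfigError("cv_obs must be >= 0")
    ratio = cv_obs ** 2 / ce_mean ** 2
    if ratio > PROBE_HIGH:
        rec = "reduce_effort"
    elif ratio >= PROBE_LOW:
        rec = "adequate"
    else:
        rec = "increase_sampling"
    return ProbeResult(ratio=ratio, recommendation=rec, advice=_PROBE_ADVICE[rec])


def sparseness_index(n_tiles_total: float, n_tiles_with_count: float) -> float:
    """Sparseness of the population: total tiles per count-bearing tile.

    1,900 tiles with 35 bearing a count index a sparseness of ~54.  Rounded
    to the nearest integer only at the presentation layer; the raw ratio is
    returned.
    """
    if n_tiles_with_count <= 0:
        raise UndefinedCEError("sparseness undefined without count-bearing tiles")
    if n_tiles_total < n_tiles_with_count:
        raise InvalidConfigError("total tiles < count-bearing tiles")
    return n_tiles_total / n_tiles_with_count


@dataclass(frozen=True)
class GroupSummary:
    """Pilot-group statistics and the PROBE recommendation."""

    estimates: tuple[float, ...]
    ces: tuple[float, ...]
    sparseness: float | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.estimates))

    @property
    def sd(self) -> float:
        return float(np.std(self.estimates, ddof=1))

    @property
    def cv_obs(self) -> float:
        return group_cv(self.estimates)

    @property
    def ce_mean(self) -> float:
        return group_mean_ce(self.ces)

    @property
    def cv_ani(self) -> float:
        return cv_animal(self.cv_obs, self.ce_mean)[0]

    @property
    def cv_ani_clamped(self) -> bool:
        return cv_animal(self.cv_obs, self.ce_mean)[1]

    @property
    def probe(self) -> ProbeResult:
        return probe(self.cv_obs, self.ce_mean)

    def to_dict(self) -> dict:
        pr = self.probe
        d = {
            "estimates": list(self.estimates),
            "ces": list(self.ces),
            "mean": self.mean,
            "sd": self.sd,
            "cv_obs": self.cv_obs,
            "ce_mean": self.ce_mean,
            "cv_ani": self.cv_ani,
            "cv_ani_clamped": self.cv_ani_clamped,
            "probe_ratio": pr.ratio,
            "recommendation": pr.recommendation,
        }
        if self.sparseness is not None:
            d["sparseness"] = self.sparseness
            d["sparseness_rounded"] = round(self.sparseness)
        return d

    def summary(self) -> str:
        pr = self.probe
        lines = [
            "Group summary (proportionator pilot)",
            "------------------------------------",
            f"animals:            {len(self.estimates)}",
            f"mean estimate:      {self.mean:.4g}",
            f"SD:                 {self.sd:.4g}",
            f"CV_obs:             {self.cv_obs:.3f}",
            f"mean CE (RMS):      {self.ce_mean:.3f}",
            f"CV_ani:             {self.cv_ani:.3f}"
            + ("  (clamped)" if self.cv_ani_clamped else ""),
            f"PROBE ratio:        {pr.ratio:.2f}  -> {pr.recommendation}",
        ]
        if self.sparseness is not None:
            lines.append(f"sparseness:         {round(self.sparseness)}")
        return "\n".join(lines)
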