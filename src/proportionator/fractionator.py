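"""Fractionator sampling of section pairs and the classical uniform baseline.

The fractionator samples a fixed, known fraction ``sf = 1/si`` of an
exhaustive series of sections: a random start R in the first period,
then every si-th section, each collected with its consecutive neighbour as a
physical-disector pair.  The classical estimator of the total is simply
``count / sf``; its precision under uniform sampling of a sparse population
is ``CE = 1/sqrt(count)`` -- the "hopeless case" the proportionator solves.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidConfigError, UndefinedCEError

logger = logging.getLogger(__name__)

__all__ = [
    "FractionatorDesign",
    "BaselineEstimate",
    "plan_design",
    "sample_pairs",
    "fractionator_estimate",
    "fractionator_ce",
]


@dataclass(frozen=True)
class FractionatorDesign:
    """A systematic uniform sampling plan for section pairs.

    ``si`` is the integer sampling interval and ``sf = 1/si`` the section
    sampling fraction; ``R`` (1-based, ``1 <= R <= si``) is the random start,
    absent until a concrete sample is drawn.
    """

    n_sections: int
    ns: int
    si: int
    sf: float
    R: int | None = None

    def __post_init__(self) -> None:
        if self.si < 1:
            raise InvalidConfigError("sampling interval si must be >= 1")
        if abs(self.sf * self.si - 1.0) > 1e-12:
            raise InvalidConfigError("sf must equal 1/si")
        if self.R is not None and not (1 <= self.R <= self.si):
            raise InvalidConfigError(f"random start R={self.R} outside 1..{self.si}")


@dataclass(frozen=True)
class BaselineEstimate:
    """Classical fractionator estimate from an exhaustive (or uniform)
    reading of the sampled sections.

    ``total_raw`` is the bidirectional disector event count (tops plus
    bottoms, as tabulated); ``total_count`` is the halved count that enters
    the estimate.  The CE follows the counting-noise rule
    ``1/sqrt(total_raw)``.
    """

    total_raw: float
    sf: float
    tile_fraction: float = 1.0
    units_per_animal: float = 1.0

    @property
    def total_count(self) -> float:
        return self.total_raw / 2.0

    @property
    def n_hat(self) -> float:
        return fractionator_estimate(self.total_count,
                                     self.sf * self.tile_fraction) / self.units_per_animal

    @property
    def ce(self) -> float:
        return fractionator_ce(self.total_raw)


def plan_design(height_um: float, t_um: float, ns: int) -> FractionatorDesign:
    """Plan the sampling interval for ``ns`` target section pairs.

    ``si = floor(floor(H/t) / ns)``; e.g. a 3000 um organ cut at 6 um and a
    target of 20 pairs gives 500 sections and si = 25, sf = 1/25.
    """
    if height_um <= 0 or t_um <= 0 or ns <= 0:
        raise InvalidConfigError("H, t and ns must be positive")
    n_sections = int(height_um // t_um)
    if ns > n_sections:
        raise InvalidConfigError(
            f"target ns={ns} exceeds the {n_sections} available sections")
    si = n_sections // ns
    return FractionatorDesign(n_sections=n_sections, ns=ns, si=si, sf=1.0 / si)


def sample_pairs(
    design: FractionatorDesign,
    R: int | None = None,
    seed: int | None = None,
) -> tuple[FractionatorDesign, list[tuple[int, int]]]:
    """Draw the systematic sample of section pairs.

    Sections are 1-based: the first pair is (R, R+1), subsequent pairs si
    sections apart.  A pair whose look-up section would exceed the series is
    dropped and logged.  Returns the design with R fixed and the list of
    ``(section, lookup)`` pairs.
    """
    if R is None:
        rng = np.random.default_rng(seed)
        R = int(rng.integers(1, design.si + 1))
    if not (1 <= R <= design.si):
        raise InvalidConfigError(f"random start R={R} outside 1..{design.si}")
    pairs = []
    for s in range(R, design.n_sections + 1, design.si):
        if s + 1 > design.n_sections:
            logger.info("pair at section %d dropped: look-up %d beyond the "
                        "%d-section series", s, s + 1, design.n_sections)
            continue
        pairs.append((s, s + 1))
    fixed = FractionatorDesign(design.n_sections, design.ns, design.si,
                               design.sf, R=R)
    return fixed, pairs


def fractionator_estimate(total_count: float, sf: float) -> float:
    """Scale a (halved, bidirectional) count up by the sampling fraction:
    ``N_hat = count / sf``."""
    if sf <= 0:
        raise InvalidConfigError("sampling fraction must be positive")
    if total_count < 0:
        raise InvalidConfigError("count must be >= 0")
    return total_count / sf


def fractionator_ce(total_count: float) -> float:
    """Imprecision of a uniform-sampling count: ``CE = 1/sqrt(count)``.

    Undefined at zero count -- reported as an error rather than silently
    returned as infinity.
    """
    if total_count < 0:
        raise InvalidConfigError("count must be >= 0")
    if total_count == 0:
        raise UndefinedCEError("fractionator CE undefined for a zero count")
    return 1.0 / math.sqrt(total_count)
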