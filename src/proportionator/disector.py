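"""Physical-disector counting on section pairs (simulated from ground truth).

A disector is two adjacent sections a known distance apart.  A cell is
counted when its unique counting feature -- the nucleus -- is present in the
counting section, sampled by the unbiased frame, and absent from the look-up
section: the *tops* rule, denoted Q-.  Counting both directions (swapping
the roles of the two sections, now counting bottoms) doubles the sampled
volume; the factor 2 is compensated in the estimator.

With half-open slab intervals the rule reduces to exact interval
bookkeeping: the forward direction of pair (k, k+1) counts nuclei whose top
lies in ``(k*t, (k+1)*t]``, the backward direction nuclei whose bottom lies
in ``[(k+1)*t, (k+2)*t)``.  Each nucleus top (bottom) lies in exactly one
such interval, so summing over an exhaustive series conserves the true
count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EstimationImpossibleError, InvalidConfigError
from .synthetic import OrganTruth

__all__ = [
    "TileCount",
    "apply_unbiased_frame",
    "count_pair",
    "count_tile",
    "apply_nonusable_policy",
]

POLICIES = ("exclude_rescale", "impute_ratio")


@dataclass(frozen=True)
class TileCount:
    """Bidirectional disector count of one tile."""

    tile_id: object
    q_forward: int
    q_backward: int
    usable: bool = True

    def __post_init__(self) -> None:
        if self.q_forward < 0 or self.q_backward < 0:
            raise InvalidConfigError("disector counts must be non-negative")

    @property
    def x(self) -> int:
        return self.q_forward + self.q_backward


def apply_unbiased_frame(cx: float, cy: float, x0: float, y0: float,
                         frame_um: float) -> bool:
    """Centroid-based unbiased frame rule: sampled iff the profile centroid
    lies in the half-open square ``[x0, x0+f) x [y0, y0+f)``.

    The half-open edges realise the frame's inclusion (left/bottom) and
    exclusion (right/top) lines exactly, so every point is sampled by
    exactly one tile of a tessellation.
    """
    return (x0 <= cx < x0 + frame_um) and (y0 <= cy < y0 + frame_um)


def count_pair(
    tiles_xy: np.ndarray,
    frame_um: float,
    organ: OrganTruth,
    k: int,
    t_um: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-tile (q_forward, q_backward) for section pair ``k`` (slabs k, k+1).

    Vectorised over the tessellation; tiles are indexed in the tessellation
    row order.
    """
    m = len(tiles_xy)
    qf = np.zeros(m, dtype=np.int64)
    qb = np.zeros(m, dtype=np.int64)
    if organ.n_true == 0:
        return qf, qb
    x, y, z = organ.cells[:, 0], organ.cells[:, 1], organ.cells[:, 2]
    r = organ.cells[:, 3] / 2.0
    top, bot = z + r, z - r
    fwd = (top > k * t_um) & (top <= (k + 1) * t_um)
    bwd = (bot >= (k + 1) * t_um) & (bot < (k + 2) * t_um)
    nx = int(organ.cross_section_w_um // frame_um)
    ny = int(organ.cross_section_d_um // frame_um)
    for sel, q in ((fwd, qf), (bwd, qb)):
        if not sel.any():
            continue
        ix = (x[sel] // frame_um).astype(int)
        iy = (y[sel] // frame_um).astype(int)
        ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        np.add.at(q, iy[ok] * nx + ix[ok], 1)
    return qf, qb


def count_tile(
    tile_index: int,
    tiles_xy: np.ndarray,
    frame_um: float,
    organ: OrganTruth,
    k: int,
    t_um: float,
    tile_id=None,
) -> TileCount:
    """Bidirectional disector count of a single tile of pair ``k``."""
    qf, qb = count_pair(tiles_xy, frame_um, organ, k, t_um)
    return TileCount(tile_id=tile_index if tile_id is None else tile_id,
                     q_forward=int(qf[tile_index]),
                     q_backward=int(qb[tile_index]))


def apply_nonusable_policy(
    hits: pd.DataFrame, policy: str = "exclude_rescale"
) -> tuple[pd.DataFrame, dict]:
    """Adjust a repetition's hit list for non-useable tiles.

    Tiles with staining or sectioning artifacts that confound counting are
    flagged unusable.  Two substitute policies are offered:

    ``exclude_rescale``
        drop unusable hits and rescale the repetition total by
        ``n / (n - n_unusable)`` (line counts);
    ``impute_ratio``
        replace the count of each unusable hit by its weight times the
        count-per-pixel ratio of the usable hits of the same repetition.

    ``hits`` needs columns multiplicity, weight_px, p, x, usable.  Returns
    the adjusted hit table and an info dict (policy, n lines, unusable
    lines, scale factor).
    """
    if policy not in POLICIES:
        raise InvalidConfigError(f"unknown non-useable-tile policy {policy!r}")
    n_lines = int(hits["multiplicity"].sum())
    usable = hits["usable"].astype(bool)
    n_bad = int(hits.loc[~usable, "multiplicity"].sum())
    info = {"policy": policy, "n_lines": n_lines, "n_unusable_lines": n_bad,
            "scale": 1.0}
    if n_bad == 0:
        return hits, info
    if n_bad == n_lines:
        raise EstimationImpossibleError("every sampled tile is unusable")
    if policy == "exclude_rescale":
        out = hits.loc[usable].reset_index(drop=True)
        info["scale"] = n_lines / (n_lines - n_bad)
        return out, info
    # impute_ratio
    good = hits.loc[usable]
    sx = float((good["multiplicity"] * good["x"]).sum())
    sz = float((good["multiplicity"] * good["weight_px"]).sum())
    if sz <= 0:
        raise EstimationImpossibleError("usable hits carry no weight; cannot "
                                        "impute")
    out = hits.copy()
    out.loc[~usable, "x"] = out.loc[~usable, "weight_px"] * (sx / sz)
    info["imputed_ratio"] = sx / sz
    return out, info
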