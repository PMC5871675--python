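"""Synthetic tissue: virtual organs with sparse, clustered cell populations.

The simulator emulates the situation the proportionator was designed for: a
small organ (~3 x 3 x 3 mm) sectioned exhaustively at ~6 um, containing a
*sparse* population (tens of cells per organ) that is inhomogeneously
distributed -- preferentially near the two end faces, as osteoprogenitors
cluster near the vertebral endplates.  Cells are placed by a Neyman-Scott
process (Poisson parents, Gaussian offspring) whose parent intensity is
elevated in the two end zones.

Geometry conventions
--------------------
All coordinates are 0-based with half-open intervals: section slab ``k``
occupies ``[k*t, (k+1)*t)`` on the z axis and a tile occupies
``[x, x+f) x [y, y+f)`` in the cross-section plane.  A cell nucleus is a
sphere; it is "present" in a slab when the sphere intersects the slab's
half-open z interval.  Half-open bookkeeping makes the conservation property
exact: each nucleus top lies in exactly one slab and each centroid in exactly
one tile.

Stain weights
-------------
Per-tile weights are integer "specific pixel" counts: each in-slab cell
profile contributes a strictly positive, Poisson-distributed pixel count
unless it is a false negative; a background draw and an optional large
artifact blob model nonspecific staining and stain trapping (the
"high weight / low count" failure mode that degrades -- but does not bias --
the estimator).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import InvalidConfigError

logger = logging.getLogger(__name__)

__all__ = [
    "OrganTruth",
    "StainModel",
    "TileRaster",
    "generate_organ",
    "section_organ",
    "tessellate_tiles",
    "assign_weights",
    "render_tile_raster",
]


@dataclass(frozen=True)
class OrganTruth:
    """A virtual organ with known cell positions -- the ground truth.

    ``cells`` is an ``(n, 4)`` float array of ``(x, y, z, nucleus_diameter)``
    in micrometres.  ``n_true`` is the exact total cell count the estimators
    are judged against.
    """

    height_um: float
    cross_section_w_um: float
    cross_section_d_um: float
    cells: np.ndarray
    n_true: int
    seed: int | None = None

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=float).reshape(-1, 4)
        object.__setattr__(self, "cells", cells)
        if self.n_true != len(cells):
            raise InvalidConfigError(
                f"n_true={self.n_true} does not match {len(cells)} cells"
            )
        if len(cells):
            if (cells[:, 0].min() < 0 or cells[:, 0].max() >= self.cross_section_w_um
                    or cells[:, 1].min() < 0 or cells[:, 1].max() >= self.cross_section_d_um
                    or cells[:, 2].min() < 0 or cells[:, 2].max() >= self.height_um):
                raise InvalidConfigError("cell centroid outside the organ box")

    @property
    def cross_section_area_um2(self) -> float:
        return self.cross_section_w_um * self.cross_section_d_um

    def to_json(self) -> str:
        payload = {
            "height_um": self.height_um,
            "cross_section_w_um": self.cross_section_w_um,
            "cross_section_d_um": self.cross_section_d_um,
            "seed": self.seed,
            "n_true": self.n_true,
            "cells": self.cells.tolist(),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "OrganTruth":
        d = json.loads(text)
        return cls(
            height_um=d["height_um"],
            cross_section_w_um=d["cross_section_w_um"],
            cross_section_d_um=d["cross_section_d_um"],
            cells=np.asarray(d["cells"], dtype=float).reshape(-1, 4),
            n_true=d["n_true"],
            seed=d.get("seed"),
        )


@dataclass(frozen=True)
class StainModel:
    """Stochastic model of the image-analysis weighting step.

    pixels_per_cell_mean
        Expected specific pixels contributed by one in-section cell profile.
        Profiles contribute ``1 + Poisson(mean - 1)`` pixels (strictly
        positive) unless they are false negatives, so with
        ``false_negative_rate == 0`` a countable cell always carries weight.
    background_rate
        Expected nonspecific pixels per tile (Poisson).
    artifact_rate
        Probability that a tile receives a large spurious stain blob
        ("high weight / low count").
    artifact_pixels_mean
        Expected size of such a blob (drawn as ``1 + Poisson(mean)``).
    false_negative_rate
        Probability that a cell profile contributes zero pixels (the stain
        misses the cell -- the one mechanism that can bias the estimator).
    pixel_noise_dispersion
        Extra overdispersion of the per-profile pixel count; 0 gives pure
        Poisson, d > 0 gives a gamma-Poisson mixture with variance
        ``m + d * m**2``.
    """

    pixels_per_cell_mean: float = 50.0
    background_rate: float = 0.05
    artifact_rate: float = 0.0
    artifact_pixels_mean: float = 500.0
    false_negative_rate: float = 0.0
    pixel_noise_dispersion: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pixels_per_cell_mean", "background_rate", "artifact_rate",
                     "artifact_pixels_mean", "pixel_noise_dispersion"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.false_negative_rate <= 1.0:
            raise InvalidConfigError("false_negative_rate must be in [0, 1]")


@dataclass
class TileRaster:
    """Binary raster of the specific-stain pixels of one tile.

    The positive-pixel count of ``mask`` equals the tabulated weight z_i of
    the tile, so pixel counting on the raster and the tabulated weight path
    are interchangeable.
    """

    width_px: int
    height_px: int
    mask: np.ndarray

    @property
    def weight(self) -> int:
        return int(self.mask.sum())

    def save(self, path) -> None:
        from PIL import Image

        Image.fromarray((self.mask.astype(np.uint8)) * 255, mode="L").save(path)

    @classmethod
    def load(cls, path) -> "TileRaster":
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("L")) > 0
        return cls(width_px=arr.shape[1], height_px=arr.shape[0], mask=arr)


# ---------------------------------------------------------------------------
# organ generation


def generate_organ(
    height_um: float,
    cross_section_w_um: float,
    cross_section_d_um: float,
    n_cells: int,
    seed: int,
    *,
    nucleus_diameter_um: float = 8.0,
    parent_mean: float = 8.0,
    offspring_sigma_um: float = 150.0,
    endplate_fraction: float = 0.15,
    endplate_factor: float = 4.0,
) -> OrganTruth:
    """Generate a virtual organ with exactly ``n_cells`` clustered cells.

    Parent cluster centres follow a Poisson process whose z intensity is
    ``endplate_factor`` times higher in the two end zones (each a fraction
    ``endplate_fraction`` of the organ height); offspring scatter around a
    uniformly chosen parent with isotropic Gaussian offsets and are rejected
    until inside the organ.  Cell z positions keep the whole nucleus inside
    ``[0, height)`` so every nucleus top and bottom falls in a real slab.
    """
    if height_um <= 0 or cross_section_w_um <= 0 or cross_section_d_um <= 0:
        raise InvalidConfigError("organ dimensions must be positive")
    if n_cells < 0:
        raise InvalidConfigError("target cell count must be >= 0")
    r = nucleus_diameter_um / 2.0
    if height_um <= nucleus_diameter_um:
        raise InvalidConfigError("organ shorter than one nucleus diameter")

    rng = np.random.default_rng(seed)
    if n_cells == 0:
        return OrganTruth(height_um, cross_section_w_um, cross_section_d_um,
                          np.empty((0, 4)), 0, seed)

    n_parents = max(1, int(rng.poisson(parent_mean)))
    # z mixture: end zones of total mass fraction q, elevated by the factor.
    f, g = endplate_fraction, endplate_factor
    p_end = (2 * f * g) / (2 * f * g + (1 - 2 * f)) if g > 0 else 0.0
    pz = np.empty(n_parents)
    in_end = rng.random(n_parents) < p_end
    n_end = int(in_end.sum())
    ze = rng.uniform(0.0, 2 * f * height_um, size=n_end)
    # fold the two end zones: first half maps to the bottom, second to the top
    ze = np.where(ze < f * height_um, ze, height_um - (ze - f * height_um))
    pz[in_end] = ze
    pz[~in_end] = rng.uniform(f * height_um, (1 - f) * height_um,
                              size=n_parents - n_end)
    px = rng.uniform(0.0, cross_section_w_um, size=n_parents)
    py = rng.uniform(0.0, cross_section_d_um, size=n_parents)

    cells = np.empty((n_cells, 4))
    placed = 0
    while placed < n_cells:
        j = int(rng.integers(n_parents))
        off = rng.normal(0.0, offspring_sigma_um, size=3)
        x, y, z = px[j] + off[0], py[j] + off[1], pz[j] + off[2]
        if (0.0 <= x < cross_section_w_um and 0.0 <= y < cross_section_d_um
                and r <= z <= height_um - r):
            cells[placed] = (x, y, z, nucleus_diameter_um)
            placed += 1
    return OrganTruth(height_um, cross_section_w_um, cross_section_d_um,
                      cells, n_cells, seed)


def section_organ(organ: OrganTruth, t_um: float) -> list[tuple[float, float]]:
    """Exhaustively section the organ into slabs of thickness ``t_um``.

    Returns the ordered list of half-open slabs ``[k*t, (k+1)*t)``; a
    trailing remnant thinner than ``t_um`` is discarded (and logged).
    """
    if t_um <= 0:
        raise InvalidConfigError("section thickness must be positive")
    if t_um >= organ.height_um:
        raise InvalidConfigError("section thickness >= organ height")
    n = int(organ.height_um // t_um)
    remnant = organ.height_um - n * t_um
    if remnant > 1e-12:
        logger.info("sectioning: %d slabs of %g um, remnant %g um discarded",
                    n, t_um, remnant)
    return [(k * t_um, (k + 1) * t_um) for k in range(n)]


def tessellate_tiles(
    cross_section_w_um: float, cross_section_d_um: float, frame_um: float
) -> np.ndarray:
    """Tessellate the cross section with non-overlapping square frames.

    Returns an ``(m, 2)`` array of tile origins ``(x, y)`` in row order
    (y, then x).  Partial edge tiles are excluded -- the unbiased frame has a
    fixed area a(fra) -- and the dropped margin is logged.
    """
    if frame_um <= 0:
        raise InvalidConfigError("frame size must be positive")
    nx = int(cross_section_w_um // frame_um)
    ny = int(cross_section_d_um // frame_um)
    if nx < 1 or ny < 1:
        raise InvalidConfigError("frame larger than the cross section")
    if nx * frame_um < cross_section_w_um or ny * frame_um < cross_section_d_um:
        logger.info("tessellation: margin of %g x %g um dropped (fixed frame)",
                    cross_section_w_um - nx * frame_um,
                    cross_section_d_um - ny * frame_um)
    xs = np.arange(nx) * frame_um
    ys = np.arange(ny) * frame_um
    gx, gy = np.meshgrid(xs, ys)            # row order: y outer, x inner
    return np.column_stack([gx.ravel(), gy.ravel()])


# ---------------------------------------------------------------------------
# stain weights


def _pair_profiles(organ: OrganTruth, k: int, t_um: float) -> list[tuple[int, int]]:
    """Cell profiles present in the two slabs of pair ``k`` (slabs k, k+1).

    Returns ``(cell_index, slab_offset)`` with slab_offset in {0, 1}, in
    deterministic order (slab, then cell index).  Presence = the nucleus
    sphere intersects the half-open slab interval.
    """
    out: list[tuple[int, int]] = []
    if organ.n_true == 0:
        return out
    z = organ.cells[:, 2]
    r = organ.cells[:, 3] / 2.0
    for off in (0, 1):
        lo, hi = (k + off) * t_um, (k + off + 1) * t_um
        present = np.nonzero((z - r < hi) & (z + r > lo))[0]
        out.extend((int(i), off) for i in present)
    return out


def _tile_index(organ: OrganTruth, tiles_xy: np.ndarray, frame_um: float,
                x: float, y: float) -> int:
    """Index into ``tiles_xy`` of the tile containing (x, y), or -1."""
    nx = int(organ.cross_section_w_um // frame_um)
    ny = int(organ.cross_section_d_um // frame_um)
    ix, iy = int(x // frame_um), int(y // frame_um)
    if 0 <= ix < nx and 0 <= iy < ny:
        return iy * nx + ix
    return -1


def _draw_components(
    tiles_xy: np.ndarray,
    frame_um: float,
    organ: OrganTruth,
    k: int,
    t_um: float,
    stain: StainModel,
    rng: np.random.Generator,
):
    """Draw all stochastic weight components for one section pair.

    Returns ``(profile_hits, background, artifact)`` where profile_hits is a
    list of ``(tile_index, cell_index, pixels)`` and the other two are
    per-tile integer arrays.  The draw order is fixed so the tabulated and
    rasterised weight paths consume the identical random stream.
    """
    m = len(tiles_xy)
    profile_hits: list[tuple[int, int, int]] = []
    for ci, _off in _pair_profiles(organ, k, t_um):
        fn = rng.random() < stain.false_negative_rate
        mean = max(stain.pixels_per_cell_mean - 1.0, 0.0)
        if stain.pixel_noise_dispersion > 0 and mean > 0:
            d = stain.pixel_noise_dispersion
            lam = rng.gamma(shape=1.0 / d, scale=mean * d)
            px = 1 + int(rng.poisson(lam))
        else:
            px = 1 + int(rng.poisson(mean))
        if fn:
            continue
        ti = _tile_index(organ, tiles_xy, frame_um,
                         organ.cells[ci, 0], organ.cells[ci, 1])
        if ti >= 0:
            profile_hits.append((ti, ci, px))
    background = rng.poisson(stain.background_rate, size=m).astype(np.int64)
    artifact = np.zeros(m, dtype=np.int64)
    if stain.artifact_rate > 0:
        hit = rng.random(m) < stain.artifact_rate
        nh = int(hit.sum())
        if nh:
            artifact[hit] = 1 + rng.poisson(stain.artifact_pixels_mean, size=nh)
    return profile_hits, background, artifact


def assign_weights(
    tiles_xy: np.ndarray,
    frame_um: float,
    organ: OrganTruth,
    k: int,
    t_um: float,
    stain: StainModel,
    seed,
) -> np.ndarray:
    """Per-tile integer stain weights z_i for section pair ``k``.

    ``seed`` may be an int or an already-constructed Generator (the pipeline
    passes one stream across pairs; pass an int for a standalone call).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    profile_hits, background, artifact = _draw_components(
        tiles_xy, frame_um, organ, k, t_um, stain, rng)
    z = background + artifact
    for ti, _ci, px in profile_hits:
        z[ti] += px
    return z


def _fill_cluster(mask: np.ndarray, cx: int, cy: int, k: int) -> None:
    """Set exactly ``k`` currently-unset pixels, nearest to (cx, cy) first."""
    h, w = mask.shape
    if k <= 0:
        return
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    order = np.argsort(d2.ravel(), kind="stable")
    free = ~mask.ravel()[order]
    take = order[free][:k]
    if len(take) < k:
        raise InvalidConfigError("tile raster too small for its weight")
    flat = mask.ravel()
    flat[take] = True


def render_tile_raster(
    tile_index: int,
    tiles_xy: np.ndarray,
    frame_um: float,
    organ: OrganTruth,
    k: int,
    t_um: float,
    stain: StainModel,
    seed: int,
    *,
    px_per_um: float = 1.0,
) -> TileRaster:
    """Render the specific-pixel mask of one tile of pair ``k``.

    Consumes the same random stream as :func:`assign_weights`, so the mask's
    positive-pixel count equals the tabulated weight for the same seed.  Cell
    profile pixels cluster around the in-tile cell position; background
    pixels scatter uniformly; an artifact blob clusters at a random centre.
    """
    rng = np.random.default_rng(seed)
    profile_hits, background, artifact = _draw_components(
        tiles_xy, frame_um, organ, k, t_um, stain, rng)
    side = int(round(frame_um * px_per_um))
    mask = np.zeros((side, side), dtype=bool)
    x0, y0 = tiles_xy[tile_index]
    for ti, ci, px in profile_hits:
        if ti != tile_index:
            continue
        cx = int((organ.cells[ci, 0] - x0) * px_per_um)
        cy = int((organ.cells[ci, 1] - y0) * px_per_um)
        _fill_cluster(mask, min(cx, side - 1), min(cy, side - 1), px)
    if artifact[tile_index] > 0:
        cx, cy = rng.integers(side), rng.integers(side)
        _fill_cluster(mask, int(cx), int(cy), int(artifact[tile_index]))
    nbg = int(background[tile_index])
    if nbg:
        free = np.nonzero(~mask.ravel())[0]
        if len(free) < nbg:
            raise InvalidConfigError("tile raster too small for its weight")
        sel = rng.choice(free, size=nbg, replace=False)
        flat = mask.ravel()
        flat[sel] = True
    return TileRaster(width_px=side, height_px=side, mask=mask)
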