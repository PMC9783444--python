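"""Box-counting fractal dimension of 3D binary voxel masks.

The estimator covers a region's foreground voxels with a single fixed grid of
axis-aligned cubic boxes of integer edge length ``r`` (in voxels), counts the
boxes containing at least one foreground voxel, repeats while increasing ``r``
by one voxel per step, and fits ``log N(r)`` against ``log r`` by ordinary
least squares.  The magnitude of the slope is the box-counting fractal
dimension (FD).

Conventions
-----------
* The box grid is anchored at the minimal corner of the tight bounding box of
  the foreground, which makes the count deterministic and translation
  invariant.  Partial boxes at the far boundary participate in the count
  (every foreground voxel belongs to some box).
* ``r`` increases linearly, so the fit points are *not* equally spaced on the
  log scale; all points are weighted equally.  This is deliberate and is part
  of the method definition — do not resample to equal log spacing.
* ``r`` is in voxel units throughout.  Voxel size is carried as metadata only;
  a warning is logged when voxels are anisotropic.

Default fitting windows are ``r = 2..30`` for hemisphere cortical ribbon
masks and ``r = 2..14`` for lobar masks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: fitting window (r_min, r_max) in voxels per region class
REGION_WINDOWS: dict[str, tuple[int, int]] = {
    "hemisphere": (2, 30),
    "lobe": (2, 14),
}


class EmptyMaskError(ValueError):
    """Raised when an operation requires foreground voxels and none exist."""


class DegenerateCurveError(ValueError):
    """Raised when a box-count curve cannot support a log-log fit."""


@dataclass(frozen=True)
class BinaryMask:
    """A 3D boolean occupancy grid with voxel geometry metadata.

    Parameters
    ----------
    grid
        3D boolean array; nonzero input is coerced to foreground.
    voxel_size_mm
        Edge lengths of a voxel in mm.  Metadata only; box counting works in
        voxel units.
    """

    grid: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 3:
            raise ValueError(f"mask grid must be 3D, got ndim={g.ndim}")
        if g.dtype != bool:
            g = g != 0
        object.__setattr__(self, "grid", g)
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size_mm must be 3 positive floats, got {self.voxel_size_mm}")
        object.__setattr__(self, "voxel_size_mm", vs)
        if len(set(vs)) > 1:
            logger.warning(
                "anisotropic voxels %s: box counting uses voxel units; "
                "dimension estimates assume isotropy", vs,
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def n_foreground(self) -> int:
        return int(self.grid.sum())


@dataclass(frozen=True)
class BoxCountCurve:
    """Ordered (r, N(r)) pairs for one mask.

    ``r`` is strictly increasing; ``n`` is non-increasing in ``r``.
    """

    r: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=int)
        n = np.asarray(self.n)
        if not np.issubdtype(n.dtype, np.integer):
            n = np.asarray(n, dtype=float)  # exact power-law curves are not integer
        if r.ndim != 1 or r.shape != n.shape:
            raise ValueError("r and n must be 1D arrays of equal length")
        if len(r) and np.any(np.diff(r) <= 0):
            raise ValueError("r must be strictly increasing")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "n", n)

    def __len__(self) -> int:
        return len(self.r)

    def to_frame(self):
        """Curve as a DataFrame with r, n_boxes, log_r, log_n columns."""
        import pandas as pd

        return pd.DataFrame(
            {
                "r": self.r,
                "n_boxes": self.n,
                "log_r": np.log(self.r),
                "log_n": np.log(self.n),
            }
        )


@dataclass(frozen=True)
class FDEstimate:
    """A fitted box-counting dimension with fit diagnostics.

    ``flags`` collects quality warnings ("fd_out_of_range" when fd falls
    outside (0, 3]; "flat_tail" when the last >= 3 curve points are
    identical, i.e. the window outgrew the structure).  Estimates are
    returned flagged rather than raising, so that downstream outlier
    screening can handle pathological masks.
    """

    fd: float
    intercept: float
    r_squared: float
    r_min: int
    r_max: int
    n_points: int
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def ok(self) -> bool:
        return not self.flags


def _as_mask(mask: BinaryMask | np.ndarray) -> BinaryMask:
    if isinstance(mask, BinaryMask):
        return mask
    return BinaryMask(np.asarray(mask))


def _cropped(grid: np.ndarray) -> np.ndarray:
    """Tight bounding box of the foreground (grid anchor)."""
    coords = np.nonzero(grid)
    if coords[0].size == 0:
        raise EmptyMaskError("mask has no foreground voxels")
    slices = tuple(slice(int(c.min()), int(c.max()) + 1) for c in coords)
    return grid[slices]


def count_filled_boxes(mask: BinaryMask | np.ndarray, r: int) -> int:
    """Count boxes of edge ``r`` (voxels) containing >= 1 foreground voxel.

    The grid of non-overlapping r-cubes is anchored at the minimal corner of
    the foreground bounding box; partial boxes at the far boundary count.
    """
    r = int(r)
    if r < 1:
        raise ValueError(f"box edge r must be >= 1, got {r}")
    sub = _cropped(_as_mask(mask).grid)
    pad = [(0, (-s) % r) for s in sub.shape]
    if any(p for _, p in pad):
        sub = np.pad(sub, pad)
    a, b, c = (s // r for s in sub.shape)
    return int(sub.reshape(a, r, b, r, c, r).any(axis=(1, 3, 5)).sum())


def box_count_curve(mask: BinaryMask | np.ndarray, r_min: int = 2, r_max: int = 30) -> BoxCountCurve:
    """Box counts for every integer ``r`` in ``[r_min, r_max]`` (step 1)."""
    r_min, r_max = int(r_min), int(r_max)
    if not 2 <= r_min < r_max:
        raise ValueError(f"need 2 <= r_min < r_max, got ({r_min}, {r_max})")
    mask = _as_mask(mask)
    rs = np.arange(r_min, r_max + 1)
    ns = np.array([count_filled_boxes(mask, int(r)) for r in rs])
    return BoxCountCurve(rs, ns)


def estimate_fd(curve: BoxCountCurve) -> FDEstimate:
    """OLS fit of ``log N`` on ``log r``; FD is the slope magnitude.

    All curve points are used and equally weighted; the linear r grid is
    non-equally spaced in log by construction.  Natural logs (the slope
    magnitude is base invariant).
    """
    if len(curve) < 2:
        raise DegenerateCurveError(f"need >= 2 curve points, got {len(curve)}")
    if np.any(curve.n < 1):
        raise DegenerateCurveError("curve contains n = 0; log N undefined")
    x = np.log(curve.r.astype(float))
    y = np.log(curve.n.astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    fd = abs(float(slope))
    flags: list[str] = []
    if not 0.0 < fd <= 3.0:
        flags.append("fd_out_of_range")
        logger.warning("fd=%.4f outside (0, 3]; flagging estimate", fd)
    tail = curve.n[::-1]
    n_flat = int(np.argmax(tail != tail[0])) if np.any(tail != tail[0]) else len(tail)
    if n_flat >= 3:
        flags.append("flat_tail")
    return FDEstimate(
        fd=fd,
        intercept=float(intercept),
        r_squared=r2,
        r_min=int(curve.r[0]),
        r_max=int(curve.r[-1]),
        n_points=len(curve),
        flags=tuple(flags),
    )


def region_fd(mask: BinaryMask | np.ndarray, region_class: str = "hemisphere") -> FDEstimate:
    """FD with the standard fitting window for a region class.

    ``region_class`` is "hemisphere" (r = 2..30) or "lobe" (r = 2..14).
    """
    try:
        r_min, r_max = REGION_WINDOWS[region_class]
    except KeyError:
        raise ValueError(
            f"unknown region class {region_class!r}; expected one of {sorted(REGION_WINDOWS)}"
        ) from None
    mask = _as_mask(mask)
    if mask.n_foreground < 2:
        raise EmptyMaskError(
            f"FD requires >= 2 foreground voxels, mask has {mask.n_foreground}"
        )
    return estimate_fd(box_count_curve(mask, r_min, r_max))


def brute_force_count(grid: np.ndarray, r: int) -> int:
    """Naive reference box count: explicit loop over every grid box.

    Independent oracle for :func:`count_filled_boxes`; O(boxes * r^3) and
    only meant for small masks in tests.
    """
    grid = np.asarray(grid) != 0
    coords = np.nonzero(grid)
    if coords[0].size == 0:
        raise EmptyMaskError("mask has no foreground voxels")
    lo = [int(c.min()) for c in coords]
    hi = [int(c.max()) for c in coords]
    count = 0
    for i in range(lo[0], hi[0] + 1, r):
        for j in range(lo[1], hi[1] + 1, r):
            for k in range(lo[2], hi[2] + 1, r):
                if grid[i : i + r, j : j + r, k : k + r].any():
                    count += 1
    return count
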