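"""Hemisphere and lobar binary masks from a Desikan-Killiany label volume.

Volumetric DK (aparc-style) outputs code left cortical regions as 1001-1035
and right cortical regions as 2001-2035.  The lobe grouping used here assigns
29 regions per hemisphere to the frontal (11), temporal (9), parietal (5) and
occipital (4) lobes; the insula (x035) and the cingulate regions (x002, x010,
x023, x026) belong to no lobe and are excluded from lobar masks.  Right-
hemisphere label sets are always the left sets shifted by +1000.

The grouping ships as a versioned CSV resource (``data/dk_lobes.csv`` with
columns lobe, hemisphere, label, name) so alternate dialects can be supplied.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .fd import BinaryMask, FDEstimate, region_fd

logger = logging.getLogger(__name__)

LOBES = ("frontal", "temporal", "parietal", "occipital")
HEMISPHERES = ("left", "right")

#: offset between a left DK cortical label and its right homologue
RIGHT_OFFSET = 1000

#: full cortical label ranges (used for label-derived hemisphere masks)
LEFT_CORTEX_RANGE = range(1001, 1036)
RIGHT_CORTEX_RANGE = range(2001, 2036)

#: short region keys in output-table order
REGION_KEYS = ("lh", "rh", "lf", "rf", "lt", "rt", "lp", "rp", "lo", "ro")


class EmptyRegionError(ValueError):
    """No voxel of the volume carries any label of the requested set."""

    def __init__(self, label_set: frozenset[int]):
        self.label_set = label_set
        super().__init__(f"no voxel matches labels {sorted(label_set)}")


def _load_lobe_table() -> dict[str, frozenset[int]]:
    table: dict[str, set[int]] = {lobe: set() for lobe in LOBES}
    src = resources.files("ribbonfd").joinpath("data/dk_lobes.csv")
    with src.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            table[row["lobe"]].add(int(row["label"]))
    return {lobe: frozenset(labels) for lobe, labels in table.items()}


#: left-hemisphere DK labels per lobe, loaded from the CSV resource
LEFT_LOBE_LABELS: dict[str, frozenset[int]] = _load_lobe_table()


@dataclass(frozen=True)
class RegionSpec:
    """A (lobe, hemisphere) pair naming one of the 8 lobar regions.

    ``lobe`` may also be "hemisphere" for whole-hemisphere regions, but
    :func:`labels_for_region` rejects that value: hemisphere masks come from
    the ribbon volumes (or the union of all cortical labels), not a lobe set.
    """

    lobe: str
    hemisphere: str

    def __post_init__(self) -> None:
        if self.lobe not in LOBES + ("hemisphere",):
            raise ValueError(f"unknown lobe {self.lobe!r}; expected one of {LOBES + ('hemisphere',)}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}; expected one of {HEMISPHERES}")


@dataclass(frozen=True)
class LabelVolume:
    """3D integer label grid in the DK 1000/2000 coding."""

    grid: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    label_space: str = "dk-aparc"

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 3:
            raise ValueError(f"label grid must be 3D, got ndim={g.ndim}")
        if not np.issubdtype(g.dtype, np.integer):
            if not np.all(g == np.round(g)):
                raise ValueError("label grid must contain integers")
            g = g.astype(np.int32)
        if g.size and g.min() < 0:
            raise ValueError("labels must be non-negative")
        object.__setattr__(self, "grid", g)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape


def labels_for_region(spec: RegionSpec) -> frozenset[int]:
    """The DK label codes of one lobar region.

    Right-hemisphere sets are the left sets + 1000.
    """
    if spec.lobe == "hemisphere":
        raise ValueError(
            "hemisphere masks are not label-set based; use hemisphere_mask() "
            "or supply ribbon volumes"
        )
    left = LEFT_LOBE_LABELS[spec.lobe]
    if spec.hemisphere == "left":
        return left
    return frozenset(x + RIGHT_OFFSET for x in left)


def region_mask(labels: LabelVolume, label_set: frozenset[int] | set[int]) -> BinaryMask:
    """Binary mask of the voxels whose label is in ``label_set``."""
    if not label_set:
        raise ValueError("label_set must be nonempty")
    grid = np.isin(labels.grid, sorted(label_set))
    if not grid.any():
        raise EmptyRegionError(frozenset(label_set))
    return BinaryMask(grid, labels.voxel_size_mm)


def hemisphere_mask(labels: LabelVolume, hemisphere: str) -> BinaryMask:
    """Hemisphere mask as the union of all cortical labels of one side.

    A substitute for a ribbon volume on the synthetic/label-only path; the
    substitution is recorded in output provenance by callers.
    """
    rng = LEFT_CORTEX_RANGE if hemisphere == "left" else RIGHT_CORTEX_RANGE
    return region_mask(labels, frozenset(rng))


def subject_fd_table(
    ribbon_left: BinaryMask | None,
    ribbon_right: BinaryMask | None,
    labels: LabelVolume,
) -> dict[str, FDEstimate | None]:
    """The 10 regional FD measures of one subject.

    Hemisphere FDs use the ribbon masks (hemisphere window, r = 2..30); when a
    ribbon is None it is substituted by the union of that side's cortical
    labels.  The 8 lobar FDs come from label-derived masks (lobe window,
    r = 2..14).  Empty regions are returned as None (flagged missing) while
    the remaining regions are still computed.

    Returns a dict keyed lh, rh, lf, rf, lt, rt, lp, rp, lo, ro.
    """
    for name, vol in (("ribbon_left", ribbon_left), ("ribbon_right", ribbon_right)):
        if vol is not None and vol.shape != labels.shape:
            raise ValueError(
                f"{name} shape {vol.shape} does not match label volume shape {labels.shape}"
            )

    out: dict[str, FDEstimate | None] = {}

    def _safe(key: str, fn):
        try:
            out[key] = fn()
        except (EmptyRegionError, ValueError) as exc:
            logger.warning("region %s missing: %s", key, exc)
            out[key] = None

    for key, hemi, ribbon in (("lh", "left", ribbon_left), ("rh", "right", ribbon_right)):
        if ribbon is None:
            _safe(key, lambda hemi=hemi: region_fd(hemisphere_mask(labels, hemi), "hemisphere"))
        else:
            _safe(key, lambda ribbon=ribbon: region_fd(ribbon, "hemisphere"))

    short = {"frontal": "f", "temporal": "t", "parietal": "p", "occipital": "o"}
    for lobe in LOBES:
        for hemi in HEMISPHERES:
            key = hemi[0] + short[lobe]
            spec = RegionSpec(lobe, hemi)
            _safe(key, lambda spec=spec: region_fd(region_mask(labels, labels_for_region(spec)), "lobe"))
    return {key: out[key] for key in REGION_KEYS}
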