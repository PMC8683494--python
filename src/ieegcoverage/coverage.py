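"""Radius-of-influence (RoI) coverage: union-of-spheres masks and
probability-weighted gray/white-matter volumes.

Each contact's recording volume is modeled as a sphere of radius r around
its centroid. Per patient, the *union* of all contact spheres is taken —
overlapping spheres count each voxel once, which is what makes closely
spaced leads "redundant" — and the covered volume of a tissue is

    sum over voxels in the union of  p_tissue(voxel) * voxel_volume,

with subcortical and cerebellar parcels excluded from gray- and white-matter
totals. Sweeping r from 1 to 15 mm in 0.5 mm steps gives the coverage curve;
dividing by the patient's contact count gives per-contact coverage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .electrodes import ElectrodeSet
from .grid import VolumeGrid
from .surface import contact_hemisphere
from .volumes import AtlasLabels, HemisphereMasks, TissueProbabilityVolumes

log = logging.getLogger(__name__)

NAMED_RADII_MM = (2.5, 5.0, 10.0, 15.0)


def default_radii() -> np.ndarray:
    """The swept radii: 1 mm to 15 mm at 0.5 mm intervals."""
    return np.round(np.arange(1.0, 15.0 + 1e-9, 0.5), 3)


@dataclass(frozen=True)
class RoiSweepConfig:
    radii_mm: tuple = field(default_factory=lambda: tuple(default_radii()))
    named_radii_mm: tuple = NAMED_RADII_MM
    restrict_wm: bool = True  # hemisphere-restrict white matter too
    tie_break: str = "left"

    def __post_init__(self) -> None:
        r = np.asarray(self.radii_mm, dtype=float)
        if len(r) == 0 or np.any(r <= 0) or np.any(np.diff(r) <= 0):
            raise ValueError("radii must be strictly increasing and positive")


# ---------------------------------------------------------------------------
# Mask primitives
# ---------------------------------------------------------------------------


def min_distance_field(
    centers: np.ndarray, grid: VolumeGrid, r_max: float
) -> np.ndarray:
    """Per-voxel distance to the nearest center, computed only within r_max
    (inf elsewhere). One field serves every radius of the sweep, so the
    union mask at radius r is simply ``field <= r``."""
    D2 = np.full(grid.shape, np.inf)
    centers = np.atleast_2d(centers)
    if centers.size == 0:
        return D2
    xs, ys, zs = grid.axis_coords()
    for c in centers:
        sl = []
        for ax, coords in zip(range(3), (xs, ys, zs)):
            idx = np.nonzero(np.abs(coords - c[ax]) <= r_max)[0]
            if len(idx) == 0:
                sl = None
                break
            sl.append(slice(idx[0], idx[-1] + 1))
        if sl is None:
            continue
        d2 = (
            (xs[sl[0]] - c[0])[:, None, None] ** 2
            + (ys[sl[1]] - c[1])[None, :, None] ** 2
            + (zs[sl[2]] - c[2])[None, None, :] ** 2
        )
        region = D2[tuple(sl)]
        np.minimum(region, d2, out=region)
    return np.sqrt(D2, out=D2)


def sphere_mask(center: np.ndarray, r_mm: float, grid: VolumeGrid) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within r of the point."""
    if r_mm <= 0:
        raise ValueError("radius must be positive")
    mask = min_distance_field(np.asarray(center, dtype=float), grid, r_mm) <= r_mm
    if not mask.any():
        warnings.warn(f"sphere at {center} r={r_mm} mm lies outside the grid")
    return mask


def union_mask(masks: list[np.ndarray]) -> np.ndarray:
    """Voxelwise OR of RoI masks on one shared grid."""
    if not masks:
        raise ValueError("need at least one mask")
    shapes = {m.shape for m in masks}
    if len(shapes) > 1:
        raise ValueError(f"masks live on different grids: shapes {shapes}")
    out = np.zeros(masks[0].shape, dtype=bool)
    for m in masks:
        out |= m
    return out


def weighted_volume(
    mask: np.ndarray,
    prob_map: np.ndarray,
    grid: VolumeGrid,
    exclusion: np.ndarray | None = None,
) -> float:
    """Probability-weighted tissue volume (mm^3) inside a mask."""
    prob_map = np.asarray(prob_map)
    if mask.shape != grid.shape or prob_map.shape != grid.shape:
        raise ValueError("mask/probability shape does not match grid")
    if prob_map.min() < -1e-9 or prob_map.max() > 1 + 1e-9:
        raise ValueError("probabilities outside [0, 1]")
    m = mask if exclusion is None else (mask & ~exclusion)
    return float(prob_map[m].sum() * grid.voxel_volume)


# ---------------------------------------------------------------------------
# Coverage sweep
# ---------------------------------------------------------------------------


@dataclass
class CoverageCurve:
    """Total and per-contact covered volume per tissue across the radius sweep."""

    patient_id: str
    implant_class: str
    n_contacts: int
    table: pd.DataFrame  # columns: radius_mm, tissue, scope, volume_mm3

    def value(self, radius_mm: float, tissue: str, scope: str = "per_contact") -> float:
        t = self.table
        row = t[
            (np.isclose(t.radius_mm, radius_mm))
            & (t.tissue == tissue)
            & (t.scope == scope)
        ]
        if row.empty:
            raise KeyError(f"no entry for r={radius_mm}, {tissue}, {scope}")
        return float(row.volume_mm3.iloc[0])

    def series(self, tissue: str, scope: str = "per_contact") -> pd.Series:
        t = self.table
        sel = t[(t.tissue == tissue) & (t.scope == scope)].sort_values("radius_mm")
        return pd.Series(sel.volume_mm3.values, index=sel.radius_mm.values)

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "patient_id", self.patient_id)
        out.insert(1, "implant_class", self.implant_class)
        out.to_csv(path, index=False)


def _split_by_restriction(
    electrodes: ElectrodeSet, midline_x: float, tie_break: str
) -> dict[str, np.ndarray]:
    """Contact centers grouped by hemisphere restriction (none/left/right)."""
    groups: dict[str, list[np.ndarray]] = {"free": [], "left": [], "right": []}
    for c in electrodes:
        if c.interhemispheric:
            groups[contact_hemisphere(c, midline_x, tie_break)].append(c.position)
        else:
            groups["free"].append(c.position)
    return {k: np.array(v).reshape(-1, 3) for k, v in groups.items()}


def union_roi_mask(
    distance_fields: dict[str, np.ndarray],
    r_mm: float,
    hemispheres: HemisphereMasks | None,
) -> np.ndarray:
    mask = distance_fields["free"] <= r_mm
    for side in ("left", "right"):
        if np.isfinite(distance_fields[side]).any():
            side_mask = distance_fields[side] <= r_mm
            if hemispheres is not None:
                side_mask &= hemispheres.mask_for(side)
            mask |= side_mask
    return mask


def coverage_distance_fields(
    electrodes: ElectrodeSet,
    grid: VolumeGrid,
    r_max: float,
    midline_x: float,
    tie_break: str = "left",
) -> dict[str, np.ndarray]:
    groups = _split_by_restriction(electrodes, midline_x, tie_break)
    return {k: min_distance_field(v, grid, r_max) for k, v in groups.items()}


def coverage_sweep(
    electrodes: ElectrodeSet,
    tissue: TissueProbabilityVolumes,
    atlas: AtlasLabels | None,
    hemispheres: HemisphereMasks | None,
    config: RoiSweepConfig = RoiSweepConfig(),
    midline_x: float | None = None,
) -> CoverageCurve:
    """Sweep the RoI radius and return total and per-contact GM/WM coverage.

    Strip/grid contacts are assumed already projected to the cortical
    surface. Interhemispheric contacts have their spheres clipped to their
    own hemisphere (gray and, by default, white matter alike); subcortical
    and cerebellar parcels are excluded from both tissue totals.
    """
    if len(electrodes) == 0:
        raise ValueError("electrode set is empty")
    grid = tissue.grid
    if midline_x is None:
        midline_x = float(np.mean(grid.axis_coords()[0]))
    radii = np.asarray(config.radii_mm, dtype=float)
    fields = coverage_distance_fields(
        electrodes, grid, radii.max(), midline_x, config.tie_break
    )
    excl = atlas.exclusion_mask() if atlas is not None else None
    rows = []
    for r in radii:
        mask = union_roi_mask(fields, r, hemispheres)
        if not config.restrict_wm:
            wm_mask = union_roi_mask(fields, r, None)
        else:
            wm_mask = mask
        gm = weighted_volume(mask, tissue.p_gm, grid, excl)
        wm = weighted_volume(wm_mask, tissue.p_wm, grid, excl)
        n = len(electrodes)
        rows += [
            {"radius_mm": r, "tissue": "gm", "scope": "total", "volume_mm3": gm},
            {"radius_mm": r, "tissue": "wm", "scope": "total", "volume_mm3": wm},
            {"radius_mm": r, "tissue": "gm", "scope": "per_contact", "volume_mm3": gm / n},
            {"radius_mm": r, "tissue": "wm", "scope": "per_contact", "volume_mm3": wm / n},
        ]
    return CoverageCurve(
        electrodes.patient_id,
        electrodes.implant_class,
        len(electrodes),
        pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# Region-specific coverage
# ---------------------------------------------------------------------------


@dataclass
class RegionCoverage:
    patient_id: str
    implant_class: str
    radius_mm: float
    table: pd.DataFrame  # columns: region_id, region, volume_mm3

    def volume(self, region: str) -> float:
        row = self.table[self.table.region == region]
        if row.empty:
            raise KeyError(f"unknown region {region!r}")
        return float(row.volume_mm3.iloc[0])


def region_coverage(
    electrodes: ElectrodeSet,
    atlas: AtlasLabels,
    tissue: TissueProbabilityVolumes,
    radius_mm: float,
    hemispheres: HemisphereMasks | None = None,
    midline_x: float | None = None,
    tie_break: str = "left",
) -> RegionCoverage:
    """Gray-matter coverage inside each analysis parcel at one radius."""
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    grid = tissue.grid
    if midline_x is None:
        midline_x = float(np.mean(grid.axis_coords()[0]))
    fields = coverage_distance_fields(electrodes, grid, radius_mm, midline_x, tie_break)
    mask = union_roi_mask(fields, radius_mm, hemispheres)
    rows = []
    for rid in atlas.analysis_ids:
        vol = weighted_volume(mask & atlas.mask(rid), tissue.p_gm, grid)
        rows.append(
            {"region_id": rid, "region": atlas.lut[rid], "volume_mm3": vol}
        )
    return RegionCoverage(
        electrodes.patient_id, electrodes.implant_class, radius_mm, pd.DataFrame(rows)
    )


def regional_inclusion(
    region_cov: RegionCoverage, threshold_mm3: float = 0.0
) -> dict[str, bool]:
    """Per-region inclusion flag: a patient counts for a region only if the
    region has coverage at the reference radius (5 mm in the standard
    analysis); zero-coverage regions were likely outside the localization
    hypothesis and are excluded from group comparisons."""
    return {
        str(r.region): bool(r.volume_mm3 > threshold_mm3)
        for r in region_cov.table.itertuples()
    }
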