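"""Synthetic gyrified phantom "patients" and electrode layouts.

Real analyses of intracranial coverage start from patient MRI segmentations
and CT-localized contacts; neither can ship with a library. This module
builds everything downstream stages need from closed-form geometry:

* a two-hemisphere phantom whose gray-matter ribbon is a sinusoidally folded
  sheet of fixed cortical thickness over white matter, with CSF above and in
  the interhemispheric fissure, expressed as partial-volume probability maps
  (logistic in the signed distance to each tissue boundary);
* axis-aligned atlas parcels (frontal, temporal, hippocampus, amygdala,
  insula, cingulate, plus excluded subcortical and cerebellar blocks)
  intersected with the tissue they occupy;
* electrode layouts with clinical geometry — depth leads at 5 mm
  inter-contact spacing, subdural strips/grids at 10 mm spacing — and an
  inward displacement of subdural contacts that emulates intraoperative
  brain shift.

The folding matters: spheres centered on subdural contacts, which ride the
smooth envelope of the brain, partially miss sulcal gray matter, while depth
leads reach it and the deep nuclei. That geometric asymmetry is what the
coverage analysis downstream is designed to quantify.

Axis convention: x = left-right (the interhemispheric plane is x = extent_x/2),
y = posterior-anterior, z = inferior-superior. World units are mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .electrodes import Contact, ElectrodeSet
from .grid import VolumeGrid
from .volumes import (
    CLASS_ANALYSIS,
    CLASS_CEREBELLUM,
    CLASS_SUBCORTICAL,
    AtlasLabels,
    HemisphereMasks,
    TissueProbabilityVolumes,
)


class InvalidSpecError(ValueError):
    pass


class OutOfBoundsError(ValueError):
    pass


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the synthetic head phantom.

    The gray-matter ribbon occupies the band
    ``z_top(x, y) - cortical_thickness <= z <= z_top(x, y)`` with

        z_top(x, y) = (extent_z - csf_thickness)
                      + gyral_amplitude * sin(2*pi*x / wavelength)
                                        * cos(2*pi*y / wavelength)

    — an egg-crate folding whose gyral crowns are finite bumps in both
    lateral axes, so the white-matter cores beneath them are bounded blobs
    rather than infinite walls, as in a real gyrified cortex. White matter
    fills everything below the ribbon, CSF everything above and the
    interhemispheric gap. ``softness`` is the width (mm) of the logistic
    partial-volume ramp applied to every signed-distance boundary; 0 gives
    hard binary tissue.
    """

    extent_mm: tuple[float, float, float] = (120.0, 120.0, 100.0)
    voxel_mm: float = 1.0
    cortical_thickness_mm: float = 3.0
    gyral_wavelength_mm: float = 15.0
    gyral_amplitude_mm: float = 10.0
    csf_thickness_mm: float = 15.0
    interhemispheric_gap_mm: float = 4.0
    softness_mm: float = 1.0
    include_deep_structures: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cortical_thickness_mm <= 0:
            raise InvalidSpecError("cortical thickness must be positive")
        if self.csf_thickness_mm <= 0 or min(self.extent_mm) <= 0 or self.voxel_mm <= 0:
            raise InvalidSpecError("extents, CSF thickness and voxel size must be positive")
        if self.softness_mm < 0:
            raise InvalidSpecError("softness must be non-negative")
        if self.gyral_amplitude_mm < 0 or self.gyral_wavelength_mm <= 0:
            raise InvalidSpecError("gyral amplitude must be >= 0, wavelength > 0")
        if self.gyral_amplitude_mm >= self.csf_thickness_mm:
            raise InvalidSpecError("gyral crests would pierce the top of the volume")

    # --- analytic geometry helpers (used for electrode placement) ---------

    @property
    def midline_x(self) -> float:
        return self.extent_mm[0] / 2.0

    @property
    def gm_top_mean_z(self) -> float:
        return self.extent_mm[2] - self.csf_thickness_mm

    @property
    def envelope_z(self) -> float:
        """Height of the smooth brain envelope (tangent to gyral crests)."""
        return self.gm_top_mean_z + self.gyral_amplitude_mm

    def surface_z(self, x: np.ndarray, y: np.ndarray = 0.0) -> np.ndarray:
        """Gray-matter top surface height at lateral position (x, y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        k = 2 * np.pi / self.gyral_wavelength_mm
        return self.gm_top_mean_z + self.gyral_amplitude_mm * np.sin(k * x) * np.cos(
            k * y
        )

    def crest_x(self, k: int) -> float:
        """x of the k-th gyral crest (where sin == +1)."""
        return (0.25 + k) * self.gyral_wavelength_mm

    def make_grid(self) -> VolumeGrid:
        shape = tuple(int(round(e / self.voxel_mm)) for e in self.extent_mm)
        # voxel centers at (i + 0.5) * voxel so the lattice tiles [0, extent]
        origin = (self.voxel_mm / 2.0,) * 3
        return VolumeGrid.from_spacing(shape, self.voxel_mm, origin)


# Deep structure boxes, defined per hemisphere as (name, class,
# (x_lo, x_hi) offsets from the hemisphere's inner edge going laterally,
# (y_lo, y_hi), (z_lo, z_hi)) in mm. Hippocampus and amygdala are gray-matter
# nuclei that only depth electrodes can reach; subcortical and cerebellum are
# gray matter excluded from coverage totals.
_DEEP_BOXES = [
    ("hippocampus", CLASS_ANALYSIS, (18.0, 34.0), (25.0, 45.0), (28.0, 46.0)),
    ("amygdala", CLASS_ANALYSIS, (18.0, 34.0), (45.0, 58.0), (28.0, 46.0)),
    ("subcortical", CLASS_SUBCORTICAL, (6.0, 20.0), (58.0, 84.0), (28.0, 45.0)),
]
_CEREBELLUM_BOX = ((20.0, 100.0), (2.0, 18.0), (2.0, 28.0))

# Atlas parcel bands along y intersected with the cortical ribbon.
_CORTICAL_BANDS = [
    ("temporal", (20.0, 50.0)),
    ("insula", (50.0, 62.0)),
    ("cingulate", (62.0, 74.0)),
    ("frontal", (74.0, 1e9)),
]

REGION_IDS = {
    "frontal": 1,
    "temporal": 2,
    "hippocampus": 3,
    "amygdala": 4,
    "insula": 5,
    "cingulate": 6,
    "subcortical": 7,
    "cerebellum": 8,
}


def _logistic(signed_dist: np.ndarray, softness: float) -> np.ndarray:
    """Membership weight: 1 deep inside (positive distance), 0 outside."""
    if softness == 0:
        return (signed_dist > 0).astype(float)
    return 1.0 / (1.0 + np.exp(np.clip(-signed_dist / softness, -60, 60)))


def _box_signed_distance(
    x: np.ndarray, y: np.ndarray, z: np.ndarray, box
) -> np.ndarray:
    (x0, x1), (y0, y1), (z0, z1) = box
    d = np.minimum(x - x0, x1 - x)
    d = np.minimum(d, np.minimum(y - y0, y1 - y))
    return np.minimum(d, np.minimum(z - z0, z1 - z))


def _deep_box_world(spec: PhantomSpec, lateral: tuple[float, float], side: str):
    """Convert a lateral-offset box to world x for one hemisphere."""
    cx = spec.midline_x
    if side == "left":
        return (cx - lateral[1], cx - lateral[0])
    return (cx + lateral[0], cx + lateral[1])


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[TissueProbabilityVolumes, AtlasLabels, HemisphereMasks]:
    """Build tissue probability maps, atlas labels and hemisphere masks.

    Deterministic: the same spec always yields bit-identical volumes (the
    spec's seed participates only in cohort-level layout jitter, not here).
    """
    grid = spec.make_grid()
    cx_, cy_, cz_ = grid.axis_coords()
    x = cx_[:, None, None]
    y = cy_[None, :, None]
    z = cz_[None, None, :]
    s = spec.softness_mm

    z_top = spec.surface_z(x, y)
    z_bot = z_top - spec.cortical_thickness_mm

    # Layered model: CSF above the ribbon, WM below, GM in between.
    w_csf = _logistic(z - z_top, s)
    w_wm = _logistic(z_bot - z, s)
    p_csf = np.broadcast_to(w_csf, grid.shape).copy()
    p_wm = np.broadcast_to(w_wm, grid.shape).copy()
    p_gm = np.clip(1.0 - p_csf - p_wm, 0.0, 1.0)

    # Deep gray-matter structures replace the tissue they sit in.
    label = np.zeros(grid.shape, dtype=np.int16)
    if spec.include_deep_structures:
        for name, _cls, lateral, ybox, zbox in _DEEP_BOXES:
            for side in ("left", "right"):
                box = (_deep_box_world(spec, lateral, side), ybox, zbox)
                w = _logistic(_box_signed_distance(x, y, z, box), s)
                w = np.broadcast_to(w, grid.shape)
                p_gm = p_gm * (1 - w) + w
                p_wm = p_wm * (1 - w)
                p_csf = p_csf * (1 - w)
                label[w > 0.5] = REGION_IDS[name]
        w = _logistic(_box_signed_distance(x, y, z, _CEREBELLUM_BOX), s)
        w = np.broadcast_to(w, grid.shape)
        p_gm = p_gm * (1 - w) + w
        p_wm = p_wm * (1 - w)
        p_csf = p_csf * (1 - w)
        label[w > 0.5] = REGION_IDS["cerebellum"]

    # Interhemispheric fissure: CSF cuts through everything.
    half_gap = spec.interhemispheric_gap_mm / 2.0
    if half_gap > 0:
        w_gap = _logistic(half_gap - np.abs(x - spec.midline_x), s)
        w_gap = np.broadcast_to(w_gap, grid.shape)
        p_csf = p_csf * (1 - w_gap) + w_gap
        p_gm = p_gm * (1 - w_gap)
        p_wm = p_wm * (1 - w_gap)
        label[w_gap > 0.5] = 0

    tissue = TissueProbabilityVolumes(grid, p_gm, p_wm, p_csf)

    # Cortical parcels: y-bands intersected with the ribbon (by construction,
    # not by thresholding the soft maps, so parcel volumes are auditable).
    ribbon = np.broadcast_to((z <= z_top) & (z > z_bot), grid.shape) & (label == 0)
    if half_gap > 0:
        ribbon = ribbon & np.broadcast_to(
            np.abs(x - spec.midline_x) > half_gap, grid.shape
        )
    yy = np.broadcast_to(y, grid.shape)
    for name, (y0, y1) in _CORTICAL_BANDS:
        label[ribbon & (yy >= y0) & (yy < y1)] = REGION_IDS[name]

    lut = {rid: name for name, rid in REGION_IDS.items()}
    region_class = {rid: CLASS_ANALYSIS for rid in lut}
    region_class[REGION_IDS["subcortical"]] = CLASS_SUBCORTICAL
    region_class[REGION_IDS["cerebellum"]] = CLASS_CEREBELLUM
    atlas = AtlasLabels(grid, label, lut, region_class)

    xx = np.broadcast_to(x, grid.shape)
    left = xx <= spec.midline_x
    hemis = HemisphereMasks(grid, left, ~left)
    return tissue, atlas, hemis


# ---------------------------------------------------------------------------
# Electrode layout generators
# ---------------------------------------------------------------------------


def _check_bounds(positions: np.ndarray, grid: VolumeGrid | None) -> None:
    if grid is not None and not np.all(grid.contains_world(positions)):
        raise OutOfBoundsError("lead extends outside the volume grid")


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("direction vector has zero length")
    return v / n


def generate_strip(
    n: int,
    spacing_mm: float = 10.0,
    anchor: np.ndarray = (0.0, 0.0, 0.0),
    direction: np.ndarray = (1.0, 0.0, 0.0),
    lead_id: str = "strip1",
    patient_id: str = "phantom",
    interhemispheric: bool = False,
    grid: VolumeGrid | None = None,
) -> ElectrodeSet:
    """A 1-D subdural strip: ``n`` disc contacts from ``anchor`` along ``direction``."""
    if n < 1 or spacing_mm <= 0:
        raise ValueError("need n >= 1 and positive spacing")
    u = _unit(direction)
    pos = np.asarray(anchor, dtype=float) + np.arange(n)[:, None] * spacing_mm * u
    _check_bounds(pos, grid)
    contacts = [
        Contact(f"{lead_id}-{i + 1}", lead_id, "strip", pos[i], interhemispheric)
        for i in range(n)
    ]
    return ElectrodeSet(contacts, patient_id)


def generate_grid(
    rows: int,
    cols: int,
    spacing_mm: float = 10.0,
    anchor: np.ndarray = (0.0, 0.0, 0.0),
    row_dir: np.ndarray = (0.0, 1.0, 0.0),
    col_dir: np.ndarray = (1.0, 0.0, 0.0),
    lead_id: str = "grid1",
    patient_id: str = "phantom",
    grid: VolumeGrid | None = None,
) -> ElectrodeSet:
    """A rows x cols subdural grid array in the plane spanned by the two axes."""
    if rows < 1 or cols < 1 or spacing_mm <= 0:
        raise ValueError("need rows, cols >= 1 and positive spacing")
    u, v = _unit(row_dir), _unit(col_dir)
    if abs(np.dot(u, v)) > 1e-9:
        raise ValueError("grid axes must be orthogonal")
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    pos = (
        np.asarray(anchor, dtype=float)
        + rr.ravel()[:, None] * spacing_mm * u
        + cc.ravel()[:, None] * spacing_mm * v
    )
    _check_bounds(pos, grid)
    contacts = [
        Contact(f"{lead_id}-{i + 1}", lead_id, "grid", pos[i])
        for i in range(rows * cols)
    ]
    return ElectrodeSet(contacts, patient_id)


def generate_depth(
    n: int,
    spacing_mm: float = 5.0,
    entry: np.ndarray = (0.0, 0.0, 100.0),
    target: np.ndarray = (0.0, 0.0, 50.0),
    lead_id: str = "depth1",
    patient_id: str = "phantom",
    grid: VolumeGrid | None = None,
) -> ElectrodeSet:
    """A depth (SEEG) lead: cylinder contacts on the entry->target segment.

    Contact 1 sits at the target (lead tip) and successive contacts step back
    toward the entry, the usual numbering on clinical depth leads.
    """
    if n < 1 or spacing_mm <= 0:
        raise ValueError("need n >= 1 and positive spacing")
    entry = np.asarray(entry, dtype=float)
    target = np.asarray(target, dtype=float)
    back = _unit(entry - target)
    span = (n - 1) * spacing_mm
    if span > np.linalg.norm(entry - target) + 1e-9:
        raise OutOfBoundsError("lead span exceeds the entry-target segment")
    pos = target + np.arange(n)[:, None] * spacing_mm * back
    _check_bounds(pos, grid)
    contacts = [
        Contact(f"{lead_id}-{i + 1}", lead_id, "depth", pos[i]) for i in range(n)
    ]
    return ElectrodeSet(contacts, patient_id)


def apply_brain_shift(
    electrodes: ElectrodeSet,
    displacement_mm: float,
    direction: np.ndarray = (0.0, 0.0, -1.0),
) -> ElectrodeSet:
    """Translate subdural (strip/grid) contacts by a rigid displacement.

    Emulates the intraoperative inward shift of the brain surface that makes
    CT-localized subdural contacts appear inside the brain; depth contacts
    are left untouched.
    """
    if displacement_mm < 0:
        raise ValueError("displacement must be >= 0")
    shift = displacement_mm * _unit(direction)
    moved = [
        c.moved_to(c.position + shift) if c.modality in ("strip", "grid") else c
        for c in electrodes.contacts
    ]
    return ElectrodeSet(moved, electrodes.patient_id, electrodes.implant_class)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Synthetic cohort layout. Counts are patients per implant class."""

    n_per_class: dict = field(
        default_factory=lambda: {"S": 2, "S+G": 2, "S+G+D": 2, "D": 2}
    )
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    layout_jitter_mm: float = 2.0
    brain_shift_mm: float = 10.0
    strip_len: int = 6
    n_strips: int = 6
    grid_shape: tuple[int, int] = (4, 6)
    depth_len: int = 10
    n_depth_leads: int = 8
    subdural_spacing_mm: float = 10.0
    depth_spacing_mm: float = 5.0
    include_interhemispheric: bool = True
    seed: int = 0


@dataclass
class SyntheticPatient:
    patient_id: str
    implant_class: str
    electrodes: ElectrodeSet  # post-brain-shift, as "localized from CT"
    electrodes_true: ElectrodeSet  # pre-shift ground truth
    tissue: TissueProbabilityVolumes
    atlas: AtlasLabels
    hemispheres: HemisphereMasks
    spec: PhantomSpec


def _strip_anchor(spec: PhantomSpec, rng, side: str, y: float, jitter: float, n: int, spacing: float):
    """Anchor a strip along x on one hemisphere at crest height."""
    span = (n - 1) * spacing
    cx = spec.midline_x
    if side == "left":
        lo, hi = 4.0, cx - spec.interhemispheric_gap_mm / 2 - 2.0 - span
    else:
        lo, hi = cx + spec.interhemispheric_gap_mm / 2 + 2.0, spec.extent_mm[0] - 4.0 - span
    x0 = rng.uniform(max(lo, lo), max(lo, hi))
    y0 = np.clip(y + rng.uniform(-jitter, jitter), 4.0, spec.extent_mm[1] - 4.0)
    return np.array([x0, y0, spec.envelope_z])


def _surface_layout(cfg: CohortConfig, rng, patient_id: str, with_grid: bool) -> ElectrodeSet:
    spec = cfg.phantom
    leads: list[ElectrodeSet] = []
    ys = np.linspace(25.0, 95.0, cfg.n_strips)
    n_str = cfg.n_strips - (2 if with_grid else 0)
    for i in range(max(1, n_str)):
        side = "left" if i % 2 == 0 else "right"
        anchor = _strip_anchor(
            spec, rng, side, ys[i % len(ys)], cfg.layout_jitter_mm, cfg.strip_len,
            cfg.subdural_spacing_mm,
        )
        leads.append(
            generate_strip(
                cfg.strip_len, cfg.subdural_spacing_mm, anchor, (1, 0, 0),
                lead_id=f"strip{i + 1}", patient_id=patient_id,
            )
        )
    if with_grid:
        rows, cols = cfg.grid_shape
        side = "right" if rng.uniform() < 0.5 else "left"
        anchor = _strip_anchor(
            spec, rng, side, 40.0, cfg.layout_jitter_mm, cols, cfg.subdural_spacing_mm
        )
        leads.append(
            generate_grid(
                rows, cols, cfg.subdural_spacing_mm, anchor,
                row_dir=(0, 1, 0), col_dir=(1, 0, 0),
                lead_id="grid1", patient_id=patient_id,
            )
        )
    if cfg.include_interhemispheric:
        # a short strip in the fissure, on one bank of the midline
        bank = -0.3 if rng.uniform() < 0.5 else 0.3
        anchor = np.array(
            [spec.midline_x + bank, 40.0 + rng.uniform(-cfg.layout_jitter_mm, cfg.layout_jitter_mm),
             spec.gm_top_mean_z - 2.0]
        )
        leads.append(
            generate_strip(
                4, cfg.subdural_spacing_mm, anchor, (0, 1, 0),
                lead_id="ih_strip", patient_id=patient_id, interhemispheric=True,
            )
        )
    out = leads[0]
    for l in leads[1:]:
        out = out.merged_with(l)
    return out


def _depth_targets(spec: PhantomSpec, side: str) -> list[tuple[str, np.ndarray]]:
    """Clinically motivated depth targets: mesial structures plus white matter."""
    targets = []
    for name, _cls, lateral, ybox, zbox in _DEEP_BOXES:
        if name == "subcortical":
            continue  # excluded region; clinical leads avoid it
        (x0, x1) = _deep_box_world(spec, lateral, side)
        targets.append(
            (name, np.array([(x0 + x1) / 2, (ybox[0] + ybox[1]) / 2, (zbox[0] + zbox[1]) / 2]))
        )
    cx = spec.midline_x
    lat = -1.0 if side == "left" else 1.0
    # white-matter trajectories fan away from the mesial pair, as clinical
    # SEEG implants spread leads across the hemisphere
    targets.append(("temporal_wm", np.array([cx + lat * 32.0, 22.0, 45.0])))
    targets.append(("frontal_wm", np.array([cx + lat * 22.0, 88.0, 45.0])))
    return targets


def _depth_layout(
    cfg: CohortConfig, rng, patient_id: str, n_leads: int, id_offset: int = 0
) -> ElectrodeSet:
    spec = cfg.phantom
    leads = []
    sides = ["left", "right"]
    per_side = [_depth_targets(spec, s) for s in sides]
    for i in range(n_leads):
        side = sides[i % 2]
        name, target = per_side[i % 2][(i // 2) % len(per_side[i % 2])]
        jit = rng.uniform(-cfg.layout_jitter_mm, cfg.layout_jitter_mm, size=3)
        jit[2] = 0.0
        target = target + jit
        # oblique entry on the envelope, offset laterally so the lead crosses
        # the folded ribbon rather than dropping through a single point
        entry = np.array(
            [target[0] + rng.uniform(4.0, 10.0), target[1] + rng.uniform(-3.0, 3.0),
             spec.envelope_z]
        )
        leads.append(
            generate_depth(
                cfg.depth_len, cfg.depth_spacing_mm, entry, target,
                lead_id=f"depth{id_offset + i + 1}", patient_id=patient_id,
            )
        )
    out = leads[0]
    for l in leads[1:]:
        out = out.merged_with(l)
    return out


def generate_patient(
    cfg: CohortConfig, implant_class: str, patient_id: str, rng: np.random.Generator,
    phantom: tuple | None = None,
) -> SyntheticPatient:
    if phantom is None:
        phantom = generate_phantom(cfg.phantom)
    tissue, atlas, hemis = phantom
    if implant_class == "S":
        es = _surface_layout(cfg, rng, patient_id, with_grid=False)
    elif implant_class == "S+G":
        es = _surface_layout(cfg, rng, patient_id, with_grid=True)
    elif implant_class == "S+G+D":
        es = _surface_layout(cfg, rng, patient_id, with_grid=True).merged_with(
            _depth_layout(cfg, rng, patient_id, 2)
        )
    elif implant_class == "D":
        es = _depth_layout(cfg, rng, patient_id, cfg.n_depth_leads)
    else:
        raise ValueError(f"unknown implant class {implant_class!r}")
    es = ElectrodeSet(es.contacts, patient_id, implant_class)
    shifted = apply_brain_shift(es, cfg.brain_shift_mm)
    return SyntheticPatient(
        patient_id, implant_class, shifted, es, tissue, atlas, hemis, cfg.phantom
    )


def generate_cohort(cfg: CohortConfig, seed: int | None = None) -> list[SyntheticPatient]:
    """Generate a reproducible synthetic cohort; one shared phantom geometry,
    per-patient electrode layouts drawn with the configured jitter."""
    if any(n < 0 for n in cfg.n_per_class.values()):
        raise ValueError("patient counts must be >= 0")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    phantom = generate_phantom(cfg.phantom)
    patients = []
    idx = 1
    for cls in ("S", "S+G", "S+G+D", "D"):
        for _ in range(cfg.n_per_class.get(cls, 0)):
            patients.append(
                generate_patient(cfg, cls, f"synth{idx:03d}", rng, phantom)
            )
            idx += 1
    return patients
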