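"""Smoothed gray-matter surface, hemisphere splitting, brain-shift projection.

Subdural contacts localized from a postoperative CT sit *inside* the
preoperative brain because the cortex sags intraoperatively (brain shift,
often > 1 cm). The standard correction projects each subdural contact back
onto a smoothed gray-matter surface: the binary gray-matter mask is
morphologically closed with a large spherical kernel (default 24 mm
diameter) so that sulci and small holes are bridged, iso-surfaced, and
contacts are moved to the exactly-closest surface point. Depth contacts are
never moved.
"""

from __future__ import annotations

import logging

import numpy as np
import trimesh
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from .electrodes import Contact, ElectrodeSet
from .grid import VolumeGrid
from .volumes import HemisphereMasks

log = logging.getLogger(__name__)


class EmptySurfaceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Surface extraction
# ---------------------------------------------------------------------------


def _ball_element(radius_mm: float, voxel_size: np.ndarray) -> np.ndarray:
    """Ellipsoidal structuring element equivalent to a sphere of the given
    radius in world mm on a (possibly anisotropic) voxel grid."""
    r_vox = np.maximum(radius_mm / voxel_size, 0.0)
    half = np.ceil(r_vox).astype(int)
    if np.all(half == 0):
        return np.ones((1, 1, 1), dtype=bool)
    grids = np.meshgrid(
        *[np.arange(-h, h + 1) for h in half], indexing="ij"
    )
    d2 = sum((g / max(r, 1e-12)) ** 2 for g, r in zip(grids, r_vox))
    return d2 <= 1.0 + 1e-9


def close_mask(mask: np.ndarray, kernel_mm: float, voxel_size: np.ndarray) -> np.ndarray:
    """Morphological closing with a spherical element of *diameter* kernel_mm.

    The volume is padded before closing so structures touching the array
    border behave as in an unbounded field of view.
    """
    if kernel_mm <= 0:
        return mask.copy()
    elem = _ball_element(kernel_mm / 2.0, np.asarray(voxel_size, dtype=float))
    pad = [(s // 2 + 1,) * 2 for s in elem.shape]
    padded = np.pad(mask, pad, mode="constant")
    closed = ndimage.binary_closing(padded, structure=elem)
    sl = tuple(slice(p[0], p[0] + s) for p, s in zip(pad, mask.shape))
    return closed[sl]


def extract_smooth_surface(
    p_gm: np.ndarray,
    grid: VolumeGrid,
    threshold: float = 0.5,
    closing_kernel_mm: float = 24.0,
) -> trimesh.Trimesh:
    """Iso-surface of the morphologically closed gray-matter mask.

    Returns a watertight triangle mesh in world mm. ``closing_kernel_mm`` is
    the diameter of the spherical closing element; 0 skips closing and
    iso-surfaces the raw thresholded mask.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if closing_kernel_mm < 0:
        raise ValueError("closing kernel must be >= 0")
    mask = np.asarray(p_gm) > threshold
    if not mask.any():
        raise EmptySurfaceError("no gray matter above threshold")
    mask = close_mask(mask, closing_kernel_mm, grid.voxel_size)
    mask = ndimage.binary_fill_holes(mask)
    # pad so marching cubes closes the surface at the array border
    padded = np.pad(mask, 1).astype(float)
    verts, faces, _, _ = marching_cubes(padded, level=0.5)
    verts -= 1.0  # undo padding offset, back to voxel-index coordinates
    verts_world = grid.voxel_to_world(verts)
    mesh = trimesh.Trimesh(vertices=verts_world, faces=faces, process=True)
    mesh.update_faces(mesh.nondegenerate_faces())
    if mesh.volume < 0:  # orient outward so enclosed volume is positive
        mesh.invert()
    return mesh


# ---------------------------------------------------------------------------
# Hemisphere masks
# ---------------------------------------------------------------------------


def split_hemispheres(
    p_gm: np.ndarray,
    grid: VolumeGrid,
    midline_x: float,
    threshold: float = 0.5,
    smoothing_kernel_mm: float = 0.1,
) -> HemisphereMasks:
    """Split thresholded gray matter at the sagittal plane ``x = midline_x``,
    hole-fill each side, and optionally mean-filter with a Gaussian kernel.

    The default 0.1 mm kernel is far below any practical voxel size and is
    therefore effectively the identity; it is kept configurable for parity
    with pipelines that smooth more aggressively.
    """
    xs = grid.axis_coords()[0]
    if not (xs.min() <= midline_x <= xs.max()):
        raise ValueError("midline plane does not intersect the volume")
    gm = np.asarray(p_gm) > threshold
    side_left = (xs <= midline_x)[:, None, None]
    masks = {}
    for name, side in (("left", side_left), ("right", ~side_left)):
        m = gm & np.broadcast_to(side, gm.shape)
        m = ndimage.binary_fill_holes(m)
        if smoothing_kernel_mm > 0:
            sigma = smoothing_kernel_mm / grid.voxel_size
            m = ndimage.gaussian_filter(m.astype(float), sigma) > 0.5
        # smoothing must not drop genuine GM voxels nor cross the midline
        m = (m | (gm & np.broadcast_to(side, gm.shape))) & np.broadcast_to(
            side, gm.shape
        )
        masks[name] = m
    return HemisphereMasks(grid, masks["left"], masks["right"])


def contact_hemisphere(
    contact: Contact, midline_x: float, tie_break: str = "left"
) -> str:
    """Which hemisphere a contact records from, by the sign of x - midline."""
    dx = contact.position[0] - midline_x
    if dx < 0:
        return "left"
    if dx > 0:
        return "right"
    log.warning(
        "contact %s lies exactly on the midline plane; assigning %s",
        contact.id,
        tie_break,
    )
    return tie_break


def restrict_hemisphere(
    roi_mask: np.ndarray,
    contact: Contact,
    hemispheres: HemisphereMasks,
    midline_x: float,
    tie_break: str = "left",
) -> np.ndarray:
    """Restrict an RoI mask of an interhemispheric contact to its own
    hemisphere so it cannot claim gray matter across the fissure. No-op for
    ordinary contacts."""
    if not contact.interhemispheric:
        return roi_mask
    side = contact_hemisphere(contact, midline_x, tie_break)
    return roi_mask & hemispheres.mask_for(side)


# ---------------------------------------------------------------------------
# Closest point on mesh (exact, kd-tree accelerated; no spatial index deps)
# ---------------------------------------------------------------------------


def _closest_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point to ``p`` on each triangle (Ericson's region method)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac = b - a, c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    out = np.empty_like(a)
    done = np.zeros(len(tri), dtype=bool)

    def put(mask, pts):
        m = mask & ~done
        out[m] = pts[m] if pts.ndim == 2 else pts
        done[m] = True

    put((d1 <= 0) & (d2 <= 0), a)
    put((d3 >= 0) & (d4 <= d3), b)
    put((d6 >= 0) & (d5 <= d6), c)
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        put((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)
        v_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        put((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + v_ac[:, None] * ac)
        den_bc = (d4 - d3) + (d5 - d6)
        v_bc = np.where(den_bc != 0, (d4 - d3) / den_bc, 0.0)
        put(
            (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
            b + v_bc[:, None] * (c - b),
        )
        denom = va + vb + vc
        denom = np.where(denom != 0, denom, 1.0)
        v = vb / denom
        w = vc / denom
        put(np.ones(len(tri), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)
    return out


class MeshProximity:
    """Exact closest-point queries against a triangle mesh.

    Candidate triangles come from a kd-tree over centroids; the candidate
    set is then widened by the largest triangle circumradius so the result
    is exact, not approximate.
    """

    def __init__(self, mesh: trimesh.Trimesh):
        self.mesh = mesh
        self.triangles = mesh.triangles.view(np.ndarray)
        self.centroids = self.triangles.mean(axis=1)
        self.tree = cKDTree(self.centroids)
        rel = self.triangles - self.centroids[:, None, :]
        self.max_reach = float(np.linalg.norm(rel, axis=2).max())

    def closest_point(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        closest = np.empty_like(points)
        dists = np.empty(len(points))
        k = min(32, len(self.centroids))
        d0, idx0 = self.tree.query(points, k=k)
        d0 = np.atleast_2d(d0)
        idx0 = np.atleast_2d(idx0)
        for i, p in enumerate(points):
            cand = idx0[i]
            pts = _closest_on_triangles(p, self.triangles[cand])
            d = np.linalg.norm(pts - p, axis=1)
            best = d.argmin()
            best_d, best_p = d[best], pts[best]
            # widen: any triangle whose centroid is within best_d + reach
            # could still beat the current best
            extra = self.tree.query_ball_point(p, best_d + self.max_reach)
            extra = np.setdiff1d(np.asarray(extra, dtype=int), cand)
            if len(extra):
                pts = _closest_on_triangles(p, self.triangles[extra])
                d = np.linalg.norm(pts - p, axis=1)
                j = d.argmin()
                if d[j] < best_d:
                    best_d, best_p = d[j], pts[j]
            closest[i] = best_p
            dists[i] = best_d
        return closest, dists


def distance_to_surface(mesh: trimesh.Trimesh, points: np.ndarray) -> np.ndarray:
    """Unsigned distance from each point to the mesh surface (mm)."""
    return MeshProximity(mesh).closest_point(points)[1]


# ---------------------------------------------------------------------------
# Contact projection
# ---------------------------------------------------------------------------


def project_surface_contacts(
    electrodes: ElectrodeSet,
    surface: trimesh.Trimesh,
    max_distance_mm: float = 25.0,
    return_flagged: bool = False,
):
    """Project strip/grid contacts onto the smoothed gray-matter surface.

    Each strip/grid contact is moved to the exactly-closest surface point,
    which for a displacement along the local surface normal (the dominant
    brain-shift mode) coincides with the foot of the perpendicular. Contacts
    farther than ``max_distance_mm`` from the surface are flagged and left
    in place. Depth contacts are never moved; the operation is idempotent.
    """
    surf_contacts = electrodes.surface_contacts()
    if not surf_contacts:
        raise ValueError("electrode set has no strip/grid contacts to project")
    prox = MeshProximity(surface)
    positions = np.array([c.position for c in surf_contacts])
    nearest, dists = prox.closest_point(positions)

    new_positions = {}
    flagged: list[str] = []
    for i, c in enumerate(surf_contacts):
        if dists[i] > max_distance_mm:
            flagged.append(c.id)
            continue
        new_positions[c.id] = nearest[i]
    if flagged:
        log.warning(
            "%d contact(s) farther than %.1f mm from the surface were flagged "
            "and not projected: %s",
            len(flagged),
            max_distance_mm,
            flagged,
        )
    moved = [
        c.moved_to(new_positions[c.id]) if c.id in new_positions else c
        for c in electrodes.contacts
    ]
    out = ElectrodeSet(moved, electrodes.patient_id, electrodes.implant_class)
    if return_flagged:
        return out, flagged
    return out
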