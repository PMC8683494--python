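"""Finite-element recording volumes and their comparison to spherical RoIs.

The quasi-static potential of a current-injecting contact obeys
``div(sigma grad V) = 0`` with piecewise-constant tissue conductivity
(CSF 1.79, gray 0.33, white 0.142 S/m). The solver is linear (P1)
tetrahedral FEM: the phantom is voxelized onto a node lattice at the target
edge length, each cell is split into six Kuhn tetrahedra (conforming without
parity bookkeeping), and each element takes the conductivity of the majority
tissue at its centroid. Current (default 1 mA) enters through the mesh nodes
inside the contact's physical footprint (disc or cylinder) and returns
through a grounded patch — the top 5% of the outer boundary by facet area —
mimicking skull screws at the vertex.

An FEM-based recording volume for nominal radius r is the region where
|V| exceeds the mean |V| sampled on the r-sphere around the contact; in a
homogeneous medium this is nearly the sphere itself, and the Dice overlap
between the two quantifies how much tissue heterogeneity (chiefly highly
conductive CSF) distorts the recording volume.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import RegularGridInterpolator

from .coverage import sphere_mask, weighted_volume
from .electrodes import Contact, ElectrodeSet
from .grid import VolumeGrid
from .volumes import AtlasLabels, TissueProbabilityVolumes

log = logging.getLogger(__name__)

TISSUES = ("csf", "gm", "wm")


@dataclass(frozen=True)
class ConductivityTable:
    """Tissue conductivities in S/m."""

    csf: float = 1.79
    gm: float = 0.33
    wm: float = 0.142

    def __post_init__(self) -> None:
        if min(self.csf, self.gm, self.wm) <= 0:
            raise ValueError("conductivities must be positive")

    def of(self, tissue_index: np.ndarray) -> np.ndarray:
        return np.array([self.csf, self.gm, self.wm])[tissue_index]


@dataclass(frozen=True)
class FemSourceConfig:
    current_a: float = 1e-3  # 1 mA injected
    ground_fraction: float = 0.05  # top share of outer boundary area grounded
    contact_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.current_a == 0:
            raise ValueError("source current must be nonzero")
        if not 0 < self.ground_fraction < 1:
            raise ValueError("ground fraction must be in (0, 1)")


class MeshingError(RuntimeError):
    pass


@dataclass
class TetMesh:
    """Linear tetrahedral mesh with per-element tissue indices.

    Nodes form a structured lattice (``node_shape`` / ``node_coords``), which
    the potential interpolation exploits.
    """

    nodes: np.ndarray  # (N, 3) mm
    tets: np.ndarray  # (M, 4) node indices
    tissue: np.ndarray  # (M,) index into TISSUES
    node_shape: tuple[int, int, int]
    node_coords: tuple[np.ndarray, np.ndarray, np.ndarray]

    def __post_init__(self) -> None:
        if self.element_volumes().min() <= 0:
            raise MeshingError("mesh contains inverted or degenerate elements")

    def element_volumes(self) -> np.ndarray:
        p = self.nodes[self.tets]
        a = p[:, 1] - p[:, 0]
        b = p[:, 2] - p[:, 0]
        c = p[:, 3] - p[:, 0]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    def tissue_volume(self, tissue: str) -> float:
        return float(self.element_volumes()[self.tissue == TISSUES.index(tissue)].sum())

    @property
    def total_volume(self) -> float:
        return float(self.element_volumes().sum())

    def boundary_faces(self) -> np.ndarray:
        """Triangular facets belonging to exactly one tetrahedron."""
        faces = self.tets[:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]].reshape(-1, 3)
        key = np.sort(faces, axis=1)
        _, inv, counts = np.unique(
            key, axis=0, return_inverse=True, return_counts=True
        )
        return faces[counts[inv] == 1]

    def save_vtk(self, path, point_data: dict | None = None) -> None:
        """Write the mesh (legacy ASCII VTK unstructured grid)."""
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\ntet mesh\nASCII\n")
            fh.write("DATASET UNSTRUCTURED_GRID\n")
            fh.write(f"POINTS {len(self.nodes)} float\n")
            np.savetxt(fh, self.nodes, fmt="%.6f")
            m = len(self.tets)
            fh.write(f"CELLS {m} {5 * m}\n")
            np.savetxt(
                fh, np.column_stack([np.full(m, 4), self.tets]), fmt="%d"
            )
            fh.write(f"CELL_TYPES {m}\n")
            np.savetxt(fh, np.full(m, 10), fmt="%d")
            fh.write(f"CELL_DATA {m}\nSCALARS tissue int 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, self.tissue, fmt="%d")
            if point_data:
                fh.write(f"POINT_DATA {len(self.nodes)}\n")
                for name, vals in point_data.items():
                    fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                    np.savetxt(fh, np.asarray(vals), fmt="%.8e")


# Kuhn decomposition of the unit cube into six conforming tetrahedra.
_KUHN_TETS = np.array(
    [
        [(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)],
        [(0, 0, 0), (1, 1, 0), (0, 1, 0), (1, 1, 1)],
        [(0, 0, 0), (0, 1, 0), (0, 1, 1), (1, 1, 1)],
        [(0, 0, 0), (0, 1, 1), (0, 0, 1), (1, 1, 1)],
        [(0, 0, 0), (0, 0, 1), (1, 0, 1), (1, 1, 1)],
        [(0, 0, 0), (1, 0, 1), (1, 0, 0), (1, 1, 1)],
    ]
)


def build_tet_mesh(
    tissue: TissueProbabilityVolumes,
    edge_length_mm: float = 1.5,
    bbox: tuple[np.ndarray, np.ndarray] | None = None,
) -> TetMesh:
    """Mesh the phantom (or a sub-box of it) at the target edge length.

    Element tissue = majority (argmax) probability at the element centroid,
    looked up at the nearest phantom voxel.
    """
    if edge_length_mm <= 0:
        raise ValueError("edge length must be positive")
    grid = tissue.grid
    xs, ys, zs = grid.axis_coords()
    if bbox is None:
        lo = np.array([xs[0], ys[0], zs[0]])
        hi = np.array([xs[-1], ys[-1], zs[-1]])
    else:
        lo, hi = np.asarray(bbox[0], dtype=float), np.asarray(bbox[1], dtype=float)
    n_cells = np.maximum(np.round((hi - lo) / edge_length_mm).astype(int), 1)
    coords = [np.linspace(lo[a], hi[a], n_cells[a] + 1) for a in range(3)]
    shape = tuple(len(c) for c in coords)
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * shape[1] + j) * shape[2] + k

    ii, jj, kk = np.meshgrid(
        np.arange(n_cells[0]), np.arange(n_cells[1]), np.arange(n_cells[2]),
        indexing="ij",
    )
    ii, jj, kk = ii.ravel(), jj.ravel(), kk.ravel()
    tets = np.empty((len(ii) * 6, 4), dtype=np.int64)
    for t, corners in enumerate(_KUHN_TETS):
        cols = [nid(ii + di, jj + dj, kk + dk) for (di, dj, dk) in corners]
        tets[t::6] = np.column_stack(cols)

    # orient all elements positively
    p = nodes[tets]
    vol6 = np.einsum(
        "ij,ij->i",
        p[:, 1] - p[:, 0],
        np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]),
    )
    flip = vol6 < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]

    centroids = nodes[tets].mean(axis=1)
    vox = np.round(grid.world_to_voxel(centroids)).astype(int)
    vox = np.clip(vox, 0, np.asarray(grid.shape) - 1)
    probs = np.stack(
        [
            tissue.p_csf[vox[:, 0], vox[:, 1], vox[:, 2]],
            tissue.p_gm[vox[:, 0], vox[:, 1], vox[:, 2]],
            tissue.p_wm[vox[:, 0], vox[:, 1], vox[:, 2]],
        ],
        axis=1,
    )
    labels = probs.argmax(axis=1).astype(np.int8)
    return TetMesh(nodes, tets, labels, shape, tuple(np.asarray(c) for c in coords))


# ---------------------------------------------------------------------------
# Assembly and solve
# ---------------------------------------------------------------------------


def assemble_stiffness(mesh: TetMesh, conductivities: ConductivityTable) -> sp.csr_matrix:
    """Global P1 stiffness matrix for div(sigma grad V)."""
    n = len(mesh.nodes)
    K = sp.csr_matrix((n, n))
    # node coordinates are mm; convert S/m -> S/mm so potentials are volts
    sigma = conductivities.of(mesh.tissue) * 1e-3
    chunk = 400_000
    for start in range(0, len(mesh.tets), chunk):
        tets = mesh.tets[start : start + chunk]
        sig = sigma[start : start + chunk]
        p = mesh.nodes[tets]
        A = p[:, 1:] - p[:, 0:1]  # (m, 3, 3) edge rows
        vol = np.abs(np.linalg.det(A)) / 6.0
        Ainv = np.linalg.inv(A)
        # grad of barycentric 1..3 are the columns of A^-1
        g = np.empty((len(tets), 4, 3))
        g[:, 1:] = np.transpose(Ainv, (0, 2, 1))
        g[:, 0] = -g[:, 1:].sum(axis=1)
        Ke = np.einsum("mid,mjd->mij", g, g) * (sig * vol)[:, None, None]
        rows = np.repeat(tets, 4, axis=1).reshape(-1)
        cols = np.tile(tets, (1, 4)).reshape(-1)
        K = K + sp.coo_matrix(
            (Ke.reshape(-1), (rows, cols)), shape=(n, n)
        ).tocsr()
    return K


def _source_nodes(mesh: TetMesh, contact: Contact, axis: np.ndarray) -> np.ndarray:
    """Mesh nodes inside the contact's physical footprint, dilated by half an
    edge length so coarse meshes still catch at least a node ring."""
    geom = contact.geometry
    rel = mesh.nodes - contact.position
    h = float(min(np.diff(c).min() for c in mesh.node_coords))
    pad = h / 2.0
    ax = axis / np.linalg.norm(axis)
    along = rel @ ax
    radial = np.linalg.norm(rel - np.outer(along, ax), axis=1)
    if geom.kind == "cylinder":
        sel = (radial <= geom.diameter_mm / 2 + pad) & (
            np.abs(along) <= geom.height_mm / 2 + pad
        )
    else:  # disc
        sel = (radial <= geom.diameter_mm / 2 + pad) & (np.abs(along) <= pad)
    idx = np.nonzero(sel)[0]
    if len(idx) == 0:
        idx = np.array([np.linalg.norm(rel, axis=1).argmin()])
    return idx


def ground_nodes(mesh: TetMesh, fraction: float) -> np.ndarray:
    """Nodes of the grounded patch: outer-boundary facets with the highest
    superior (z) centroid, accumulated to the given share of boundary area."""
    faces = mesh.boundary_faces()
    pts = mesh.nodes[faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(pts[:, 1] - pts[:, 0], pts[:, 2] - pts[:, 0]), axis=1
    )
    cz = pts[:, :, 2].mean(axis=1)
    order = np.argsort(-cz)
    cum = np.cumsum(areas[order])
    n_take = int(np.searchsorted(cum, fraction * areas.sum())) + 1
    return np.unique(faces[order[:n_take]])


@dataclass
class PotentialField:
    mesh: TetMesh
    voltages: np.ndarray  # (N,) volts
    source_contact_id: str
    source_node_ids: np.ndarray
    ground_node_ids: np.ndarray
    stiffness: sp.csr_matrix
    load: np.ndarray

    def ground_flux(self) -> float:
        """Current (A) through the grounded patch (reaction sum); equals
        minus the injected current when the solve has converged."""
        r = self.stiffness @ self.voltages - self.load
        return float(r[self.ground_node_ids].sum())

    def interpolator(self, magnitude: bool = True) -> RegularGridInterpolator:
        vals = np.abs(self.voltages) if magnitude else self.voltages
        return RegularGridInterpolator(
            self.mesh.node_coords,
            vals.reshape(self.mesh.node_shape),
            bounds_error=False,
            fill_value=0.0,
        )


def solve_potential(
    mesh: TetMesh,
    conductivities: ConductivityTable,
    source: FemSourceConfig,
    contact: Contact,
    rtol: float = 1e-9,
    boundary_potential=None,
) -> PotentialField:
    """Solve the quasi-static potential for one current-injecting contact.

    Neumann current injection over the contact footprint (total current
    split across its nodes), V = 0 Dirichlet on the grounded patch (top
    share of the outer boundary), natural (insulating) conditions elsewhere.

    ``boundary_potential`` is a verification hook: a callable mapping node
    coordinates (n, 3) to potentials imposed on the *entire* outer boundary
    (e.g. the infinite-medium point-source solution), which removes the
    finite-domain bias when checking the solver against analytic fields.
    """
    K = assemble_stiffness(mesh, conductivities)
    n = len(mesh.nodes)
    src = _source_nodes(mesh, contact, np.asarray(source.contact_axis, dtype=float))
    f = np.zeros(n)
    f[src] = source.current_a / len(src)

    if boundary_potential is None:
        gnd = ground_nodes(mesh, source.ground_fraction)
        v_gnd = np.zeros(len(gnd))
    else:
        gnd = np.unique(mesh.boundary_faces())
        v_gnd = np.asarray(boundary_potential(mesh.nodes[gnd]), dtype=float)
    if len(gnd) == 0:
        raise RuntimeError("ground region is empty; system would be singular")

    free = np.setdiff1d(np.arange(n), gnd)
    Kff = K[free][:, free].tocsr()
    rhs = f[free] - K[free][:, gnd] @ v_gnd
    M = sp.diags(1.0 / Kff.diagonal())
    v_free, info = spla.cg(Kff, rhs, M=M, rtol=rtol, maxiter=20000)
    if info != 0:
        raise RuntimeError(f"CG did not converge (info={info})")
    v = np.zeros(n)
    v[free] = v_free
    v[gnd] = v_gnd
    return PotentialField(mesh, v, contact.id, src, gnd, K, f)


# ---------------------------------------------------------------------------
# FEM-based recording volumes and Dice
# ---------------------------------------------------------------------------


def fibonacci_sphere(n: int) -> np.ndarray:
    """Near-uniform unit-sphere sample directions."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


@dataclass
class FemVolume:
    mask: np.ndarray
    grid: VolumeGrid
    threshold_v: float
    radius_mm: float

    def __post_init__(self) -> None:
        if self.threshold_v <= 0:
            raise ValueError("threshold voltage must be positive")


def fem_volume(
    field: PotentialField,
    center: np.ndarray,
    r_mm: float,
    sampling_grid: VolumeGrid,
    n_samples: int = 500,
    magnitude: bool = True,
) -> FemVolume:
    """Iso-|V| recording volume for nominal radius r: threshold at the mean
    |V| over the r-sphere around the contact, then keep voxels at or above
    the threshold."""
    if r_mm <= 0:
        raise ValueError("radius must be positive")
    center = np.asarray(center, dtype=float)
    interp = field.interpolator(magnitude=magnitude)
    pts = center + r_mm * fibonacci_sphere(n_samples)
    lo = np.array([c[0] for c in field.mesh.node_coords])
    hi = np.array([c[-1] for c in field.mesh.node_coords])
    inside = np.all((pts >= lo) & (pts <= hi), axis=1)
    if inside.sum() < 0.8 * n_samples:
        warnings.warn(
            f"{n_samples - int(inside.sum())}/{n_samples} sphere samples fall "
            "outside the mesh and were dropped"
        )
    if not inside.any():
        raise RuntimeError("sampling sphere lies entirely outside the mesh")
    threshold = float(np.abs(interp(pts[inside])).mean())
    xs, ys, zs = sampling_grid.axis_coords()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    vals = interp(np.column_stack([X.ravel(), Y.ravel(), Z.ravel()]))
    mask = np.abs(vals).reshape(sampling_grid.shape) >= threshold
    return FemVolume(mask, sampling_grid, threshold, r_mm)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A&B| / (|A|+|B|) of two masks on one grid."""
    if a.shape != b.shape:
        raise ValueError("masks live on different grids")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("Dice undefined: both masks empty")
    return 2.0 * int((a & b).sum()) / (na + nb)


def fem_coverage_compare(
    electrodes: ElectrodeSet,
    tissue: TissueProbabilityVolumes,
    fields: dict[str, PotentialField],
    radii_mm: tuple = (2.5, 5.0, 10.0, 15.0),
    atlas: AtlasLabels | None = None,
    sampling_grid: VolumeGrid | None = None,
) -> pd.DataFrame:
    """Paired spherical vs FEM gray-matter coverage and Dice per contact."""
    grid = sampling_grid or tissue.grid
    excl = atlas.exclusion_mask() if atlas is not None else None
    rows = []
    for c in electrodes:
        if c.id not in fields:
            raise KeyError(f"no potential field solved for contact {c.id}")
        fld = fields[c.id]
        for r in radii_mm:
            smask = sphere_mask(c.position, r, grid)
            fvol = fem_volume(fld, c.position, r, grid)
            rows.append(
                {
                    "patient_id": electrodes.patient_id,
                    "implant_class": electrodes.implant_class,
                    "contact_id": c.id,
                    "modality": c.modality,
                    "radius_mm": r,
                    "gm_sphere_mm3": weighted_volume(smask, tissue.p_gm, grid, excl),
                    "gm_fem_mm3": weighted_volume(fvol.mask, tissue.p_gm, grid, excl),
                    "dice": dice(smask, fvol.mask),
                }
            )
    return pd.DataFrame(rows)
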