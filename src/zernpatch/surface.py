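"""Voxelized molecular surface and physicochemical feature fields.

The molecular volume is rasterized on a cubic grid (default 0.6 Å
spacing).  The solvent-excluded volume is found operationally with a
probe-rolling approximation: voxels farther than (atom radius + probe)
from every atom are probe-accessible; the accessible region connected to
the box boundary is flood-filled and dilated back by the probe radius to
give the solvent; everything else — atom interiors, reentrant volume and
probe-inaccessible cavities — is protein.  Surface points are protein
voxels with at least one solvent voxel among their 26 neighbors.

Four scalar fields are evaluated on surface points:

* electrostatic potential — screened Coulomb with a distance-dependent
  dielectric ε(r) = 4r (or trilinear interpolation of an external OpenDX
  grid, e.g. a Poisson–Boltzmann map),
* molecular hydrophobic field — the distance-weighted average of atomic
  logP contributions, MHP_i = Σ_j f_j w_ij / Σ_j w_ij with
  w_ij = 1/(1 + exp(r_ij − 4)),
* hydrogen-bond character — +1 / −1 / 0 by the class of the nearest heavy
  atom (donor / acceptor / otherwise; ambivalent "dual" atoms map to 0),
* visibility — the fraction of 512 rays from the point that escape
  without passing within 0.3 Å of another surface point; 1 for fully
  exposed, 0 for fully buried.  A local-curvature proxy.

The interaction interface is the subset of surface points strictly closer
than 5 Å to any heavy atom of the binding partner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .structure import ParameterizedStructure

__all__ = [
    "VoxelGrid",
    "FeatureSurface",
    "PPISurface",
    "build_grid",
    "extract_surface",
    "extract_ppi_surface",
    "compute_mhp",
    "assign_hbond",
    "compute_visibility",
    "compute_electrostatics",
    "fibonacci_sphere",
    "surface_to_tsv",
]


@dataclass
class VoxelGrid:
    """Cubic grid with a boolean protein/solvent occupancy."""

    origin: np.ndarray  # (3,) Å, center of voxel [0,0,0]
    spacing: float
    protein: np.ndarray  # bool, shape dims

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.protein.shape

    def voxel_centers(self, index: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(index, dtype=float) * self.spacing

    def index_of(self, points: np.ndarray) -> np.ndarray:
        return np.rint((np.asarray(points) - self.origin) / self.spacing).astype(int)


@dataclass
class FeatureSurface:
    """Surface voxel centers carrying the feature fields.

    Fields are ``None`` until the corresponding compute step runs.
    ``voxel_index`` keeps the integer grid index of each point so that ray
    marching and surface-graph construction stay exact.
    """

    points: np.ndarray  # (N, 3) Å
    voxel_index: np.ndarray  # (N, 3) int
    grid: VoxelGrid
    owner_chain_set: frozenset[str] = frozenset()
    electrostatic: np.ndarray | None = None
    mhp: np.ndarray | None = None
    hbond: np.ndarray | None = None
    visibility: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class PPISurface:
    """Interface subset of a :class:`FeatureSurface`."""

    parent: FeatureSurface
    indices: np.ndarray  # indices into parent.points
    partner_chain_set: frozenset[str] = frozenset()

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def points(self) -> np.ndarray:
        return self.parent.points[self.indices]

    @property
    def voxel_index(self) -> np.ndarray:
        return self.parent.voxel_index[self.indices]

    def feature(self, name: str) -> np.ndarray:
        arr = getattr(self.parent, name)
        if arr is None:
            raise ValueError(f"feature field {name!r} has not been computed")
        return arr[self.indices]


def build_grid(
    structure: ParameterizedStructure,
    spacing: float = 0.6,
    probe: float = 1.4,
) -> VoxelGrid:
    """Rasterize the solvent-excluded volume of the heavy atoms.

    The box covers all atoms with padding ≥ probe + max radius so the grid
    boundary is guaranteed solvent.
    """
    heavy = structure.heavy_view()
    if len(heavy) == 0:
        raise ValueError("structure has no heavy atoms")
    coords = heavy.coords
    radii = heavy.radius
    if radii.size == 0:
        raise ValueError("assign_parameters must run before build_grid")
    pad = probe + float(radii.max()) + 2 * spacing
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    # snap the origin to the global lattice of multiples of the spacing so
    # that voxelization commutes exactly with axis-aligned 90° rotations
    origin = np.floor(lo / spacing) * spacing
    dims = np.ceil((hi - origin) / spacing).astype(int) + 1

    # probe-excluded region: union of spheres radius (r_atom + probe),
    # stamped atom by atom (stamp cubes are tiny relative to the grid)
    excluded = np.zeros(tuple(dims), dtype=bool)
    inside_atom = np.zeros(tuple(dims), dtype=bool)
    for pos, r in zip(coords, radii):
        for target, rad in ((excluded, r + probe), (inside_atom, r)):
            n = int(np.floor(rad / spacing))
            center_idx = (pos - origin) / spacing
            c = np.rint(center_idx).astype(int)
            sl = tuple(
                slice(max(c[k] - n - 1, 0), min(c[k] + n + 2, dims[k])) for k in range(3)
            )
            ax = [np.arange(sl[k].start, sl[k].stop) * spacing + origin[k] - pos[k]
                  for k in range(3)]
            d2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
                  + ax[2][None, None, :] ** 2)
            target[sl] |= d2 <= rad * rad

    accessible = ~excluded
    # flood fill the accessible region from the box boundary
    labels, _ = ndimage.label(accessible)
    border_labels = set()
    for axis in range(3):
        face = [slice(None)] * 3
        for edge in (0, -1):
            face[axis] = edge
            border_labels |= set(np.unique(labels[tuple(face)]))
    border_labels.discard(0)
    outside = np.isin(labels, sorted(border_labels))
    # dilate the outside-accessible region back by the probe radius; the
    # extra half spacing compensates the center-to-center distance
    # underestimating the distance to the accessible *region* boundary
    dist_to_outside = ndimage.distance_transform_edt(
        ~outside, sampling=(spacing, spacing, spacing)
    )
    solvent = dist_to_outside <= probe + spacing / 2
    protein = ~solvent
    # atom interiors are protein by construction (an accessible point is
    # > r_atom + probe from every center, so its probe ball misses atoms)
    protein |= inside_atom
    return VoxelGrid(origin=origin, spacing=spacing, protein=protein)


def extract_surface(
    grid: VoxelGrid, owner_chain_set: frozenset[str] | set[str] = frozenset()
) -> FeatureSurface:
    """Surface points: protein voxels with ≥ 1 solvent voxel among 26 neighbors."""
    protein = grid.protein
    if not protein.any():
        raise ValueError("grid contains no protein voxels")
    if protein.all():
        raise ValueError("grid contains no solvent voxels")
    core = ndimage.binary_erosion(
        protein, structure=np.ones((3, 3, 3), dtype=bool), border_value=0
    )
    surface_mask = protein & ~core
    idx = np.argwhere(surface_mask)
    points = grid.origin + idx * grid.spacing
    return FeatureSurface(
        points=points,
        voxel_index=idx,
        grid=grid,
        owner_chain_set=frozenset(owner_chain_set),
    )


def extract_ppi_surface(
    surface: FeatureSurface,
    partner: ParameterizedStructure,
    cutoff: float = 5.0,
) -> PPISurface:
    """Surface points strictly closer than ``cutoff`` to a partner heavy atom."""
    if len(surface) == 0:
        raise ValueError("empty surface")
    partner_xyz = partner.heavy_coords()
    if partner_xyz.size == 0:
        raise ValueError("partner has no heavy atoms")
    tree = cKDTree(partner_xyz)
    d, _ = tree.query(surface.points)
    keep = np.flatnonzero(d < cutoff)
    if keep.size == 0:
        raise ValueError(
            f"no interface: no surface point is closer than {cutoff} Å "
            "to a partner heavy atom"
        )
    partner_chains = frozenset(a.chain_id for a in partner.atoms)
    return PPISurface(parent=surface, indices=keep, partner_chain_set=partner_chains)


def compute_mhp(
    surface: FeatureSurface, structure: ParameterizedStructure
) -> FeatureSurface:
    """Molecular hydrophobic field on every surface point.

    MHP_i = Σ_j f_j w_ij / Σ_j w_ij, w_ij = 1/(1 + exp(r_ij − 4)), the sum
    running over all heavy atoms j with logP contribution f_j.  The field
    is a convex combination of atomic logP values.
    """
    heavy = structure.heavy_view()
    if heavy.atomic_logp.size == 0:
        raise ValueError("atomic logP not assigned; run assign_parameters")
    f = heavy.atomic_logp
    xyz = heavy.coords
    out = np.empty(len(surface))
    chunk = 4096
    for start in range(0, len(surface), chunk):
        pts = surface.points[start : start + chunk]
        r = np.sqrt(((pts[:, None, :] - xyz[None, :, :]) ** 2).sum(-1))
        # w = 1/(1+exp(r-4)) computed in log space to avoid overflow
        w = np.exp(-np.logaddexp(0.0, r - 4.0))
        out[start : start + chunk] = (w * f).sum(1) / w.sum(1)
    surface.mhp = out
    return surface


_HBOND_VALUE = {"donor": 1, "acceptor": -1, "dual": 0, "none": 0}


def assign_hbond(
    surface: FeatureSurface, structure: ParameterizedStructure
) -> FeatureSurface:
    """±1/0 hydrogen-bond character from the nearest heavy atom.

    Donor → +1, acceptor → −1, otherwise 0; atoms with both characters
    (dual) map to 0.  Nearest-atom ties are broken by lowest atom serial.
    """
    heavy = structure.heavy_view()
    if not heavy.hbond_class:
        raise ValueError("hbond classes not assigned; run assign_parameters")
    xyz = heavy.coords
    tree = cKDTree(xyz)
    k = min(4, len(heavy))
    d, j = tree.query(surface.points, k=k)
    d = np.atleast_2d(d.reshape(len(surface), k))
    j = np.atleast_2d(j.reshape(len(surface), k))
    serials = np.array([a.serial for a in heavy.atoms])
    values = np.array([_HBOND_VALUE[c] for c in heavy.hbond_class], dtype=np.int8)
    out = np.empty(len(surface), dtype=np.int8)
    for i in range(len(surface)):
        tied = np.flatnonzero(d[i] <= d[i, 0] + 1e-9)
        pick = j[i, tied[np.argmin(serials[j[i, tied]])]]
        out[i] = values[pick]
    surface.hbond = out
    return surface


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform covering of the unit sphere with n points."""
    if n <= 0:
        raise ValueError("number of ray directions must be positive")
    i = np.arange(n, dtype=float)
    golden = (1 + np.sqrt(5)) / 2
    z = 1 - (2 * i + 1) / n
    r = np.sqrt(np.clip(1 - z * z, 0, None))
    phi = 2 * np.pi * i / golden
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def compute_visibility(
    surface: FeatureSurface,
    n_rays: int = 512,
    ray_length: float = 20.0,
    block_tol: float = 0.3,
    point_indices: np.ndarray | None = None,
) -> FeatureSurface:
    """Ray-cast visibility in [0, 1] (unblocked rays / total rays).

    Rays leave each evaluated point along a fixed Fibonacci-lattice set of
    directions and are sampled at grid-spacing steps out to ``ray_length``.
    A ray is blocked when a sample comes within ``block_tol`` of the
    protein *interior* — protein voxels behind the one-voxel surface
    shell.  The shell itself is transparent: the evaluated point sits at
    a voxel center, half a voxel inside the true molecular boundary, so
    counting the shell as blocking would spuriously occlude grazing rays
    and a flat wall would no longer see half the sky.  Blocking tests run
    against the full protein volume, not only the interface region.
    ``point_indices`` restricts the evaluation (e.g. to interface
    points); unevaluated entries are NaN.
    """
    dirs = fibonacci_sphere(n_rays)
    grid = surface.grid
    spacing = grid.spacing
    steps = np.arange(spacing, ray_length + spacing / 2, spacing)

    surf_mask = np.zeros(grid.dims, dtype=bool)
    surf_mask[tuple(surface.voxel_index.T)] = True
    interior = grid.protein & ~surf_mask

    if point_indices is None:
        point_indices = np.arange(len(surface))
    point_indices = np.asarray(point_indices)
    out = surface.visibility
    if out is None:
        out = np.full(len(surface), np.nan)

    # Pad the interior mask so ray samples can never index out of bounds
    # (padding is solvent): bounds checks disappear from the hot loop.
    w = len(steps) + 1
    padded = np.zeros(np.array(interior.shape) + 2 * w, dtype=bool)
    padded[w:-w, w:-w, w:-w] = interior
    pdims = np.array(padded.shape)
    flat_interior = padded.ravel()

    # Because every surface point is a voxel center, each ray sample's
    # containing voxel depends only on the sample's offset from the
    # origin — precompute the relative voxel offsets once, sorted by ray.
    # A sample within block_tol of a voxel face also probes the adjacent
    # voxel, implementing "within block_tol of the interior region".
    rel = dirs[:, None, :] * steps[None, :, None] / spacing  # (R, S, 3)
    base_iv = np.rint(rel).astype(np.int64)
    frac = rel - base_iv  # in [-0.5, 0.5] per axis
    tol = block_tol / spacing
    ray_of = np.broadcast_to(np.arange(n_rays)[:, None], rel.shape[:2])
    cand_list = [base_iv.reshape(-1, 3)]
    ray_list = [ray_of.ravel()]
    for axis in range(3):
        for sign in (1, -1):
            near = sign * frac[..., axis] > 0.5 - tol
            shifted = base_iv[near].copy()
            shifted[:, axis] += sign
            cand_list.append(shifted)
            ray_list.append(ray_of[near])
    cand_iv = np.concatenate(cand_list)
    ray_id = np.concatenate(ray_list)
    keep = (cand_iv != 0).any(axis=1)
    cand_iv, ray_id = cand_iv[keep], ray_id[keep]
    cand_flat = (cand_iv[:, 0] * pdims[1] + cand_iv[:, 1]) * pdims[2] + cand_iv[:, 2]
    if cand_flat.size == 0:  # ray_length shorter than one step
        surface.visibility = out
        out[point_indices] = 1.0
        return surface
    uniq = np.unique(np.stack([ray_id, cand_flat]), axis=1)
    ray_id, cand_flat = uniq[0], uniq[1]
    _, ray_starts = np.unique(ray_id, return_index=True)

    chunk = max(1, int(8e6 // max(len(cand_flat), 1)))
    for start in range(0, len(point_indices), chunk):
        pis = point_indices[start : start + chunk]
        own = surface.voxel_index[pis] + w  # (P, 3) in padded coordinates
        own_flat = (own[:, 0] * pdims[1] + own[:, 1]) * pdims[2] + own[:, 2]
        hit = flat_interior[own_flat[:, None] + cand_flat[None, :]]
        blocked = np.maximum.reduceat(hit, ray_starts, axis=1)  # (P, n_rays)
        out[pis] = 1.0 - blocked.sum(axis=1) / n_rays
    surface.visibility = out
    return surface


def _read_dx(map_path: str | Path):
    from gridData import Grid  # GridDataFormats

    return Grid(str(map_path))


def compute_electrostatics(
    surface: FeatureSurface,
    structure: ParameterizedStructure | None = None,
    backend: str = "coulomb",
    map_path: str | Path | None = None,
) -> FeatureSurface:
    """Electrostatic potential on surface points.

    ``coulomb``: φ_i = Σ_j q_j / (ε(r_ij) r_ij) with ε(r) = 4r and r
    clamped below at 1 Å — a screened-Coulomb stand-in on a kT/e-like
    scale.  ``dx_map``: trilinear interpolation of an external OpenDX
    scalar grid (e.g. a Poisson–Boltzmann solver's output) at each surface
    point.
    """
    if backend == "coulomb":
        if structure is None:
            raise ValueError("coulomb backend requires a structure")
        heavy = structure.heavy_view()
        if heavy.partial_charge.size == 0:
            raise ValueError("charges not assigned; run assign_parameters")
        q = heavy.partial_charge
        xyz = heavy.coords
        out = np.empty(len(surface))
        chunk = 4096
        for start in range(0, len(surface), chunk):
            pts = surface.points[start : start + chunk]
            r = np.sqrt(((pts[:, None, :] - xyz[None, :, :]) ** 2).sum(-1))
            r = np.maximum(r, 1.0)
            out[start : start + chunk] = (q / (4.0 * r * r)).sum(1)
        surface.electrostatic = out
    elif backend == "dx_map":
        if map_path is None:
            raise ValueError("dx_map backend requires map_path")
        g = _read_dx(map_path)
        lo = g.origin
        hi = g.origin + (np.array(g.grid.shape) - 1) * np.array(g.delta)
        pts = surface.points
        if (pts < lo - 1e-6).any() or (pts > hi + 1e-6).any():
            raise ValueError("OpenDX map box does not cover the surface")
        surface.electrostatic = np.asarray(g.interpolated(*pts.T), dtype=float)
    else:
        raise ValueError(f"unknown electrostatics backend {backend!r}")
    return surface


def surface_to_tsv(surface: FeatureSurface, path: str | Path) -> None:
    """Dump points and fields as TSV: x, y, z, elec, mhp, hbond, visibility."""
    n = len(surface)

    def col(arr):
        return arr if arr is not None else np.full(n, np.nan)

    data = np.column_stack(
        [
            surface.points,
            col(surface.electrostatic),
            col(surface.mhp),
            col(surface.hbond),
            col(surface.visibility),
        ]
    )
    header = "x\ty\tz\telec\tmhp\thbond\tvisibility"
    np.savetxt(path, data, fmt="%.6g", delimiter="\t", header=header, comments="")
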