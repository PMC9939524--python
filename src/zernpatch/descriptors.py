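"""End-to-end computation and serialization of interface patch descriptors.

``compute_interface_descriptors`` runs the full per-complex pipeline:
solvent-excluded voxel surface → feature fields → interface extraction →
seed selection → patch segmentation → per-feature 3D Zernike descriptors
and geodesic patch-position histograms.  The resulting
:class:`PatchDescriptorSet` is the unit of exchange (compute once,
compare many) and round-trips through a versioned JSON file.

Before voxelization the complex is moved into a canonical molecular
frame (principal axes of a ramp-weighted atom covariance, signs fixed by
third moments).  Any rigid transform of the input lands in the same
frame, so descriptors, seed sites and patch counts do not depend on the
pose in which a structure is deposited — the grid is aligned to the
molecule, not the molecule to the grid.  Seed coordinates are reported
in the caller's input frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .config import FEATURES, RunConfig
from .patching import APPHistogram, compute_app, segment_patches, select_seeds
from .structure import ParameterizedStructure
from .surface import (
    assign_hbond,
    build_grid,
    compute_electrostatics,
    compute_mhp,
    compute_visibility,
    extract_ppi_surface,
    extract_surface,
)
from .zernike import compute_3dzd_batch, descriptor_length, voxelize_patch

__all__ = [
    "PatchDescriptors",
    "PatchDescriptorSet",
    "canonical_frame",
    "compute_interface_descriptors",
    "save_descriptor_set",
    "load_descriptor_set",
]


def canonical_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic pose-independent frame (rotation rows, center).

    Axes are the principal directions of a ramp-weighted covariance of
    the coordinates (the ramp breaks spatial symmetries such as a square
    interface, which would otherwise leave the axes degenerate).  The
    sign of the first two axes follows the weighted third moment (its
    largest-magnitude coordinate decides when the moment is ~0); the
    third axis completes a right-handed system.  Applying a rigid
    transform to the input changes the output frame by exactly that
    transform, so canonical coordinates ``(x - center) @ axes.T`` are
    pose-invariant.
    """
    coords = np.asarray(coords, dtype=float)
    w = 1.0 + np.arange(len(coords)) / max(len(coords) - 1, 1)
    mu = (w[:, None] * coords).sum(0) / w.sum()
    x = coords - mu
    cov = (w[:, None, None] * (x[:, :, None] * x[:, None, :])).sum(0) / w.sum()
    evals, evecs = np.linalg.eigh(cov)
    axes = evecs[:, ::-1].T  # rows, descending variance
    for k in range(2):
        proj = x @ axes[k]
        m3 = (w * proj**3).sum()
        if abs(m3) > 1e-9:
            if m3 < 0:
                axes[k] = -axes[k]
        else:
            j = int(np.argmax(np.abs(axes[k])))
            if axes[k, j] < 0:
                axes[k] = -axes[k]
    axes[2] = np.cross(axes[0], axes[1])
    return axes, mu

FORMAT_VERSION = "1"


@dataclass
class PatchDescriptors:
    """All descriptors of a single patch."""

    patch_id: int
    seed: np.ndarray  # (3,) Å
    n_points: int
    zernike: dict[str, np.ndarray]  # feature name → F_nl vector
    app: APPHistogram


@dataclass
class PatchDescriptorSet:
    """Per-interface collection of patch descriptors."""

    patches: list[PatchDescriptors]
    order: int
    config: RunConfig = field(default_factory=RunConfig)
    label: str = ""

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def seeds(self) -> np.ndarray:
        return np.array([p.seed for p in self.patches]).reshape(-1, 3)

    def feature_matrix(self, feature: str) -> np.ndarray:
        """(n_patches, descriptor_length) matrix for one feature."""
        return np.array([p.zernike[feature] for p in self.patches])


def _transformed(st: ParameterizedStructure, axes, center) -> ParameterizedStructure:
    new_atoms = [
        replace(a, position=tuple((np.asarray(a.position) - center) @ axes.T))
        for a in st.atoms
    ]
    return ParameterizedStructure(
        atoms=new_atoms,
        radius=st.radius,
        partial_charge=st.partial_charge,
        atomic_logp=st.atomic_logp,
        hbond_class=list(st.hbond_class),
        n_param_warnings=st.n_param_warnings,
    )


def compute_interface_descriptors(
    receptor: ParameterizedStructure,
    partner: ParameterizedStructure,
    config: RunConfig | None = None,
    electrostatics_backend: str = "coulomb",
    map_path: str | Path | None = None,
    label: str = "",
    canonicalize: bool = True,
) -> PatchDescriptorSet:
    """Full pipeline from a parameterized receptor/partner pair to descriptors.

    With ``canonicalize`` (the default) the complex is voxelized in its
    canonical frame, making the result independent of the input pose; an
    external electrostatics map (``dx_map`` backend) refers to input-frame
    coordinates, so canonicalization is skipped in that case.  Feature
    fields are evaluated only where needed: hydrophobicity, hydrogen-bond
    class and electrostatics on the whole surface (cheap), ray-cast
    visibility on interface points only (rays still test against the full
    surface).  Seed coordinates in the result are in the input frame.
    """
    cfg = config or RunConfig()
    axes = np.eye(3)
    center = np.zeros(3)
    if canonicalize and electrostatics_backend != "dx_map":
        both = np.vstack([receptor.heavy_coords(), partner.heavy_coords()])
        axes, center = canonical_frame(both)
        receptor = _transformed(receptor, axes, center)
        partner = _transformed(partner, axes, center)
    grid = build_grid(receptor, spacing=cfg.grid_spacing, probe=cfg.probe_radius)
    chains = frozenset(a.chain_id for a in receptor.atoms)
    surface = extract_surface(grid, owner_chain_set=chains)
    ppi = extract_ppi_surface(surface, partner, cutoff=cfg.interface_cutoff)

    compute_mhp(surface, receptor)
    assign_hbond(surface, receptor)
    compute_electrostatics(
        surface, receptor, backend=electrostatics_backend, map_path=map_path
    )
    compute_visibility(
        surface,
        n_rays=cfg.n_rays,
        ray_length=cfg.ray_length,
        block_tol=cfg.block_tol,
        point_indices=ppi.indices,
    )

    seeds = select_seeds(ppi, min_separation=cfg.seed_separation)
    patches = segment_patches(ppi, seeds, radius=cfg.patch_radius)
    apps = compute_app(seeds, ppi, bin_width=cfg.app_bin_width, n_bins=cfg.app_n_bins)

    dim = cfg.zernike_dim
    stacked = np.empty((dim**3, len(patches) * len(FEATURES)))
    for i, patch in enumerate(patches):
        for j, feat in enumerate(FEATURES):
            ub = voxelize_patch(
                patch,
                feat,
                ppi,
                dim=dim,
                patch_radius=cfg.patch_radius,
                scale_margin=cfg.patch_scale_margin,
            )
            stacked[:, i * len(FEATURES) + j] = ub.values.ravel()
    F = compute_3dzd_batch(stacked, dim=dim, order=cfg.zernike_order)

    out = []
    for i, patch in enumerate(patches):
        zern = {
            feat: F[:, i * len(FEATURES) + j].copy()
            for j, feat in enumerate(FEATURES)
        }
        out.append(
            PatchDescriptors(
                patch_id=patch.patch_id,
                seed=patch.seed @ axes + center,  # back to the input frame
                n_points=len(patch.point_indices),
                zernike=zern,
                app=apps[i],
            )
        )
    return PatchDescriptorSet(
        patches=out, order=cfg.zernike_order, config=cfg, label=label
    )


def save_descriptor_set(dset: PatchDescriptorSet, path: str | Path) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "order": dset.order,
        "label": dset.label,
        "config": dset.config.to_dict(),
        "patches": [
            {
                "patch_id": p.patch_id,
                "seed": [round(float(v), 6) for v in p.seed],
                "n_points": p.n_points,
                "zernike": {k: v.tolist() for k, v in p.zernike.items()},
                "app_bins": p.app.bins.tolist(),
                "app_bin_width": p.app.bin_width,
            }
            for p in dset.patches
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_descriptor_set(path: str | Path) -> PatchDescriptorSet:
    doc = json.loads(Path(path).read_text())
    version = doc.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(f"unsupported descriptor file version {version!r}")
    expected = descriptor_length(doc["order"])
    patches = []
    for p in doc["patches"]:
        zern = {k: np.asarray(v, dtype=float) for k, v in p["zernike"].items()}
        for k, v in zern.items():
            if len(v) != expected:
                raise ValueError(
                    f"descriptor length mismatch for feature {k!r}: "
                    f"{len(v)} != {expected}"
                )
        patches.append(
            PatchDescriptors(
                patch_id=p["patch_id"],
                seed=np.asarray(p["seed"], dtype=float),
                n_points=p["n_points"],
                zernike=zern,
                app=APPHistogram(
                    bins=np.asarray(p["app_bins"], dtype=float),
                    bin_width=p["app_bin_width"],
                ),
            )
        )
    cfg = RunConfig.from_dict(doc["config"])
    return PatchDescriptorSet(
        patches=patches, order=doc["order"], config=cfg, label=doc.get("label", "")
    )
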