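"""Shared synthetic fixtures for the test suite.

Heavy objects (the Zernike basis, full-pipeline descriptor sets, the hub
training dataset) are session-scoped so they are computed once.
"""

from __future__ import annotations

import numpy as np
import pytest

from zernpatch import (
    APPHistogram,
    ToyComplexSpec,
    build_parameterized_pair,
    compute_interface_descriptors,
    generate_hub_dataset,
)
from zernpatch.descriptors import PatchDescriptors, PatchDescriptorSet
from zernpatch.config import FEATURES
from zernpatch.surface import FeatureSurface, PPISurface, VoxelGrid
from zernpatch.zernike import descriptor_length


def make_surface_from_indices(
    voxel_indices: np.ndarray, spacing: float = 0.6
) -> FeatureSurface:
    """FeatureSurface directly from integer voxel indices (geometry only)."""
    idx = np.asarray(voxel_indices, dtype=int)
    idx = idx - idx.min(axis=0) + 1
    dims = idx.max(axis=0) + 2
    mask = np.zeros(tuple(dims), dtype=bool)
    mask[tuple(idx.T)] = True
    grid = VoxelGrid(origin=np.zeros(3), spacing=spacing, protein=mask)
    return FeatureSurface(
        points=idx * spacing, voxel_index=idx, grid=grid
    )


def make_ppi_from_indices(voxel_indices, spacing: float = 0.6) -> PPISurface:
    surf = make_surface_from_indices(voxel_indices, spacing)
    return PPISurface(parent=surf, indices=np.arange(len(surf)))


def random_descriptor_set(
    rng: np.random.Generator,
    n_patches: int,
    order: int = 15,
    seed_scale: float = 20.0,
    n_bins: int = 50,
) -> PatchDescriptorSet:
    """Synthetic descriptor set with random descriptors and seed positions."""
    length = descriptor_length(order)
    patches = []
    for pid in range(n_patches):
        zern = {f: rng.uniform(0, 1, size=length) for f in FEATURES}
        bins = rng.uniform(0, 1, size=n_bins)
        bins /= bins.sum()
        patches.append(
            PatchDescriptors(
                patch_id=pid,
                seed=rng.uniform(0, seed_scale, size=3),
                n_points=int(rng.integers(20, 200)),
                zernike=zern,
                app=APPHistogram(bins=bins),
            )
        )
    return PatchDescriptorSet(patches=patches, order=order)


@pytest.fixture(scope="session")
def toy_pair():
    """A small slab complex (receptor, partner) with parameters assigned."""
    spec = ToyComplexSpec(geometry="slab", n_atoms=100, interface_gap=3.0, rng_seed=7)
    return build_parameterized_pair(spec)


@pytest.fixture(scope="session")
def toy_descriptors(toy_pair):
    rec, par = toy_pair
    return compute_interface_descriptors(rec, par, label="toy")


@pytest.fixture(scope="session")
def hub_dataset():
    """2 hubs × 3 partners with hydrophobicity carrying the planted signal."""
    return generate_hub_dataset(
        n_hubs=2, partners_per_hub=3, signal_feature="hydrophobicity", rng_seed=11
    )
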