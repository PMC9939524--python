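"""Order-15 3D Zernike descriptors of functions on the unit ball.

A patch feature field is resampled onto a cubic grid covering the unit
ball and expanded in the Canterakis–Zernike basis

    Z_nlm(r, θ, φ) = R_nl(r) · Y_lm(θ, φ),    0 ≤ l ≤ n,  n − l even,

with moments Ω_nlm = (3/4π) ∫_{|x|≤1} f(x) conj(Z_nlm(x)) dx evaluated as
a voxel sum.  The rotation-invariant descriptor collects the per-(n, l)
norms F_nl = sqrt(Σ_m |Ω_nlm|²); at order 15 there are 72 (n, l) pairs,
hence a 72-dimensional vector per feature.

The radial polynomials are evaluated through their Jacobi-polynomial
closed form, R_nl(r) = sqrt(2n+3) r^l P_k^{(0, l+1/2)}(2r² − 1) with
k = (n − l)/2, which is orthonormal with weight r² on [0, 1].  Real
spherical harmonics are used internally; the m-norms F_nl are identical
to those of the complex basis.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import eval_jacobi, sph_harm_y

from .patching import Patch
from .surface import PPISurface

__all__ = [
    "UnitBallFunction",
    "ZernikeDescriptor",
    "nl_pairs",
    "radial_poly",
    "real_sph_harm",
    "voxelize_patch",
    "compute_3dzd",
    "descriptor_length",
]

# feature fields rescaled per patch to [-1, 1] before expansion (the two
# fields with unbounded natural scale)
RESCALED_FEATURES = frozenset({"electrostatic", "hydrophobicity"})

_FEATURE_FIELD = {
    "electrostatic": "electrostatic",
    "visibility": "visibility",
    "hbond": "hbond",
    "hydrophobicity": "mhp",
}


@dataclass
class UnitBallFunction:
    """Scalar function sampled on a cubic grid spanning [-1, 1]³.

    Voxels outside the unit ball are ignored by the expansion (and kept
    zero by the voxelizer).
    """

    values: np.ndarray  # (dim, dim, dim)

    @property
    def dim(self) -> int:
        return self.values.shape[0]


@dataclass
class ZernikeDescriptor:
    """Rotation-invariant norms F_nl, ordered by (n, l) lexicographically."""

    order: int
    values: np.ndarray  # (len(nl_pairs(order)),) non-negative
    moments: np.ndarray | None = None  # real-basis moments, row per (n,l,m)

    def __len__(self) -> int:
        return len(self.values)


def nl_pairs(order: int) -> list[tuple[int, int]]:
    """Valid (n, l) index pairs: 0 ≤ l ≤ n ≤ order, n − l even."""
    if order < 0:
        raise ValueError("order must be ≥ 0")
    return [(n, l) for n in range(order + 1) for l in range(n % 2, n + 1, 2)]


def descriptor_length(order: int) -> int:
    return len(nl_pairs(order))


def radial_poly(n: int, l: int, r: np.ndarray) -> np.ndarray:
    """Canterakis radial polynomial R_nl on r ∈ [0, 1] (orthonormal, weight r²)."""
    if (n - l) % 2 or l > n:
        raise ValueError("require 0 ≤ l ≤ n with n − l even")
    k = (n - l) // 2
    r = np.asarray(r, dtype=float)
    return np.sqrt(2 * n + 3) * r**l * eval_jacobi(k, 0.0, l + 0.5, 2 * r * r - 1)


def real_sph_harm(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real spherical harmonic Y_lm (theta = polar angle, phi = azimuth)."""
    y = sph_harm_y(l, abs(m), theta, phi)
    if m == 0:
        return y.real
    if m > 0:
        return np.sqrt(2.0) * (-1.0) ** m * y.real
    return np.sqrt(2.0) * (-1.0) ** m * y.imag


class _Basis:
    """Precomputed real Zernike basis sampled at in-ball voxel centers."""

    def __init__(self, dim: int, order: int):
        self.dim = dim
        self.order = order
        centers = (np.arange(dim) + 0.5) * (2.0 / dim) - 1.0
        X, Y, Z = np.meshgrid(centers, centers, centers, indexing="ij")
        r = np.sqrt(X**2 + Y**2 + Z**2)
        inside = r <= 1.0
        self.inside_flat = np.flatnonzero(inside.ravel())
        x, y, z = X[inside], Y[inside], Z[inside]
        rr = r[inside]
        theta = np.arccos(np.clip(np.divide(z, rr, out=np.zeros_like(z), where=rr > 0), -1, 1))
        phi = np.arctan2(y, x)
        self.dv = (2.0 / dim) ** 3

        pairs = nl_pairs(order)
        rows = []
        self.row_index: list[tuple[int, int, int]] = []
        radial_cache: dict[tuple[int, int], np.ndarray] = {}
        harm_cache: dict[tuple[int, int], np.ndarray] = {}
        for n, l in pairs:
            radial_cache[(n, l)] = radial_poly(n, l, rr)
        for l in sorted({l for _, l in pairs}):
            for m in range(l + 1):
                # one complex evaluation serves both ±m real harmonics
                y = sph_harm_y(l, m, theta, phi)
                if m == 0:
                    harm_cache[(l, 0)] = y.real
                else:
                    sign = (-1.0) ** m
                    harm_cache[(l, m)] = np.sqrt(2.0) * sign * y.real
                    harm_cache[(l, -m)] = np.sqrt(2.0) * sign * y.imag
        for n, l in pairs:
            R = radial_cache[(n, l)]
            for m in range(-l, l + 1):
                rows.append(R * harm_cache[(l, m)])
                self.row_index.append((n, l, m))
        self.matrix = np.asarray(rows)  # (n_rows, n_inside)
        # slices grouping rows of one (n, l)
        self.nl_slices: list[slice] = []
        start = 0
        for n, l in pairs:
            self.nl_slices.append(slice(start, start + 2 * l + 1))
            start += 2 * l + 1
        self.pairs = pairs

    def moments(self, values_flat: np.ndarray) -> np.ndarray:
        """Ω for one or more stacked functions; values shape (N³,) or (N³, k)."""
        v = values_flat[self.inside_flat]
        return (3.0 / (4.0 * np.pi)) * (self.matrix @ v) * self.dv

    def invariants(self, omega: np.ndarray) -> np.ndarray:
        out = np.empty((len(self.pairs),) + omega.shape[1:])
        for i, sl in enumerate(self.nl_slices):
            out[i] = np.sqrt((omega[sl] ** 2).sum(axis=0))
        return out


@lru_cache(maxsize=2)
def _get_basis(dim: int, order: int) -> _Basis:
    return _Basis(dim, order)


def compute_3dzd(
    f: UnitBallFunction, order: int = 15, keep_moments: bool = False
) -> ZernikeDescriptor:
    """Expand a unit-ball function and return its rotation-invariant norms."""
    values = np.asarray(f.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("unit-ball function contains non-finite values")
    basis = _get_basis(values.shape[0], order)
    omega = basis.moments(values.ravel())
    F = basis.invariants(omega)
    return ZernikeDescriptor(
        order=order, values=F, moments=omega if keep_moments else None
    )


def compute_3dzd_batch(
    stacked: np.ndarray, dim: int, order: int = 15
) -> np.ndarray:
    """Invariants for several functions at once; ``stacked`` is (dim³, k).

    Returns an array of shape (descriptor_length(order), k).
    """
    basis = _get_basis(dim, order)
    omega = basis.moments(stacked)
    return basis.invariants(omega)


def voxelize_patch(
    patch: Patch,
    feature: str,
    ppi: PPISurface,
    dim: int = 64,
    patch_radius: float = 10.0,
    scale_margin: float = 1.25,
    eps: float = 1e-9,
) -> UnitBallFunction:
    """Resample one patch feature onto the unit-ball grid.

    The patch is translated so its seed sits at the origin and scaled by
    1/(patch_radius · scale_margin), keeping every point strictly inside
    the unit ball (radius ≤ 1/scale_margin = 0.8 by default).  The shape
    feature writes 1 at occupied voxels; electrostatics and hydrophobicity
    are divided by M = max(max |value|, eps) over the patch so their voxel
    values span [-1, 1]; hydrogen-bond (±1/0) and visibility ([0, 1])
    already do.  Points sharing a voxel are averaged.
    """
    if len(patch.point_indices) == 0:
        raise ValueError("empty patch")
    pts = ppi.points[patch.point_indices]
    rel = (pts - patch.seed) / (patch_radius * scale_margin)

    if feature == "shape":
        vals = np.ones(len(rel))
    else:
        field = _FEATURE_FIELD.get(feature)
        if field is None:
            raise ValueError(f"unknown feature {feature!r}")
        vals = np.asarray(ppi.feature(field), dtype=float)[patch.point_indices].copy()
        if feature in RESCALED_FEATURES:
            M = max(np.abs(vals).max(), eps)
            vals = vals / M

    idx = np.floor((rel + 1.0) / (2.0 / dim)).astype(int)
    idx = np.clip(idx, 0, dim - 1)
    flat = (idx[:, 0] * dim + idx[:, 1]) * dim + idx[:, 2]
    acc = np.zeros(dim**3)
    cnt = np.zeros(dim**3)
    np.add.at(acc, flat, vals)
    np.add.at(cnt, flat, 1.0)
    occupied = cnt > 0
    acc[occupied] /= cnt[occupied]
    return UnitBallFunction(values=acc.reshape(dim, dim, dim))
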