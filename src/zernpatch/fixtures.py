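"""Deterministic synthetic protein-complex fixtures.

The generators build small two-chain pseudo-proteins — poly-alanine
backbones arranged as sphere clusters, helical spirals or flat slabs —
with a controllable contact gap between the chains, so that every
pipeline stage (surface, interface, patches, descriptors, matching,
training) can be exercised without downloading real structures.  Atoms
use standard residue/atom naming so the bundled parameter table applies;
per-atom charges, logP contributions and hydrogen-bond classes can be
perturbed or replaced through the spec to emulate feature noise and
planted training signal.  The same spec and seed always produce
byte-identical PDB output.

The geometries are deliberately unphysical (no rotamers, no realistic
backbone): they emulate the *surface statistics* the method consumes —
a contiguous interface with enough area for several patch seeds — not
protein chemistry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .config import RunConfig
from .descriptors import compute_interface_descriptors
from .structure import (
    Atom,
    ParameterizedStructure,
    assign_parameters,
    load_parameter_table,
    write_structure,
)
from .training import HubDataset, HubPartner

__all__ = [
    "ToyComplexSpec",
    "generate_toy_complex",
    "build_parameterized_pair",
    "generate_hub_dataset",
]

GEOMETRIES = ("sphere-cluster", "helix-spiral", "slab")

# local heavy-atom offsets of one pseudo-residue (N, CA, C, O, CB), Å
_RESIDUE_TEMPLATE = np.array(
    [
        [0.0, 0.0, 0.0],  # N
        [1.46, 0.0, 0.0],  # CA
        [2.0, 1.4, 0.0],  # C
        [1.4, 2.4, 0.4],  # O
        [2.0, -0.8, 1.2],  # CB
    ]
)
_ATOM_NAMES = ("N", "CA", "C", "O", "CB")


@dataclass(frozen=True)
class ToyComplexSpec:
    """Specification of a synthetic two-chain complex.

    ``n_atoms`` is per chain and is rounded down to whole pseudo-residues
    of five heavy atoms.  ``interface_gap`` is the closest heavy-atom
    approach between the chains; a gap ≥ 5 Å cannot produce an interface
    under the 5 Å cutoff, so ``expect_interface`` must then be False.
    ``charge_sigma``/``logp_sigma`` add Gaussian noise to the table
    parameters, ``logp_gradient`` plants a deterministic sinusoidal
    hydrophobicity pattern along x, and ``hbond_shuffle`` reassigns each
    atom's H-bond class uniformly at random with the given probability.
    """

    geometry: str = "slab"
    n_atoms: int = 150
    interface_gap: float = 3.0
    rng_seed: int = 0
    expect_interface: bool = True
    jitter: float = 0.3
    charge_sigma: float = 0.0
    logp_sigma: float = 0.0
    logp_gradient: float = 0.0
    hbond_shuffle: float = 0.0

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"geometry must be one of {GEOMETRIES}")
        if self.n_atoms < 5:
            raise ValueError("need at least one 5-atom pseudo-residue per chain")
        if self.expect_interface and self.interface_gap >= 5.0:
            raise ValueError(
                "interface_gap ≥ 5 Å cannot yield an interface under the 5 Å "
                "cutoff; set expect_interface=False if that is intended"
            )


def _residue_centers(geometry: str, n_res: int, rng: np.random.Generator) -> np.ndarray:
    if geometry == "sphere-cluster":
        radius = 2.5 * n_res ** (1 / 3) + 2.0
        pts = rng.normal(size=(4 * n_res, 3))
        pts = radius * pts / np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= rng.uniform(0, 1, size=(len(pts), 1)) ** (1 / 3)
        # thin to ≥ 4 Å separation, greedy
        out = []
        for p in pts:
            if all(np.linalg.norm(p - q) > 4.0 for q in out):
                out.append(p)
            if len(out) == n_res:
                break
        while len(out) < n_res:  # top up deterministically if thinning starved
            out.append(rng.normal(scale=radius / 2, size=3))
        return np.array(out)
    if geometry == "helix-spiral":
        t = np.arange(n_res) * 1.75
        r = 8.0
        return np.column_stack([r * np.cos(t / 3), r * np.sin(t / 3), 1.5 * t / 3])
    # slab: near-square grid in the xy-plane, 5 Å pitch
    nx = int(np.ceil(np.sqrt(n_res)))
    xs, ys = np.meshgrid(np.arange(nx), np.arange(nx), indexing="ij")
    centers = np.column_stack(
        [xs.ravel() * 5.0, ys.ravel() * 5.0, np.zeros(nx * nx)]
    )[:n_res]
    return centers - centers.mean(axis=0)


def _chain_atoms(
    centers: np.ndarray,
    chain_id: str,
    first_serial: int,
    first_resseq: int,
    rng: np.random.Generator,
    jitter: float,
) -> list[Atom]:
    atoms = []
    serial = first_serial
    for ri, c in enumerate(centers):
        noise = rng.normal(scale=jitter, size=_RESIDUE_TEMPLATE.shape)
        for name, offset, dx in zip(_ATOM_NAMES, _RESIDUE_TEMPLATE, noise):
            pos = c + offset + dx
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    residue_name="ALA",
                    chain_id=chain_id,
                    residue_seq=first_resseq + ri,
                    position=(round(pos[0], 3), round(pos[1], 3), round(pos[2], 3)),
                    element=name[0],
                )
            )
            serial += 1
    return atoms


def _calibrate_gap(xyz_a: np.ndarray, xyz_b: np.ndarray, gap: float) -> np.ndarray:
    """Slide chain B down along z until the closest approach equals the gap.

    Bisection: the minimum inter-chain distance decreases monotonically
    while the chains approach from above.
    """
    xyz_b = xyz_b.copy()
    xyz_b[:, 2] += xyz_a[:, 2].max() - xyz_b[:, 2].min() + 20.0

    def min_dist(s: float) -> float:
        moved = xyz_b - [0.0, 0.0, s]
        return np.sqrt(((xyz_a[:, None] - moved[None, :]) ** 2).sum(-1)).min()

    lo, hi = 0.0, xyz_b[:, 2].max() - xyz_a[:, 2].min() + 20.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if min_dist(mid) > gap:
            lo = mid
        else:
            hi = mid
    xyz_b[:, 2] -= 0.5 * (lo + hi)
    return xyz_b


def _build_chains(spec: ToyComplexSpec) -> tuple[list[Atom], list[Atom]]:
    rng = np.random.default_rng(spec.rng_seed)
    n_res = spec.n_atoms // 5
    centers_a = _residue_centers(spec.geometry, n_res, rng)
    centers_b = _residue_centers(spec.geometry, max(n_res // 2, 2), rng)
    atoms_a = _chain_atoms(centers_a, "A", 1, 1, rng, spec.jitter)
    atoms_b = _chain_atoms(centers_b, "B", len(atoms_a) + 1, 1000, rng, spec.jitter)

    xyz_a = np.array([a.position for a in atoms_a])
    xyz_b = _calibrate_gap(xyz_a, np.array([a.position for a in atoms_b]),
                           spec.interface_gap)
    atoms_b = [
        replace(a, position=(round(p[0], 3), round(p[1], 3), round(p[2], 3)))
        for a, p in zip(atoms_b, xyz_b)
    ]
    return atoms_a, atoms_b


def build_parameterized_pair(
    spec: ToyComplexSpec,
) -> tuple[ParameterizedStructure, ParameterizedStructure]:
    """In-memory receptor (chain A) and partner (chain B) with parameters.

    Table parameters are applied first, then the spec's perturbations
    (noise, planted hydrophobicity gradient, H-bond reshuffling), using a
    dedicated RNG stream so coordinates and parameters are independently
    reproducible.
    """
    atoms_a, atoms_b = _build_chains(spec)
    table = load_parameter_table()
    rng = np.random.default_rng(spec.rng_seed + 10_000)
    out = []
    for atoms in (atoms_a, atoms_b):
        st = assign_parameters(ParameterizedStructure(atoms=list(atoms)), table)
        if spec.charge_sigma > 0:
            st.partial_charge = st.partial_charge + rng.normal(
                scale=spec.charge_sigma, size=len(st)
            )
        if spec.logp_sigma > 0:
            st.atomic_logp = st.atomic_logp + rng.normal(
                scale=spec.logp_sigma, size=len(st)
            )
        if spec.logp_gradient != 0.0:
            x = st.coords[:, 0]
            st.atomic_logp = st.atomic_logp + spec.logp_gradient * np.sin(
                2 * np.pi * x / 12.0
            )
        if spec.hbond_shuffle > 0:
            classes = ("donor", "acceptor", "dual", "none")
            flip = rng.uniform(size=len(st)) < spec.hbond_shuffle
            draw = rng.integers(0, 4, size=len(st))
            st.hbond_class = [
                classes[draw[i]] if flip[i] else c
                for i, c in enumerate(st.hbond_class)
            ]
        out.append(st)
    return out[0], out[1]


def generate_toy_complex(
    spec: ToyComplexSpec, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write the complex as PDB plus a ground-truth TSV; returns both paths.

    The TSV lists, per atom, the parameters actually generated and whether
    the atom is interfacial (within 5 Å of the other chain).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rec, par = build_parameterized_pair(spec)
    both = ParameterizedStructure(atoms=rec.atoms + par.atoms)
    tag = f"{spec.geometry}_seed{spec.rng_seed}"
    pdb_path = out_dir / f"toy_{tag}.pdb"
    truth_path = out_dir / f"toy_{tag}_truth.tsv"
    write_structure(both, pdb_path)

    xyz_a, xyz_b = rec.coords, par.coords
    d_ab = np.sqrt(((xyz_a[:, None] - xyz_b[None, :]) ** 2).sum(-1))
    inter_a = (d_ab < 5.0).any(axis=1)
    inter_b = (d_ab < 5.0).any(axis=0)
    lines = ["serial\tchain\tresseq\tatom\tcharge\tlogp\thbond_class\tinterfacial"]
    for st, mask in ((rec, inter_a), (par, inter_b)):
        for i, a in enumerate(st.atoms):
            lines.append(
                f"{a.serial}\t{a.chain_id}\t{a.residue_seq}\t{a.name}\t"
                f"{st.partial_charge[i]:.4f}\t{st.atomic_logp[i]:.4f}\t"
                f"{st.hbond_class[i]}\t{int(mask[i])}"
            )
    truth_path.write_text("\n".join(lines) + "\n")
    return pdb_path, truth_path


def _plant_field(
    st: ParameterizedStructure,
    feature: str,
    region_values: np.ndarray,
    region_of_atom: np.ndarray,
) -> None:
    """Overwrite one parameter channel with a fixed per-region pattern."""
    vals = region_values[region_of_atom]
    if feature == "hydrophobicity":
        st.atomic_logp = vals
    elif feature == "electrostatic":
        st.partial_charge = vals
    elif feature == "hbond":
        classes = ("donor", "acceptor", "none")
        st.hbond_class = [classes[int(v) % 3] for v in np.floor(vals * 10)]
    else:
        raise ValueError(
            "plantable features are hydrophobicity, electrostatic, hbond"
        )


def generate_hub_dataset(
    n_hubs: int = 2,
    partners_per_hub: int = 3,
    signal_feature: str = "hydrophobicity",
    rng_seed: int = 0,
    out_dir: str | Path | None = None,
    config: RunConfig | None = None,
    partner_grid: tuple[int, int] = (6, 3),
    partner_jitter: float = 0.1,
) -> HubDataset:
    """Synthetic hub dataset with a single feature carrying planted signal.

    Each hub is a flat rectangular slab; its partners are jittered copies
    of one base slab pressed against it, so patch seeds of different
    partners of the same hub nearly coincide and correspondences are
    known by construction (identity hub alignment).  The rectangle is
    deliberately anisotropic: a square interface would leave the
    canonical principal frame nearly degenerate and let jitter rotate
    the voxelization between partner copies.  The designated
    ``signal_feature`` gets a per-residue random pattern that is *fixed
    across partners of a hub*, while the remaining scalar channels are
    re-randomized per partner — only the signal feature can identify
    corresponding patches.  Hubs differ in pattern and in slab extent.

    Descriptors are computed with the genuine pipeline.  When ``out_dir``
    is given, complexes are written as PDB plus a JSON manifest.
    """
    if partners_per_hub < 2:
        raise ValueError("need at least 2 partners per hub")
    if n_hubs < 1:
        raise ValueError("need at least 1 hub")
    cfg = config or RunConfig()
    rng = np.random.default_rng(rng_seed)
    partners: list[HubPartner] = []
    manifest = []
    for h in range(n_hubs):
        nx, ny = partner_grid[0], partner_grid[1] + h  # hubs differ in extent

        def rect(nx_, ny_):
            xs, ys = np.meshgrid(np.arange(nx_), np.arange(ny_), indexing="ij")
            c = np.column_stack(
                [xs.ravel() * 5.0, ys.ravel() * 5.0, np.zeros(nx_ * ny_)]
            )
            return c - c.mean(axis=0)

        base_rng = np.random.default_rng(rng_seed * 1000 + h)
        base_a = _chain_atoms(rect(nx, ny), "A", 1, 1, base_rng, 0.0)
        hub_atoms = _chain_atoms(
            rect(max(nx - 2, 2), max(ny - 1, 2)), "B",
            len(base_a) + 1, 1000, base_rng, 0.0,
        )
        xyz_a = np.array([a.position for a in base_a])
        xyz_hub = _calibrate_gap(
            xyz_a, np.array([a.position for a in hub_atoms]), 3.0
        )
        base_b = [
            replace(a, position=(round(p[0], 3), round(p[1], 3), round(p[2], 3)))
            for a, p in zip(hub_atoms, xyz_hub)
        ]
        region_of_atom = np.array([a.residue_seq for a in base_a])
        region_of_atom = region_of_atom - region_of_atom.min()
        # planted field: an independent random value per residue (5 Å
        # pitch), fixed across the partner copies of a hub — a spatial
        # fingerprint that only repeats at corresponding sites
        signal_values = rng.uniform(-1.0, 1.0, size=region_of_atom.max() + 1)
        table = load_parameter_table()
        for p in range(partners_per_hub):
            prng = np.random.default_rng(rng_seed * 1000 + 100 * h + p + 1)
            jitter_a = prng.normal(scale=partner_jitter, size=(len(base_a), 3))
            atoms_a = [
                replace(
                    a,
                    serial=a.serial,
                    position=tuple(np.round(np.array(a.position) + d, 3)),
                )
                for a, d in zip(base_a, jitter_a)
            ]
            receptor = assign_parameters(
                ParameterizedStructure(atoms=atoms_a), table
            )
            hub_st = assign_parameters(
                ParameterizedStructure(atoms=[replace(a) for a in base_b]), table
            )
            # noise channels: re-randomized per partner
            receptor.partial_charge = prng.uniform(-0.8, 0.8, size=len(receptor))
            receptor.atomic_logp = prng.uniform(-1.0, 1.0, size=len(receptor))
            classes = ("donor", "acceptor", "none")
            receptor.hbond_class = [
                classes[i] for i in prng.integers(0, 3, size=len(receptor))
            ]
            _plant_field(receptor, signal_feature, signal_values, region_of_atom)
            name = f"hub{h}_partner{p}"
            dset = compute_interface_descriptors(
                receptor, hub_st, config=cfg, label=name
            )
            partners.append(
                HubPartner(hub_id=f"hub{h}", name=name, descriptors=dset)
            )
            if out_dir is not None:
                out_dir = Path(out_dir)
                out_dir.mkdir(parents=True, exist_ok=True)
                both = ParameterizedStructure(atoms=receptor.atoms + hub_st.atoms)
                pdb = out_dir / f"{name}.pdb"
                write_structure(both, pdb)
                manifest.append(
                    {
                        "hub": f"hub{h}",
                        "name": name,
                        "pdb": pdb.name,
                        "receptor_chains": ["A"],
                        "partner_chains": ["B"],
                        "transform": {"rotation": np.eye(3).tolist(),
                                      "translation": [0.0, 0.0, 0.0]},
                    }
                )
    if out_dir is not None:
        (Path(out_dir) / "manifest.json").write_text(
            json.dumps({"signal_feature": signal_feature, "entries": manifest},
                       indent=1)
        )
    return HubDataset.build(partners)
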