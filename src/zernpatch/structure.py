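"""Coordinate parsing and per-atom physicochemical parameterization.

Atoms are read from PDB files with gemmi, filtered to the requested
chains, and annotated with four per-atom parameters from a bundled lookup
table: a van der Waals radius (Å), an approximate partial charge (e), a
Crippen-style atomic logP contribution (the per-atom hydrophobicity that
feeds the molecular hydrophobic field), and a hydrogen-bond class (donor,
acceptor, dual, or none).  The table is an open substitute for the
proprietary atomic logP parameterization used in the original study; the
hydrophobic field only requires a consistent per-atom logP scale.

Hydrogens, if present in the file, are parsed but excluded from every
heavy-atom query (interface cutoffs, surface construction, nearest-atom
feature assignment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Atom",
    "ParameterizedStructure",
    "load_parameter_table",
    "parse_structure",
    "assign_parameters",
    "write_structure",
]

_DEFAULT_RADIUS = 1.7
_DEFAULT_CHARGE = 0.0
_DEFAULT_LOGP = 0.0
_DEFAULT_HBOND = "none"

HBOND_CLASSES = ("donor", "acceptor", "dual", "none")


@dataclass(frozen=True)
class Atom:
    """A single atom record."""

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_seq: int
    position: tuple[float, float, float]
    element: str

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("atom element must be non-empty")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class ParameterizedStructure:
    """Ordered atoms plus per-atom radius, charge, logP and H-bond class.

    Parameter arrays are aligned with ``atoms``; before
    :func:`assign_parameters` runs they are empty.  ``n_param_warnings``
    counts atoms whose (residue, atom-name) key missed the lookup table
    and received neutral defaults.
    """

    atoms: list[Atom]
    radius: np.ndarray = field(default_factory=lambda: np.empty(0))
    partial_charge: np.ndarray = field(default_factory=lambda: np.empty(0))
    atomic_logp: np.ndarray = field(default_factory=lambda: np.empty(0))
    hbond_class: list[str] = field(default_factory=list)
    n_param_warnings: int = 0

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([not a.is_hydrogen for a in self.atoms], dtype=bool)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        return self.coords[self.heavy_mask].reshape(-1, 3)

    def heavy_view(self) -> "ParameterizedStructure":
        """Structure restricted to heavy atoms (parameters sliced along)."""
        m = self.heavy_mask
        idx = np.flatnonzero(m)
        return ParameterizedStructure(
            atoms=[self.atoms[i] for i in idx],
            radius=self.radius[m] if self.radius.size else self.radius,
            partial_charge=(
                self.partial_charge[m] if self.partial_charge.size else self.partial_charge
            ),
            atomic_logp=self.atomic_logp[m] if self.atomic_logp.size else self.atomic_logp,
            hbond_class=[self.hbond_class[i] for i in idx] if self.hbond_class else [],
            n_param_warnings=self.n_param_warnings,
        )


def load_parameter_table(path: str | Path | None = None) -> dict[tuple[str, str], tuple]:
    """Load a (residue, atom) → (radius, charge, logp, hbond_class) table.

    Without ``path`` the bundled table is used.  The format is TSV with a
    ``residue  atom  radius  charge  logp  hbond_class`` header;
    ``#`` lines are comments.
    """
    if path is None:
        src = resources.files("zernpatch").joinpath("data/atom_params.tsv")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    table: dict[tuple[str, str], tuple] = {}
    header_seen = False
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            header_seen = True  # column header row
            continue
        res, atom, radius, charge, logp, hb = line.split("\t")
        radius_f = float(radius)
        if not 0 < radius_f <= 3:
            raise ValueError(f"radius out of range (0, 3] for {res} {atom}")
        if hb not in HBOND_CLASSES:
            raise ValueError(f"unknown hbond class {hb!r} for {res} {atom}")
        table[(res, atom)] = (radius_f, float(charge), float(logp), hb)
    return table


def parse_structure(path: str | Path, chains: Iterable[str]) -> ParameterizedStructure:
    """Parse a PDB file and keep the atoms of the requested chains.

    Alternate locations are resolved to the highest-occupancy record (ties:
    the first record wins); HETATM water is excluded.  Raises
    ``FileNotFoundError`` for a missing file and ``ValueError`` when no
    atom of a requested chain is present.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    chains = set(chains)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"unparsable PDB file {path}: {exc}") from exc
    st.setup_entities()

    atoms: list[Atom] = []
    model = st[0]
    for chain in model:
        if chain.name not in chains:
            continue
        for residue in chain:
            if residue.is_water():
                continue
            if residue.het_flag == "H":
                continue  # non-water HETATM excluded by policy
            # resolve altlocs: group by atom name, keep highest occupancy
            by_name: dict[str, gemmi.Atom] = {}
            for at in residue:
                prev = by_name.get(at.name)
                if prev is None or at.occ > prev.occ:
                    by_name[at.name] = at
            for at in residue:
                chosen = by_name[at.name]
                if chosen is not at:
                    continue
                atoms.append(
                    Atom(
                        serial=at.serial,
                        name=at.name,
                        residue_name=residue.name,
                        chain_id=chain.name,
                        residue_seq=residue.seqid.num,
                        position=(at.pos.x, at.pos.y, at.pos.z),
                        element=at.element.name or at.name[0],
                    )
                )
    if not atoms:
        raise ValueError(
            f"no atoms for chain(s) {sorted(chains)} in {path}"
        )
    return ParameterizedStructure(atoms=atoms)


def assign_parameters(
    structure: ParameterizedStructure,
    tables: Mapping[tuple[str, str], tuple] | None = None,
) -> ParameterizedStructure:
    """Attach radius, charge, logP and H-bond class to every atom.

    Lookup is by (residue name, atom name); a miss falls back to a 1.7 Å
    radius, zero charge, zero logP and H-bond class ``none`` and is counted
    in ``n_param_warnings`` (one summary warning is emitted).  Assignment is
    per-atom and order-independent.
    """
    if len(structure) == 0:
        raise ValueError("cannot assign parameters to an empty structure")
    if tables is None:
        tables = load_parameter_table()
    n = len(structure)
    radius = np.empty(n)
    charge = np.empty(n)
    logp = np.empty(n)
    hbond: list[str] = []
    misses = 0
    for i, atom in enumerate(structure.atoms):
        key = (atom.residue_name, atom.name)
        entry = tables.get(key)
        if entry is None and atom.is_hydrogen:
            entry = (1.0, 0.0, 0.0, "none")
        if entry is None:
            entry = (_DEFAULT_RADIUS, _DEFAULT_CHARGE, _DEFAULT_LOGP, _DEFAULT_HBOND)
            misses += 1
        radius[i], charge[i], logp[i], hb = entry
        hbond.append(hb)
    if misses:
        warnings.warn(
            f"{misses} atom(s) missing from the parameter table; neutral defaults applied",
            stacklevel=2,
        )
    structure.radius = radius
    structure.partial_charge = charge
    structure.atomic_logp = logp
    structure.hbond_class = hbond
    structure.n_param_warnings = misses
    return structure


def write_structure(structure: ParameterizedStructure, path: str | Path) -> None:
    """Write atoms back out as minimal fixed-format PDB ATOM records."""
    lines = []
    for a in structure.atoms:
        x, y, z = a.position
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        lines.append(
            f"ATOM  {a.serial:>5d} {name}{'':1s}{a.residue_name:>3s} "
            f"{a.chain_id:1s}{a.residue_seq:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
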