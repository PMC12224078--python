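"""Coordinate model container, PDB/mmCIF I/O and consensus atom sets.

An ensemble of near-identical structures (e.g. the same protein solved from
several molecular-replacement starting models) is compared on its *consensus
set*: the atom keys present in every member, restricted to a residue range
and minus explicit exclusions such as the terminal nitrogen atoms of
arginine side chains whose positions are poorly determined.

File parsing and writing are delegated to :mod:`gemmi`; this module owns the
in-memory model and the selection logic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "ConsensusSet",
    "UnitCell",
    "AtomKey",
    "ExclusionRule",
    "read_structure",
    "write_structure",
    "build_consensus_set",
    "DEFAULT_CONSENSUS_RULES",
]

AtomKey = tuple[str, int, str]

#: Residue names never included in consensus sets (solvent / cryoprotectant).
SOLVENT_RESNAMES = frozenset({"HOH", "WAT", "DOD", "GOL", "EDO", "PEG", "SO4", "PO4", "CL", "NA"})

#: Canonical PDB v3 heavy-atom ordering used to make selections deterministic.
_ATOM_ORDER = [
    "N", "CA", "C", "O", "OXT",
    "CB", "CG", "CG1", "CG2", "OG", "OG1", "SG",
    "CD", "CD1", "CD2", "OD1", "OD2", "ND1", "ND2", "SD",
    "CE", "CE1", "CE2", "CE3", "NE", "NE1", "NE2", "OE1", "OE2",
    "CZ", "CZ2", "CZ3", "NZ",
    "CH2", "OH", "NH1", "NH2",
]
_ATOM_RANK = {name: i for i, name in enumerate(_ATOM_ORDER)}


def atom_sort_key(key: AtomKey) -> tuple:
    chain, resnum, name = key
    return (chain, resnum, _ATOM_RANK.get(name, len(_ATOM_ORDER)), name)


@dataclass
class UnitCell:
    """Crystallographic unit cell (lengths in Å, angles in degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")

    def to_gemmi(self):
        import gemmi

        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def volume(self) -> float:
        return float(self.to_gemmi().volume)

    def frac_matrix(self) -> np.ndarray:
        """3x3 matrix taking Cartesian (Å) to fractional coordinates."""
        m = self.to_gemmi().frac.mat
        return np.array(m.tolist(), dtype=float)


@dataclass
class Atom:
    """One heavy atom of a coordinate model.

    ``confidence`` optionally carries a predictor score; ``confidence_kind``
    distinguishes pLDDT (0-100, higher = better) from an estimated
    coordinate error in Å (lower = better).
    """

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray
    b_factor: float = 0.0
    occupancy: float = 1.0
    confidence: float | None = None
    confidence_kind: str | None = None  # "plddt" | "error_angstrom"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"bad position for atom {self.atom_name}: {self.position}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        self.atom_name = self.atom_name.strip()
        self.element = self.element.strip().capitalize()

    @property
    def key(self) -> AtomKey:
        return (self.chain_id, self.residue_number, self.atom_name)

    def copy(self) -> "Atom":
        return replace(self, position=self.position.copy())


@dataclass
class Structure:
    """An ordered collection of atoms, optionally with cell and symmetry.

    ``symmetry`` holds symmetry operator triplets (e.g. ``"-X,Y+1/2,-Z"``);
    interpretation is left to the structure-factor machinery.
    """

    atoms: list[Atom] = field(default_factory=list)
    cell: UnitCell | None = None
    symmetry: list[str] | None = None
    label: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def keys(self) -> list[AtomKey]:
        return [a.key for a in self.atoms]

    def atom_map(self) -> dict[AtomKey, Atom]:
        return {a.key: a for a in self.atoms}

    def coords(self, keys: Sequence[AtomKey] | None = None) -> np.ndarray:
        """(n, 3) coordinate array, optionally in the order of ``keys``."""
        if keys is None:
            return np.array([a.position for a in self.atoms], dtype=float)
        amap = self.atom_map()
        try:
            return np.array([amap[k].position for k in keys], dtype=float)
        except KeyError as exc:
            raise KeyError(f"atom {exc.args[0]} not present in structure {self.label!r}") from None

    def copy(self, label: str | None = None) -> "Structure":
        return Structure(
            atoms=[a.copy() for a in self.atoms],
            cell=self.cell,
            symmetry=list(self.symmetry) if self.symmetry else None,
            label=self.label if label is None else label,
        )

    def subset(self, keys: Iterable[AtomKey]) -> "Structure":
        keyset = set(keys)
        return Structure(
            atoms=[a.copy() for a in self.atoms if a.key in keyset],
            cell=self.cell,
            symmetry=list(self.symmetry) if self.symmetry else None,
            label=self.label,
        )

    def residues(self) -> dict[tuple[str, int], list[Atom]]:
        out: dict[tuple[str, int], list[Atom]] = {}
        for a in self.atoms:
            out.setdefault((a.chain_id, a.residue_number), []).append(a)
        return out

    def validate_unique_keys(self) -> None:
        seen = set()
        for a in self.atoms:
            if a.key in seen:
                raise ValueError(f"duplicate atom key {a.key}")
            seen.add(a.key)


@dataclass(frozen=True)
class ExclusionRule:
    """Exclude atoms named ``atom_name`` from residues matching ``residue``.

    ``residue`` is either a 3-letter residue name (e.g. ``"ARG"``) or an
    author residue number (e.g. ``29``).
    """

    residue: str | int
    atom_name: str

    def matches(self, atom: Atom) -> bool:
        if atom.atom_name != self.atom_name:
            return False
        if isinstance(self.residue, int):
            return atom.residue_number == self.residue
        return atom.residue_name == self.residue.upper()


#: Standard exclusion rules for the synthetic mini-protein ensemble: arginine
#: eta-nitrogens, tyrosine eta-oxygens and the zeta-nitrogens of the two
#: lysines at author positions 29 and 56.
DEFAULT_CONSENSUS_RULES: tuple[ExclusionRule, ...] = (
    ExclusionRule("ARG", "NH1"),
    ExclusionRule("ARG", "NH2"),
    ExclusionRule("TYR", "OH"),
    ExclusionRule(29, "NZ"),
    ExclusionRule(56, "NZ"),
)


@dataclass
class ConsensusSet:
    """Ordered atom keys shared by every member of an ensemble."""

    keys: list[AtomKey]
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.keys)

    def __iter__(self):
        return iter(self.keys)

    def ca_only(self) -> "ConsensusSet":
        return ConsensusSet(
            keys=[k for k in self.keys if k[2] == "CA"],
            provenance=self.provenance + ["restricted to CA"],
        )


def _is_hydrogen(element: str, name: str) -> bool:
    el = element.strip().upper()
    if el in ("H", "D"):
        return True
    return el == "" and name.strip().upper().startswith(("H", "D"))


def read_structure(path: str | Path, format: str = "auto", keep_hydrogens: bool = False) -> Structure:
    """Read a PDB or mmCIF coordinate file into a :class:`Structure`.

    Hydrogen atoms are dropped by default.  Alternate locations other than
    blank or 'A' are rejected: the ensembles this package targets are
    single-conformer models, and silently picking one altloc would bias
    every downstream comparison.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if fmt == "pdb":
        st = gemmi.read_pdb(str(path))
    elif fmt in ("mmcif", "cif"):
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    else:
        raise ValueError(f"unknown format {format!r}")
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")

    atoms: list[Atom] = []
    model = st[0]
    for chain in model:
        for res in chain:
            for at in res:
                if at.altloc not in ("", "\x00", "A"):
                    raise ValueError(
                        f"{path}: atom {chain.name}/{res.seqid.num}/{at.name} has "
                        f"altloc {at.altloc!r}; alternate conformations are not supported"
                    )
                if not keep_hydrogens and _is_hydrogen(at.element.name, at.name):
                    continue
                atoms.append(
                    Atom(
                        chain_id=chain.name,
                        residue_number=res.seqid.num,
                        residue_name=res.name,
                        atom_name=at.name,
                        element=at.element.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        b_factor=at.b_iso,
                        occupancy=at.occ,
                    )
                )
    if not atoms:
        raise ValueError(f"{path}: no atoms read")

    cell = None
    gc = st.cell
    if gc is not None and gc.a > 1.0 and gc.volume > 1.0:
        cell = UnitCell(gc.a, gc.b, gc.c, gc.alpha, gc.beta, gc.gamma)
    symmetry = None
    sg = gemmi.find_spacegroup_by_name(st.spacegroup_hm) if st.spacegroup_hm else None
    if sg is not None:
        symmetry = [op.triplet() for op in sg.operations()]
    structure = Structure(atoms=atoms, cell=cell, symmetry=symmetry, label=path.stem)
    structure.validate_unique_keys()
    return structure


def write_structure(s: Structure, path: str | Path, format: str = "auto") -> Path:
    """Write a :class:`Structure` to PDB (fixed-column) or mmCIF."""
    import gemmi

    if len(s) == 0:
        raise ValueError("refusing to write a structure with no atoms")
    path = Path(path)
    fmt = format.lower()
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"

    st = gemmi.Structure()
    st.name = s.label or "model"
    if s.cell is not None:
        st.cell = s.cell.to_gemmi()
        st.spacegroup_hm = "P 1"
    model = gemmi.Model("1")
    chain_order: list[str] = []
    chains: dict[str, gemmi.Chain] = {}
    for a in s.atoms:
        if a.chain_id not in chains:
            chains[a.chain_id] = gemmi.Chain(a.chain_id)
            chain_order.append(a.chain_id)
        ch = chains[a.chain_id]
        if len(ch) == 0 or ch[len(ch) - 1].seqid.num != a.residue_number:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, " ")
            ch.add_residue(res)
        res = ch[len(ch) - 1]
        at = gemmi.Atom()
        at.name = a.atom_name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.position)
        at.b_iso = a.b_factor
        at.occ = a.occupancy
        res.add_atom(at)
    for name in chain_order:
        model.add_chain(chains[name])
    st.add_model(model)
    st.setup_entities()
    if fmt == "pdb":
        st.write_pdb(str(path))
    elif fmt in ("mmcif", "cif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def build_consensus_set(
    models: Sequence[Structure],
    residue_range: tuple[int, int] | None = None,
    atom_exclusions: Sequence[ExclusionRule] = (),
    include_solvent: bool = False,
) -> ConsensusSet:
    """Intersect atom keys over an ensemble of models.

    The result is ordered by (chain, residue number, canonical atom order)
    and is therefore independent of the order in which models are given.
    """
    if len(models) < 2:
        raise ValueError("need at least two models to build a consensus set")
    provenance: list[str] = []

    def eligible(a: Atom) -> bool:
        if not include_solvent and a.residue_name in SOLVENT_RESNAMES:
            return False
        if residue_range is not None and not residue_range[0] <= a.residue_number <= residue_range[1]:
            return False
        return not any(rule.matches(a) for rule in atom_exclusions)

    key_sets = []
    for m in models:
        key_sets.append({a.key for a in m.atoms if eligible(a)})
    shared = set.intersection(*key_sets)
    if not shared:
        raise ValueError("consensus set is empty: models share no eligible atoms")

    if residue_range is not None:
        provenance.append(f"residue range {residue_range[0]}-{residue_range[1]}")
    for rule in atom_exclusions:
        provenance.append(f"excluded {rule.residue}/{rule.atom_name}")
    if not include_solvent:
        provenance.append("solvent/co-solvent excluded")

    ordered = sorted(shared, key=atom_sort_key)
    return ConsensusSet(keys=ordered, provenance=provenance)
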