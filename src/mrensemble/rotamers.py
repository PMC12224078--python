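"""Side-chain dihedral angles, rotamer classification and torus histograms.

Rotamer states follow the penultimate-library nomenclature: the chi1 and
chi2 angles are binned into p (plus, gauche+, around +65°), t (trans,
around 180°) and m (minus, gauche-, around -65°), and the terminal chi
carries an explicit canonical value in the state name, e.g. "tt 0°" for a
glutamate with chi1 and chi2 trans and chi3 near 0°.  The glutamate
carboxylate is two-fold symmetric, so chi3 is only defined modulo 180°.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._geometry import dihedral, wrap_angle
from .structure import Structure

__all__ = [
    "DihedralSet",
    "RotamerAssignment",
    "TorusHistogram",
    "chi_angles",
    "assign_rotamer",
    "ensemble_rotamer_table",
    "torus_histogram",
    "CHI_ATOMS",
    "CANONICAL_ROTAMERS",
]

#: Atom quadruples defining chi angles, per residue type.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"), ("CB", "CG", "SD", "CE")],
    "LYS": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "CE"),
        ("CG", "CD", "CE", "NZ"),
    ],
    "ARG": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "NE"),
        ("CG", "CD", "NE", "CZ"),
    ],
}

#: Idealized chi1/chi2 bin centres (degrees).
BIN_CENTERS = {"p": 65.0, "t": 180.0, "m": -65.0}

#: Canonical rotamer states per residue type: name -> (chi1, chi2, chi_terminal).
#: Glutamate has eight named states (every chi1/chi2 bin combination except pp).
CANONICAL_ROTAMERS: dict[str, dict[str, tuple[float, ...]]] = {
    "GLU": {
        "tt 0°": (180.0, 180.0, 0.0),
        "mm-40°": (-65.0, -65.0, -40.0),
        "mt-10°": (-65.0, 180.0, -10.0),
        "pm0°": (65.0, -65.0, 0.0),
        "tm-20°": (180.0, -65.0, -20.0),
        "pt-20°": (65.0, 180.0, -20.0),
        "tp10°": (180.0, 65.0, 10.0),
        "mp0°": (-65.0, 65.0, 0.0),
    },
}

#: Residue types with a symmetric terminal group: terminal chi modulo 180°.
SYMMETRIC_TERMINAL = frozenset({"GLU", "ASP", "PHE", "TYR"})


@dataclass
class DihedralSet:
    """Chi angles of one residue in one model (degrees, (-180, 180])."""

    chain_id: str
    residue_number: int
    residue_name: str
    chi: tuple[float | None, ...]  # None marks an undefined angle
    label: str = ""

    @property
    def defined(self) -> bool:
        return all(c is not None for c in self.chi)


@dataclass
class RotamerAssignment:
    state_name: str
    chi_bins: str  # e.g. "tt"
    chi3_canonical: float
    distance: float  # torus distance (degrees) to the canonical point
    flagged: bool = False  # True when the chi1/chi2 bin had no named state
    label: str = ""


@dataclass
class TorusHistogram:
    """Probability density on the (chi1, chi2) torus, bins on [0, 360)^2."""

    edges: np.ndarray  # (n_bins + 1,) shared by both axes
    density: np.ndarray  # (n_bins, n_bins), per square degree

    def integral(self) -> float:
        width = np.diff(self.edges)
        return float(np.sum(self.density * np.outer(width, width)))

    def mode(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.argmax(self.density), self.density.shape)
        centers = 0.5 * (self.edges[:-1] + self.edges[1:])
        return float(centers[i]), float(centers[j])


def chi_angles(s: Structure, chain_id: str, residue_number: int) -> DihedralSet:
    """Chi dihedrals of one residue; missing atoms give explicit ``None``
    entries rather than a silent zero."""
    atoms = {
        a.atom_name: a
        for a in s.atoms
        if a.chain_id == chain_id and a.residue_number == residue_number
    }
    if not atoms:
        raise KeyError(f"residue {chain_id}/{residue_number} not found")
    resname = next(iter(atoms.values())).residue_name
    if resname not in CHI_ATOMS:
        raise ValueError(f"no chi definition for residue type {resname!r}")
    chis: list[float | None] = []
    for quad in CHI_ATOMS[resname]:
        if all(name in atoms for name in quad):
            chis.append(dihedral(*(atoms[name].position for name in quad)))
        else:
            chis.append(None)
    return DihedralSet(
        chain_id=chain_id,
        residue_number=residue_number,
        residue_name=resname,
        chi=tuple(chis),
        label=s.label,
    )


def _circular_diff(a: float, b: float, period: float = 360.0) -> float:
    d = (a - b) % period
    return min(d, period - d)


def _bin_letter(chi: float) -> str:
    chi = wrap_angle(chi)
    if abs(chi) > 120.0:
        return "t"
    return "p" if chi > 0 else "m"


def assign_rotamer(d: DihedralSet, residue_type: str | None = None) -> RotamerAssignment:
    """Nearest canonical rotamer state for a full set of chi angles.

    chi1/chi2 select the p/t/m bin combination; among canonical states of
    that combination the one with the nearest terminal chi (on the circle,
    modulo 180° for symmetric carboxylates) is chosen.  A bin combination
    with no named state falls back to the globally nearest state, flagged.
    """
    resname = (residue_type or d.residue_name).upper()
    if resname not in CANONICAL_ROTAMERS:
        raise ValueError(f"no canonical rotamer table for residue type {resname!r}")
    if not d.defined:
        raise ValueError("cannot assign a rotamer with undefined chi angles")
    table = CANONICAL_ROTAMERS[resname]
    chi3_period = 180.0 if resname in SYMMETRIC_TERMINAL else 360.0

    def torus_distance(state_chis: tuple[float, ...]) -> float:
        d1 = _circular_diff(d.chi[0], state_chis[0])
        d2 = _circular_diff(d.chi[1], state_chis[1])
        d3 = _circular_diff(d.chi[2], state_chis[2], period=chi3_period)
        return float(np.sqrt(d1**2 + d2**2 + d3**2))

    bins = _bin_letter(d.chi[0]) + _bin_letter(d.chi[1])
    in_bin = {
        name: chis
        for name, chis in table.items()
        if _bin_letter(chis[0]) + _bin_letter(chis[1]) == bins
    }
    flagged = not in_bin
    candidates = in_bin if in_bin else table
    best = min(candidates.items(), key=lambda kv: torus_distance(kv[1]))
    name, chis = best
    return RotamerAssignment(
        state_name=name,
        chi_bins=bins,
        chi3_canonical=chis[2],
        distance=torus_distance(chis),
        flagged=flagged,
        label=d.label,
    )


def ensemble_rotamer_table(
    models: Sequence[Structure], chain_id: str, residue_number: int
) -> list[RotamerAssignment]:
    """Rotamer assignment of one residue across every model of an ensemble."""
    out = []
    for s in models:
        d = chi_angles(s, chain_id, residue_number)
        a = assign_rotamer(d)
        a.label = s.label
        out.append(a)
    return out


def torus_histogram(samples: Sequence[tuple[float, float]], n_bins: int = 72) -> TorusHistogram:
    """Normalized 2-D histogram of (chi1, chi2) samples on [0, 360)^2.

    Angles are wrapped periodically before binning, so samples straddling
    +-180° land in the correct bins.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise ValueError("no samples")
    arr = np.mod(arr, 360.0)
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    hist, _, _ = np.histogram2d(arr[:, 0], arr[:, 1], bins=[edges, edges])
    width = 360.0 / n_bins
    density = hist / (hist.sum() * width * width)
    return TorusHistogram(edges=edges, density=density)
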