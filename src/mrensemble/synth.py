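"""Synthetic study system: an idealized helical mini-protein, ensembles of
near-identical solutions, dihedral sample tables and simulated amplitudes.

The generator emulates the regime of a multi-start structure determination
of a small all-helical protein solved at ~2 Å: six solutions whose
backbones agree to ~0.1-0.25 Å all-atom RMSD but whose surface side chains
were solved in different rotamers, and observed amplitudes arising from a
population-weighted mixture of such conformers.

Everything is deterministic given (spec, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._geometry import place_atom
from .structure import Atom, Structure, UnitCell
from .rotamers import CANONICAL_ROTAMERS
from .sf import (
    ComplexSFSet,
    ReflectionSet,
    SymmetryOps,
    calc_structure_factors,
    ensemble_average_sf,
    generate_hkl,
    make_free_flags,
)

__all__ = [
    "EnsembleSpec",
    "DiffractionSpec",
    "Mode",
    "make_helix_protein",
    "make_solution_ensemble",
    "simulate_observed",
    "sample_dihedrals",
    "set_rotamer",
    "rotamer_flipped_conformers",
    "cell_for_structure",
    "DEFAULT_SEQUENCE",
]

# --------------------------------------------------------------------------
# amino-acid templates (ideal internal coordinates, Å / degrees)
# --------------------------------------------------------------------------

AA3 = {
    "A": "ALA", "G": "GLY", "S": "SER", "T": "THR", "V": "VAL", "L": "LEU",
    "I": "ILE", "N": "ASN", "D": "ASP", "Q": "GLN", "E": "GLU", "K": "LYS",
    "R": "ARG", "F": "PHE", "Y": "TYR",
}

# backbone ideal geometry
BB = {
    "N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231,
    "N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.8,
    "CA-CB": 1.530, "N-CA-CB": 109.5, "C-N-CA-CB": -120.0,  # L chirality
}

HELIX_PHI_PSI = (-57.0, -47.0)

# Side-chain z-matrix beyond CB.  Each entry:
#   (atom, element, (a, b, c), bond, angle, torsion)
# torsion is either a float (fixed) or ("chi", k, offset) meaning
# chi_k + offset degrees; chi indices are 1-based.
_SC = {
    "ALA": [],
    "GLY": [],
    "SER": [("OG", "O", ("N", "CA", "CB"), 1.428, 109.5, ("chi", 1, 0.0))],
    "THR": [
        ("OG1", "O", ("N", "CA", "CB"), 1.428, 109.5, ("chi", 1, 0.0)),
        ("CG2", "C", ("N", "CA", "CB"), 1.530, 109.5, ("chi", 1, -120.0)),
    ],
    "VAL": [
        ("CG1", "C", ("N", "CA", "CB"), 1.530, 109.5, ("chi", 1, 0.0)),
        ("CG2", "C", ("N", "CA", "CB"), 1.529, 109.5, ("chi", 1, 120.0)),
    ],
    "ILE": [
        ("CG1", "C", ("N", "CA", "CB"), 1.529, 109.5, ("chi", 1, 0.0)),
        ("CG2", "C", ("N", "CA", "CB"), 1.530, 109.5, ("chi", 1, -120.0)),
        ("CD1", "C", ("CA", "CB", "CG1"), 1.529, 109.5, ("chi", 2, 0.0)),
    ],
    "LEU": [
        ("CG", "C", ("N", "CA", "CB"), 1.530, 109.5, ("chi", 1, 0.0)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.530, 109.5, ("chi", 2, 0.0)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.529, 109.5, ("chi", 2, 120.0)),
    ],
    "ASP": [
        ("CG", "C", ("N", "CA", "CB"), 1.508, 109.5, ("chi", 1, 0.0)),
        ("OD1", "O", ("CA", "CB", "CG"), 1.230, 120.0, ("chi", 2, 0.0)),
        ("OD2", "O", ("CA", "CB", "CG"), 1.230, 120.0, ("chi", 2, 180.0)),
    ],
    "ASN": [
        ("CG", "C", ("N", "CA", "CB"), 1.507, 109.5, ("chi", 1, 0.0)),
        ("OD1", "O", ("CA", "CB", "CG"), 1.213, 120.0, ("chi", 2, 0.0)),
        ("ND2", "N", ("CA", "CB", "CG"), 1.348, 120.0, ("chi", 2, 180.0)),
    ],
    "GLU": [
        ("CG", "C", ("N", "CA", "CB"), 1.531, 109.4, ("chi", 1, 0.0)),
        ("CD", "C", ("CA", "CB", "CG"), 1.508, 109.4, ("chi", 2, 0.0)),
        ("OE1", "O", ("CB", "CG", "CD"), 1.230, 120.0, ("chi", 3, 0.0)),
        ("OE2", "O", ("CB", "CG", "CD"), 1.230, 120.0, ("chi", 3, 180.0)),
    ],
    "GLN": [
        ("CG", "C", ("N", "CA", "CB"), 1.528, 109.5, ("chi", 1, 0.0)),
        ("CD", "C", ("CA", "CB", "CG"), 1.507, 109.5, ("chi", 2, 0.0)),
        ("OE1", "O", ("CB", "CG", "CD"), 1.212, 120.0, ("chi", 3, 0.0)),
        ("NE2", "N", ("CB", "CG", "CD"), 1.347, 120.0, ("chi", 3, 180.0)),
    ],
    "LYS": [
        ("CG", "C", ("N", "CA", "CB"), 1.531, 109.4, ("chi", 1, 0.0)),
        ("CD", "C", ("CA", "CB", "CG"), 1.531, 109.4, ("chi", 2, 0.0)),
        ("CE", "C", ("CB", "CG", "CD"), 1.529, 109.5, ("chi", 3, 0.0)),
        ("NZ", "N", ("CG", "CD", "CE"), 1.469, 109.5, ("chi", 4, 0.0)),
    ],
    "ARG": [
        ("CG", "C", ("N", "CA", "CB"), 1.537, 114.5, ("chi", 1, 0.0)),
        ("CD", "C", ("CA", "CB", "CG"), 1.527, 112.4, ("chi", 2, 0.0)),
        ("NE", "N", ("CB", "CG", "CD"), 1.444, 111.0, ("chi", 3, 0.0)),
        ("CZ", "C", ("CG", "CD", "NE"), 1.406, 123.0, ("chi", 4, 0.0)),
        ("NH1", "N", ("CD", "NE", "CZ"), 1.391, 121.0, 180.0),
        ("NH2", "N", ("CD", "NE", "CZ"), 1.391, 119.8, 0.0),
    ],
    "PHE": [
        ("CG", "C", ("N", "CA", "CB"), 1.505, 109.5, ("chi", 1, 0.0)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.382, 120.0, ("chi", 2, 0.0)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.383, 120.0, ("chi", 2, 180.0)),
        ("CE1", "C", ("CB", "CG", "CD1"), 1.382, 120.0, 180.0),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.382, 120.0, 180.0),
        ("CZ", "C", ("CG", "CD1", "CE1"), 1.381, 120.0, 0.0),
    ],
    "TYR": [
        ("CG", "C", ("N", "CA", "CB"), 1.506, 109.5, ("chi", 1, 0.0)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.382, 119.9, ("chi", 2, 0.0)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.383, 119.9, ("chi", 2, 180.0)),
        ("CE1", "C", ("CB", "CG", "CD1"), 1.381, 120.1, 180.0),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.381, 120.0, 180.0),
        ("CZ", "C", ("CG", "CD1", "CE1"), 1.387, 120.0, 0.0),
        ("OH", "O", ("CD1", "CE1", "CZ"), 1.358, 120.1, 180.0),
    ],
}

#: Default chi angles used when a residue is first built (common helix
#: rotamers; glutamate defaults to the "tt 0°" state).
_DEFAULT_CHI = {
    "SER": (-65.0,),
    "THR": (-60.0,),
    "VAL": (175.0,),
    "ILE": (-65.0, 170.0),
    "LEU": (-65.0, 175.0),
    "ASP": (-70.0, -15.0),
    "ASN": (-65.0, -20.0),
    "GLU": (180.0, 180.0, 0.0),
    "GLN": (-65.0, 180.0, 0.0),
    "LYS": (-65.0, 180.0, 180.0, 180.0),
    "ARG": (-177.0, 180.0, -65.0, 90.0),
    "PHE": (-65.0, -30.0),
    "TYR": (-65.0, -30.0),
}

#: 58-residue all-helical default sequence.  Surface positions mirror the
#: residue types the consensus-set and rotamer analyses need: Ser2, Tyr12, Lys29,
#: Arg41, Asn43, Glu46, Arg49, Arg52, Glu53 (the dynamic surface glutamate),
#: Lys56 and Arg57.
DEFAULT_SEQUENCE = "DSELAKELAIVYLEKALQAVGDGSELAEKLIVEALQAFEKRGNGEELARLIRERLKRL"
# helices 1-20, 25-41, 45-58; loops 21-24 and 42-44

#: Loop backbone torsions producing compact chain reversals between the
#: helices (type-I'-like turns followed by a re-entry residue).
_LOOP4_TORSIONS = [(111.4, 103.8), (83.0, 10.6), (-8.8, 160.4), (-106.0, 105.9)]
_LOOP3_TORSIONS = [(109.7, 67.1), (-137.4, -162.8), (-91.3, 76.6)]


@dataclass
class Mode:
    """One programmed collective backbone mode."""

    kind: str  # "loop_shift" | "helix_translate"
    amplitude: float  # Å
    residue_range: tuple[int, int]

    def __post_init__(self) -> None:
        if self.kind not in ("loop_shift", "helix_translate"):
            raise ValueError(f"unknown mode kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("mode amplitude must be non-negative")


@dataclass
class EnsembleSpec:
    """Conditions under which a multi-start solution ensemble is emulated."""

    n_models: int = 6
    backbone_noise_sigma: float = 0.07  # per-coordinate Gaussian noise, Å
    programmed_modes: list[Mode] = field(default_factory=list)
    rotamer_plan: dict[int, list[str]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 2:
            raise ValueError("need at least two models")
        for resnum, states in self.rotamer_plan.items():
            if len(states) != self.n_models:
                raise ValueError(
                    f"rotamer plan for residue {resnum} lists {len(states)} states "
                    f"for {self.n_models} models"
                )


@dataclass
class DiffractionSpec:
    """Conditions for simulating observed amplitudes from a conformer mix."""

    weights: tuple[float, ...] = (0.5, 0.5)
    noise_fraction: float = 0.05
    d_min: float = 2.1
    free_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be non-negative and sum to 1")
        if self.noise_fraction < 0:
            raise ValueError("noise fraction must be non-negative")


def _segments(n_res: int) -> list[tuple[str, int, int]]:
    """(kind, first, last) 1-based segments of the chain layout."""
    if n_res < 40:
        return [("helix", 1, n_res)]
    return [
        ("helix", 1, 20),
        ("loop4", 21, 24),
        ("helix", 25, 41),
        ("loop3", 42, 44),
        ("helix", 45, n_res),
    ]


def _backbone_torsions(n_res: int) -> list[tuple[float, float]]:
    torsions: list[tuple[float, float]] = [None] * n_res
    for kind, first, last in _segments(n_res):
        if kind == "helix":
            for i in range(first, last + 1):
                torsions[i - 1] = HELIX_PHI_PSI
        else:
            table = _LOOP4_TORSIONS if kind == "loop4" else _LOOP3_TORSIONS
            for offset, i in enumerate(range(first, last + 1)):
                torsions[i - 1] = table[offset]
    return torsions


def _build_side_chain(
    resname: str,
    backbone: dict[str, np.ndarray],
    chi: Sequence[float] | None,
) -> list[tuple[str, str, np.ndarray]]:
    """Atom (name, element, position) list for a side chain beyond CA."""
    out: list[tuple[str, str, np.ndarray]] = []
    if resname == "GLY":
        return out
    pos = dict(backbone)
    cb = place_atom(pos["C"], pos["N"], pos["CA"], BB["CA-CB"], BB["N-CA-CB"], BB["C-N-CA-CB"])
    pos["CB"] = cb
    out.append(("CB", "C", cb))
    entries = _SC[resname]
    if chi is None:
        chi = _DEFAULT_CHI.get(resname, ())
    for name, element, parents, bond, ang, torsion in entries:
        if isinstance(torsion, tuple):
            _, k, offset = torsion
            if k > len(chi):
                raise ValueError(f"{resname} needs chi{k} but only {len(chi)} given")
            tor = chi[k - 1] + offset
        else:
            tor = torsion
        p = place_atom(pos[parents[0]], pos[parents[1]], pos[parents[2]], bond, ang, tor)
        pos[name] = p
        out.append((name, element, p))
    return out


def make_helix_protein(
    n_res: int = 58,
    sequence: str | None = None,
    chain_id: str = "A",
    label: str = "synthetic",
) -> Structure:
    """Idealized helical mini-protein built from internal coordinates.

    The backbone uses ideal helix torsions (phi, psi) = (-57, -47) within
    helices; for n_res >= 40 the chain is laid out as three helices joined
    by two reversing loops.  Side chains are built in common helix rotamers.
    """
    if n_res < 5:
        raise ValueError("need at least 5 residues")
    if sequence is None:
        if n_res == len(DEFAULT_SEQUENCE):
            sequence = DEFAULT_SEQUENCE
        else:
            sequence = ("AEALKA" * (n_res // 6 + 1))[:n_res]
    if len(sequence) != n_res:
        raise ValueError("sequence length does not match n_res")
    for letter in sequence:
        if letter not in AA3:
            raise ValueError(f"unsupported residue letter {letter!r}")

    torsions = _backbone_torsions(n_res)
    atoms: list[Atom] = []

    # first residue backbone in a fixed frame
    n0 = np.zeros(3)
    ca0 = np.array([BB["N-CA"], 0.0, 0.0])
    ang = np.radians(180.0 - BB["N-CA-C"])
    c0 = ca0 + BB["CA-C"] * np.array([np.cos(ang), np.sin(ang), 0.0])
    bb_n, bb_ca, bb_c = [n0], [ca0], [c0]
    for i in range(1, n_res):
        psi_prev = torsions[i - 1][1]
        phi = torsions[i][0]
        n_i = place_atom(bb_n[-1], bb_ca[-1], bb_c[-1], BB["C-N"], BB["CA-C-N"], psi_prev)
        ca_i = place_atom(bb_ca[-1], bb_c[-1], n_i, BB["N-CA"], BB["C-N-CA"], 180.0)
        c_i = place_atom(bb_c[-1], n_i, ca_i, BB["CA-C"], BB["N-CA-C"], phi)
        bb_n.append(n_i)
        bb_ca.append(ca_i)
        bb_c.append(c_i)

    for i in range(n_res):
        resname = AA3[sequence[i]]
        resnum = i + 1
        backbone = {"N": bb_n[i], "CA": bb_ca[i], "C": bb_c[i]}
        o_pos = place_atom(bb_n[i], bb_ca[i], bb_c[i], BB["C-O"], BB["CA-C-O"], torsions[i][1] + 180.0)
        for name, element, p in [("N", "N", bb_n[i]), ("CA", "C", bb_ca[i]), ("C", "C", bb_c[i]), ("O", "O", o_pos)]:
            atoms.append(Atom(chain_id, resnum, resname, name, element, p, b_factor=15.0))
        for name, element, p in _build_side_chain(resname, backbone, None):
            atoms.append(Atom(chain_id, resnum, resname, name, element, p, b_factor=15.0))
    return Structure(atoms=atoms, label=label)


def set_rotamer(
    s: Structure,
    residue_number: int,
    state: str | Sequence[float],
    chain_id: str = "A",
    clash_tolerance: float = 2.0,
) -> bool:
    """Rebuild one side chain into a named canonical rotamer state (or an
    explicit chi tuple), in place.

    Returns True if the rebuilt side chain clashes (non-bonded contact
    below ``clash_tolerance`` Å) with the rest of the model; a clash is
    reported with a warning but is not fatal.
    """
    res_atoms = [a for a in s.atoms if a.chain_id == chain_id and a.residue_number == residue_number]
    if not res_atoms:
        raise KeyError(f"residue {chain_id}/{residue_number} not found")
    resname = res_atoms[0].residue_name
    if isinstance(state, str):
        try:
            chi = CANONICAL_ROTAMERS[resname][state]
        except KeyError:
            raise ValueError(f"no canonical state {state!r} for {resname}") from None
    else:
        chi = tuple(state)
    amap = {a.atom_name: a for a in res_atoms}
    backbone = {n: amap[n].position for n in ("N", "CA", "C")}
    rebuilt = _build_side_chain(resname, backbone, chi)
    new_pos = {name: p for name, _el, p in rebuilt}
    moved = []
    for a in res_atoms:
        if a.atom_name in new_pos:
            a.position = new_pos[a.atom_name]
            if a.atom_name not in ("CB",):
                moved.append(a)
    clash = False
    exclude = {(chain_id, residue_number)}
    for a in moved:
        for b in s.atoms:
            if (b.chain_id, b.residue_number) in exclude:
                continue
            if np.linalg.norm(a.position - b.position) < clash_tolerance:
                clash = True
                break
        if clash:
            break
    if clash:
        warnings.warn(
            f"rotamer rebuild of {resname}{residue_number} -> {state} clashes "
            f"with a neighbouring residue (closer than {clash_tolerance} Å)",
            stacklevel=2,
        )
    return clash


def _helix_axis(ca: np.ndarray) -> np.ndarray:
    """Dominant direction of a run of CA atoms (unit vector)."""
    centered = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    # orient along increasing residue index
    if np.dot(ca[-1] - ca[0], axis) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _mode_displacement(base: Structure, mode: Mode) -> np.ndarray:
    """(n_atoms, 3) unit-amplitude displacement field of one mode."""
    coords = base.coords()
    resnums = np.array([a.residue_number for a in base.atoms])
    first, last = mode.residue_range
    in_range = (resnums >= first) & (resnums <= last)
    disp = np.zeros_like(coords)
    if mode.kind == "helix_translate":
        ca = np.array([a.position for a in base.atoms if a.atom_name == "CA" and first <= a.residue_number <= last])
        axis = _helix_axis(ca)
        # translate perpendicular to the helix axis (a positional shift of
        # the helix within the bundle), direction chosen deterministically
        perp = np.cross(axis, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(axis, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        disp[in_range] = perp
    else:  # loop_shift: hinge-like bump, peaked at the window centre
        centroid_all = coords.mean(axis=0)
        loop_atoms = coords[in_range]
        outward = loop_atoms.mean(axis=0) - centroid_all
        outward /= np.linalg.norm(outward)
        span = max(last - first, 1)
        for idx in np.where(in_range)[0]:
            t = (resnums[idx] - first) / span  # 0..1 across the window
            weight = np.sin(np.pi * t) if span > 1 else 1.0
            disp[idx] = weight * outward
    return disp


def make_solution_ensemble(base: Structure, spec: EnsembleSpec) -> list[Structure]:
    """Ensemble of near-identical copies of ``base``.

    Per model: programmed collective modes with random coefficients in
    [-amplitude, amplitude], iid Gaussian coordinate noise, then side
    chains listed in the rotamer plan rebuilt into their per-model states.
    """
    rng = np.random.default_rng(spec.seed)
    mode_fields = [_mode_displacement(base, m) for m in spec.programmed_modes]
    models: list[Structure] = []
    for i in range(spec.n_models):
        s = base.copy(label=f"model_{i + 1}")
        coords = s.coords()
        for mode, disp in zip(spec.programmed_modes, mode_fields):
            coeff = rng.uniform(-1.0, 1.0) * mode.amplitude
            coords = coords + coeff * disp
        coords = coords + rng.normal(0.0, spec.backbone_noise_sigma, coords.shape)
        for a, p in zip(s.atoms, coords):
            a.position = p
        for resnum in sorted(spec.rotamer_plan):
            set_rotamer(s, resnum, spec.rotamer_plan[resnum][i])
        models.append(s)
    return models


#: Side-chain flips distinguishing the two crystal conformers of the
#: simulated mixture: the dynamic surface glutamate plus two long basic
#: side chains, mirroring solutions that differ at several surface sites.
CONFORMER_FLIPS: tuple[tuple[int, str | tuple[float, ...]], ...] = (
    (53, "mm-40°"),  # Glu53 tt 0° -> mm-40°
    (29, (-177.0, 180.0, 180.0, 180.0)),  # Lys29 chi1 m -> t
    (49, (-177.0, 180.0, -65.0, -90.0)),  # Arg49 chi4 flip
)


def rotamer_flipped_conformers(base: Structure) -> tuple[Structure, Structure]:
    """The canonical two-conformer pair used for mixture simulations.

    Conformer A is ``base`` itself; conformer B has the three surface side
    chains of :data:`CONFORMER_FLIPS` rebuilt into alternative rotamers.
    """
    conf_a = base.copy(label="conformer_a")
    conf_b = base.copy(label="conformer_b")
    for resnum, state in CONFORMER_FLIPS:
        set_rotamer(conf_b, resnum, state)
    return conf_a, conf_b


def cell_for_structure(s: Structure, padding: float = 5.0) -> UnitCell:
    """Orthogonal P1-style box enclosing the molecule with padding."""
    xyz = s.coords()
    extent = xyz.max(axis=0) - xyz.min(axis=0)
    dims = extent + 2.0 * padding
    return UnitCell(float(dims[0]), float(dims[1]), float(dims[2]))


def simulate_observed(
    conformers: Sequence[Structure],
    cell: UnitCell,
    ops: SymmetryOps,
    spec: DiffractionSpec,
) -> ReflectionSet:
    """Observed amplitudes from a population-weighted conformer mixture.

    The true structure factors are the complex weighted average of the
    per-conformer structure factors; amplitudes get relative Gaussian
    noise and a seeded cross-validation flag set.
    """
    if len(conformers) != len(spec.weights):
        raise ValueError("one weight per conformer required")
    hkl = generate_hkl(cell, spec.d_min)
    sets = [calc_structure_factors(c, cell, ops, spec.d_min, hkl=hkl) for c in conformers]
    f_true = ensemble_average_sf(sets, list(spec.weights))
    amp = np.abs(f_true.values)
    rng = np.random.default_rng(spec.seed)
    eps = rng.normal(0.0, spec.noise_fraction, len(amp)) if spec.noise_fraction > 0 else np.zeros(len(amp))
    f_obs = np.clip(amp * (1.0 + eps), 0.0, None)
    sigma = np.maximum(spec.noise_fraction, 1e-6) * amp
    refs = ReflectionSet(
        hkl=hkl,
        f_obs=f_obs,
        sigma=sigma,
        free_flag=np.zeros(len(amp), dtype=bool),
        cell=cell,
        symmetry=ops,
        d_min=spec.d_min,
    )
    return make_free_flags(refs, spec.free_fraction, seed=spec.seed + 1)


def sample_dihedrals(
    states: Sequence[tuple[float, float, float]],
    wrap_sigma: float,
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """(n, 2) samples of (chi1, chi2) from a wrapped-normal mixture.

    ``states`` lists (chi1 centre, chi2 centre, weight); weights must sum
    to 1.  Output angles are in [0, 360).
    """
    weights = np.array([w for _, _, w in states], float)
    if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
        raise ValueError("state weights must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    which = rng.choice(len(states), size=n, p=weights)
    centers = np.array([(c1, c2) for c1, c2, _ in states], float)
    samples = centers[which] + rng.normal(0.0, wrap_sigma, size=(n, 2))
    return np.mod(samples, 360.0)
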