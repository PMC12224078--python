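"""Search-model preparation for molecular replacement.

Predicted models arrive with a confidence score per atom — either a pLDDT
(0-100, higher is better, often stored in the B-factor column) or an
estimated coordinate error in Å (lower is better).  Before a model is used
as an MR search model, low-confidence atoms are trimmed and the B-factor
column is filled by one of three protocols:

``constant``
    every atom gets the same B (the specific value is immaterial to the
    subsequent MR likelihood scoring);
``asa_based``
    B grows monotonically with the atom's solvent-accessible surface area,
    so flexible surface atoms are down-weighted;
``confidence_based``
    the pLDDT is mapped to an estimated coordinate error ``err`` and then
    to ``B = (8*pi^2/3) * err^2`` (the isotropic displacement equivalent
    of a Gaussian positional error), after trimming at the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structure import Atom, Structure

__all__ = [
    "BProtocol",
    "TrimReport",
    "trim_by_confidence",
    "shrake_rupley_asa",
    "assign_bfactors",
    "plddt_to_error",
    "VDW_RADII",
]

#: Van der Waals radii (Å) used for accessibility calculations.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "Se": 1.90,
}

B_FROM_ERR = 8.0 * math.pi**2 / 3.0  # B = (8 pi^2 / 3) err^2


@dataclass
class BProtocol:
    """Parameters of one B-factor assignment protocol."""

    kind: str  # "constant" | "asa_based" | "confidence_based"
    constant_value: float = 20.0
    trim_threshold: float = 70.0
    # asa map: B = asa_b_min + asa_b_range * (ASA / ASA_isolated), clamped
    asa_b_min: float = 5.0
    asa_b_range: float = 25.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "asa_based", "confidence_based"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.kind == "constant" and self.constant_value <= 0:
            raise ValueError("constant B must be positive")
        if self.kind == "confidence_based" and not 0 < self.trim_threshold <= 100:
            raise ValueError("pLDDT trim threshold must lie in (0, 100]")


@dataclass
class TrimReport:
    """What was removed by confidence trimming."""

    removed_atoms: list[tuple[str, int, str, str]] = field(default_factory=list)
    removed_residues: list[tuple[str, int, str]] = field(default_factory=list)

    def to_rows(self) -> list[dict]:
        rows = [
            {"chain": c, "residue_number": n, "residue_name": rn, "atom_name": an}
            for (c, n, rn, an) in self.removed_atoms
        ]
        rows += [
            {"chain": c, "residue_number": n, "residue_name": rn, "atom_name": "*"}
            for (c, n, rn) in self.removed_residues
        ]
        return rows


def plddt_to_error(plddt: float | np.ndarray) -> float | np.ndarray:
    """Monotone decreasing map from pLDDT to estimated coordinate error (Å).

    ``err = 1.5 * exp(4 * (0.7 - pLDDT/100))`` clamped to [0.1, 10] Å: an
    atom at the conventional pLDDT = 70 confidence cut-off is assigned a
    1.5 Å error.  This default is deliberately simple and replaceable.
    """
    err = 1.5 * np.exp(4.0 * (0.7 - np.asarray(plddt, float) / 100.0))
    out = np.clip(err, 0.1, 10.0)
    return float(out) if np.ndim(plddt) == 0 else out


def _check_confidence(s: Structure) -> str:
    kinds = {a.confidence_kind for a in s.atoms}
    if None in kinds or len(kinds) != 1:
        raise ValueError(
            "every atom must carry a confidence score of a single kind "
            f"(found kinds: {sorted(str(k) for k in kinds)})"
        )
    (kind,) = kinds
    if kind not in ("plddt", "error_angstrom"):
        raise ValueError(f"unknown confidence kind {kind!r}")
    return kind


def _is_low_confidence(a: Atom, kind: str, threshold: float) -> bool:
    if kind == "plddt":
        return a.confidence < threshold
    return a.confidence > threshold  # coordinate error: larger is worse


def trim_by_confidence(
    s: Structure,
    threshold: float,
    granularity: str | None = None,
) -> tuple[Structure, TrimReport]:
    """Remove low-confidence atoms or whole residues.

    For pLDDT scores the default granularity is ``atom`` (single poorly
    predicted side-chain tips get deleted); for coordinate-error scores it
    is ``residue`` (whole low-confidence termini get deleted).
    """
    kind = _check_confidence(s)
    if granularity is None:
        granularity = "atom" if kind == "plddt" else "residue"
    if granularity not in ("atom", "residue"):
        raise ValueError(f"granularity must be 'atom' or 'residue', got {granularity!r}")
    if kind == "plddt" and not 0 < threshold <= 100:
        raise ValueError("pLDDT threshold must lie in (0, 100]")
    if kind == "error_angstrom" and threshold <= 0:
        raise ValueError("coordinate-error threshold must be positive")

    report = TrimReport()
    if granularity == "atom":
        kept = []
        for a in s.atoms:
            if _is_low_confidence(a, kind, threshold):
                report.removed_atoms.append((a.chain_id, a.residue_number, a.residue_name, a.atom_name))
            else:
                kept.append(a.copy())
    else:
        bad_residues = set()
        resname: dict[tuple[str, int], str] = {}
        for a in s.atoms:
            resname[(a.chain_id, a.residue_number)] = a.residue_name
            if _is_low_confidence(a, kind, threshold):
                bad_residues.add((a.chain_id, a.residue_number))
        for c, n in sorted(bad_residues):
            report.removed_residues.append((c, n, resname[(c, n)]))
        kept = [a.copy() for a in s.atoms if (a.chain_id, a.residue_number) not in bad_residues]

    out = Structure(atoms=kept, cell=s.cell, symmetry=s.symmetry, label=s.label)
    return out, report


def _sphere_points(n: int) -> np.ndarray:
    """Nearly uniform points on the unit sphere (Fibonacci lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def shrake_rupley_asa(
    s: Structure, probe_radius: float = 1.4, n_points: int = 960
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²) by the rolling-probe
    point-sampling method of Shrake & Rupley.

    Each atom is expanded by the probe radius and sampled with ``n_points``
    quasi-uniform surface points; the accessible fraction is the fraction
    of points not inside any neighbouring expanded sphere.
    """
    if len(s) == 0:
        return np.zeros(0)
    try:
        radii = np.array([VDW_RADII[a.element] for a in s.atoms])
    except KeyError as exc:
        raise ValueError(f"no van der Waals radius for element {exc.args[0]!r}") from None
    xyz = s.coords()
    ext = radii + probe_radius
    unit = _sphere_points(n_points)

    from scipy.spatial import cKDTree

    tree = cKDTree(xyz)
    max_reach = 2.0 * ext.max()
    asa = np.zeros(len(s))
    for i in range(len(s)):
        pts = xyz[i] + ext[i] * unit
        neighbours = [j for j in tree.query_ball_point(xyz[i], max_reach) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            accessible &= d2 > ext[j] ** 2
        asa[i] = 4.0 * np.pi * ext[i] ** 2 * accessible.mean()
    return asa


def assign_bfactors(s: Structure, protocol: BProtocol) -> Structure:
    """Return a copy of ``s`` with B factors set by ``protocol``.

    Coordinates and atom identities are never modified; the
    ``confidence_based`` protocol first trims atoms below the threshold.
    """
    if protocol.kind == "constant":
        out = s.copy()
        for a in out.atoms:
            a.b_factor = protocol.constant_value
        return out

    if protocol.kind == "asa_based":
        out = s.copy()
        asa = shrake_rupley_asa(out)
        for a, area in zip(out.atoms, asa):
            iso = 4.0 * np.pi * (VDW_RADII[a.element] + 1.4) ** 2
            frac = min(area / iso, 1.0)
            a.b_factor = protocol.asa_b_min + protocol.asa_b_range * frac
        return out

    # confidence_based
    kind = _check_confidence(s)
    if kind != "plddt":
        raise ValueError("confidence_based protocol requires pLDDT confidences")
    trimmed, _ = trim_by_confidence(s, protocol.trim_threshold, granularity="atom")
    for a in trimmed.atoms:
        err = plddt_to_error(a.confidence)
        a.b_factor = B_FROM_ERR * err**2
    return trimmed
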