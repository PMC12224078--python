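"""Rigid-body superposition and ensemble comparison metrics.

Three complementary metrics quantify how similar two models of the same
protein are on a shared atom selection:

* pairwise RMSD after least-squares (Kabsch) superposition — global,
  dominated by the largest deviations;
* GDT-HA — the mean fraction of atoms within {0.5, 1, 2, 4} Å of the
  reference under the best superposition found, times 100; robust to a few
  badly placed atoms;
* lDDT — superposition-free preservation of local inter-atomic distances,
  insensitive to rigid movements of whole segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structure import ConsensusSet, Structure

__all__ = [
    "SuperpositionResult",
    "RMSDMatrix",
    "kabsch_superpose",
    "rmsd",
    "rmsd_matrix",
    "gdt_ha",
    "lddt",
]

GDT_HA_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)
LDDT_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # applied after rotation
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class RMSDMatrix:
    labels: list[str]
    values: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(np.round(self.values, 2), index=self.labels, columns=self.labels)


def _check_selection(coords: np.ndarray) -> None:
    if len(coords) < 3:
        raise ValueError("need at least 3 atoms for superposition")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear or coincident) atom selection")


def _kabsch(mobile_xyz: np.ndarray, ref_xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation/translation of mobile onto reference."""
    mc = mobile_xyz.mean(axis=0)
    rc = ref_xyz.mean(axis=0)
    p = mobile_xyz - mc
    q = ref_xyz - rc
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])  # reflection correction
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    moved = mobile_xyz @ rot.T + trans
    value = float(np.sqrt(np.mean(np.sum((moved - ref_xyz) ** 2, axis=1))))
    return rot, trans, value


def kabsch_superpose(
    mobile: Structure, reference: Structure, selection: ConsensusSet
) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of ``mobile`` onto
    ``reference`` over ``selection``."""
    mx = mobile.coords(selection.keys)
    rx = reference.coords(selection.keys)
    _check_selection(mx)
    _check_selection(rx)
    rot, trans, value = _kabsch(mx, rx)
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=value, n_atoms=len(mx))


def rmsd(
    a: Structure, b: Structure, selection: ConsensusSet, fit: bool = True
) -> float:
    """RMSD between two structures over a selection, optionally after an
    optimal rigid fit."""
    ax = a.coords(selection.keys)
    bx = b.coords(selection.keys)
    if fit:
        return kabsch_superpose(a, b, selection).rmsd
    return float(np.sqrt(np.mean(np.sum((ax - bx) ** 2, axis=1))))


def rmsd_matrix(models: Sequence[Structure], selection: ConsensusSet) -> RMSDMatrix:
    """Symmetric matrix of all pairwise fitted RMSDs."""
    if len(models) < 2:
        raise ValueError("need at least two models")
    n = len(models)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = rmsd(models[i], models[j], selection, fit=True)
    labels = [m.label or f"model{i}" for i, m in enumerate(models)]
    return RMSDMatrix(labels=labels, values=values)


def _fragment_seeds(n: int, min_len: int = 3) -> list[tuple[int, int]]:
    """All contiguous index windows of length >= min_len, plus the full range."""
    seeds = [(i, j) for i in range(n) for j in range(i + min_len, n + 1)]
    return seeds


def gdt_ha(
    model: Structure,
    reference: Structure,
    selection: ConsensusSet,
    ca_only: bool = True,
) -> float:
    """GDT-HA score in [0, 100].

    The optimal-superposition search is approximated by seeding Kabsch fits
    from every contiguous fragment of at least 3 selected atoms (in
    selection order) and, per distance threshold, keeping the best fraction
    found over all seeds.  For near-identical structures this matches the
    exhaustive search; it is not the full LGA algorithm.
    """
    sel = selection.ca_only() if ca_only else selection
    mx = model.coords(sel.keys)
    rx = reference.coords(sel.keys)
    _check_selection(mx)
    n = len(mx)
    best = {t: 0.0 for t in GDT_HA_THRESHOLDS}
    for i, j in _fragment_seeds(n):
        frag_m = mx[i:j]
        centered = frag_m - frag_m.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
            continue
        rot, trans, _ = _kabsch(frag_m, rx[i:j])
        moved = mx @ rot.T + trans
        dist = np.linalg.norm(moved - rx, axis=1)
        for t in GDT_HA_THRESHOLDS:
            frac = float(np.mean(dist < t + 1e-12))
            if frac > best[t]:
                best[t] = frac
    return 100.0 * sum(best.values()) / len(GDT_HA_THRESHOLDS)


def lddt(
    model: Structure,
    reference: Structure,
    selection: ConsensusSet,
    inclusion_radius: float = 15.0,
    thresholds: Sequence[float] = LDDT_THRESHOLDS,
) -> float:
    """Local distance difference test score in [0, 1].

    Superposition-free: over all pairs of selected atoms belonging to
    different residues whose *reference* distance is below the inclusion
    radius, the score is the mean over thresholds of the fraction of pairs
    whose distance change stays below the threshold.
    """
    keys = selection.keys
    mx = model.coords(keys)
    rx = reference.coords(keys)
    res_id = np.array([hash((k[0], k[1])) for k in keys])

    diff_res = res_id[:, None] != res_id[None, :]
    dref = np.linalg.norm(rx[:, None, :] - rx[None, :, :], axis=-1)
    dmod = np.linalg.norm(mx[:, None, :] - mx[None, :, :], axis=-1)
    iu = np.triu_indices(len(keys), k=1)
    mask = diff_res[iu] & (dref[iu] < inclusion_radius)
    if not np.any(mask):
        raise ValueError("no atom pairs qualify within the inclusion radius")
    delta = np.abs(dmod[iu][mask] - dref[iu][mask])
    fractions = [float(np.mean(delta < t)) for t in thresholds]
    return float(np.mean(fractions))
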