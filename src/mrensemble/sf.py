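"""Direct-summation structure factors, R factors and ensemble averaging.

This is a deliberately small crystallographic engine sufficient to study
the *ensemble* effect: complex model structure factors from several
near-identical conformers are averaged per reflection before amplitudes
are compared with observed data.  When the crystal truly contains a
mixture of conformations, the averaged ensemble gives lower R_work/R_free
than any single conformer.

For each reflection with d >= d_min,

    F(hkl) = sum_ops sum_atoms occ * f_elem(s) * exp(-B s^2 / 4)
             * exp(2 pi i h . (R x_frac + t)),       s = 1/d,

with 4-Gaussian X-ray scattering factors.  No bulk-solvent model, no
anisotropic scaling, no twinning: absolute R values from this engine are
not comparable to values from full refinement programs, but differences
between models on the same data are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .structure import Structure, UnitCell

__all__ = [
    "SymmetryOps",
    "ReflectionSet",
    "ComplexSFSet",
    "RFactorReport",
    "P1",
    "P212121",
    "generate_hkl",
    "calc_structure_factors",
    "ensemble_average_sf",
    "scale_and_rfactor",
    "make_free_flags",
    "fit_mixture_weight",
    "read_reflections",
    "write_reflections",
]


@dataclass
class SymmetryOps:
    """Symmetry operators as (rotation, translation) pairs in fractional
    space, constructed from triplet strings like ``-X,Y+1/2,-Z``."""

    triplets: list[str]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.triplets:
            raise ValueError("need at least the identity operator")
        self._parsed = [_parse_triplet(t) for t in self.triplets]
        if not any(
            np.array_equal(r, np.eye(3)) and np.allclose(tr % 1.0, 0.0)
            for r, tr in self._parsed
        ):
            raise ValueError("identity operator missing")

    def __len__(self) -> int:
        return len(self._parsed)

    def matrices(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(r.copy(), t.copy()) for r, t in self._parsed]


def _parse_triplet(triplet: str) -> tuple[np.ndarray, np.ndarray]:
    import gemmi

    op = gemmi.Op(triplet.lower())
    rot = np.array(op.rot, dtype=float) / gemmi.Op.DEN
    tran = np.array(op.tran, dtype=float) / gemmi.Op.DEN
    return rot, tran


P1 = SymmetryOps(["x,y,z"], name="P 1")
P212121 = SymmetryOps(
    ["x,y,z", "x+1/2,-y+1/2,-z", "-x,y+1/2,-z+1/2", "-x+1/2,-y,z+1/2"],
    name="P 21 21 21",
)


@dataclass
class ReflectionSet:
    """Indexed observed amplitudes with sigmas and free flags."""

    hkl: np.ndarray  # (n, 3) int
    f_obs: np.ndarray  # (n,) >= 0
    sigma: np.ndarray  # (n,)
    free_flag: np.ndarray  # (n,) bool
    cell: UnitCell
    symmetry: SymmetryOps
    d_min: float
    d_max: float | None = None

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int)
        self.f_obs = np.asarray(self.f_obs, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.free_flag = np.asarray(self.free_flag, dtype=bool)
        if np.any(self.f_obs < 0):
            raise ValueError("observed amplitudes must be non-negative")
        uniq = {tuple(h) for h in self.hkl}
        if len(uniq) != len(self.hkl):
            raise ValueError("duplicate hkl indices")

    def __len__(self) -> int:
        return len(self.hkl)

    def d_spacings(self) -> np.ndarray:
        return _d_spacings(self.cell, self.hkl)


@dataclass
class ComplexSFSet:
    """Complex model structure factors on an hkl list."""

    hkl: np.ndarray  # (n, 3) int
    values: np.ndarray  # (n,) complex

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int)
        self.values = np.asarray(self.values, dtype=complex)
        if len(self.hkl) != len(self.values):
            raise ValueError("hkl/value length mismatch")

    def __len__(self) -> int:
        return len(self.hkl)

    def amplitudes(self) -> np.ndarray:
        return np.abs(self.values)


@dataclass
class RFactorReport:
    scale: float
    r_work: float
    r_free: float
    n_work: int
    n_free: int


def _d_spacings(cell: UnitCell, hkl: np.ndarray) -> np.ndarray:
    frac = cell.frac_matrix()
    gstar = frac @ frac.T  # reciprocal metric tensor
    h = np.asarray(hkl, dtype=float)
    s2 = np.einsum("ni,ij,nj->n", h, gstar, h)
    with np.errstate(divide="ignore"):
        return 1.0 / np.sqrt(s2)


def generate_hkl(cell: UnitCell, d_min: float, d_max: float | None = None) -> np.ndarray:
    """Friedel-unique reflection indices with d >= d_min.

    The full index box is enumerated and one mate of each Friedel pair is
    kept (the one whose first nonzero index is positive); (0,0,0) is
    excluded.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    hmax = int(np.floor(cell.a / d_min)) + 1
    kmax = int(np.floor(cell.b / d_min)) + 1
    lmax = int(np.floor(cell.c / d_min)) + 1
    h, k, l = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    nonzero = np.any(hkl != 0, axis=1)
    hkl = hkl[nonzero]
    # Friedel-unique: first nonzero index positive
    lead = np.where(hkl[:, 0] != 0, hkl[:, 0], np.where(hkl[:, 1] != 0, hkl[:, 1], hkl[:, 2]))
    hkl = hkl[lead > 0]
    d = _d_spacings(cell, hkl)
    keep = d >= d_min
    if d_max is not None:
        keep &= d <= d_max
    hkl = hkl[keep]
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0]))
    return hkl[order]


def _scattering_factors(element: str, stol2: np.ndarray) -> np.ndarray:
    """4-Gaussian X-ray form factors f(sin(theta)/lambda squared)."""
    import gemmi

    el = gemmi.Element(element)
    it92 = el.it92
    if it92 is None:
        raise ValueError(f"no scattering coefficients for element {element!r}")
    coefs = it92.get_coefs()  # [a1..a4, b1..b4, c]
    a = np.array(coefs[0:4])
    b = np.array(coefs[4:8])
    c = coefs[8]
    return c + np.sum(a[None, :] * np.exp(-b[None, :] * stol2[:, None]), axis=1)


def calc_structure_factors(
    s: Structure,
    cell: UnitCell,
    ops: SymmetryOps,
    d_min: float,
    hkl: np.ndarray | None = None,
) -> ComplexSFSet:
    """Direct-summation complex structure factors for every reflection with
    d >= d_min (or an explicit ``hkl`` list)."""
    if len(s) == 0:
        raise ValueError("empty structure")
    if hkl is None:
        hkl = generate_hkl(cell, d_min)
    hkl = np.asarray(hkl, dtype=int)
    d = _d_spacings(cell, hkl)
    s2 = 1.0 / d**2
    stol2 = s2 / 4.0

    elements = [a.element for a in s.atoms]
    occ = np.array([a.occupancy for a in s.atoms])
    b_iso = np.array([a.b_factor for a in s.atoms])
    frac = cell.frac_matrix()
    x_frac = s.coords() @ frac.T  # (n_atoms, 3)

    values = np.zeros(len(hkl), dtype=complex)
    hf = hkl.astype(float)
    sym_xp = [x_frac @ rot.T + tran for rot, tran in ops.matrices()]
    chunk = 8192  # bound the (n_hkl x n_atoms) temporaries
    for start in range(0, len(hkl), chunk):
        sl = slice(start, start + chunk)
        f_elem = np.empty((hf[sl].shape[0], len(s)))
        for el in set(elements):
            col = np.array([e == el for e in elements])
            f_elem[:, col] = _scattering_factors(el, stol2[sl])[:, None]
        weights = occ[None, :] * f_elem * np.exp(-b_iso[None, :] * s2[sl, None] / 4.0)
        for xp in sym_xp:
            phase = np.exp(2j * np.pi * (hf[sl] @ xp.T))
            values[sl] += np.sum(weights * phase, axis=1)
    return ComplexSFSet(hkl=hkl, values=values)


def ensemble_average_sf(
    sets: Sequence[ComplexSFSet], weights: Sequence[float] | None = None
) -> ComplexSFSet:
    """Population-weighted *complex* average of model structure factors.

    Averaging complex values (not amplitudes) is what models a crystal
    whose unit cells contain a mixture of conformers: interference between
    conformer contributions is retained.
    """
    if not sets:
        raise ValueError("no structure-factor sets")
    if weights is None:
        weights = [1.0 / len(sets)] * len(sets)
    w = np.asarray(weights, dtype=float)
    if len(w) != len(sets):
        raise ValueError("one weight per set required")
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must be non-negative and sum to 1")
    ref = sets[0].hkl
    for other in sets[1:]:
        if other.hkl.shape != ref.shape or np.any(other.hkl != ref):
            raise ValueError("structure-factor sets are indexed differently")
    values = np.zeros(len(ref), dtype=complex)
    for wi, si in zip(w, sets):
        values += wi * si.values
    return ComplexSFSet(hkl=ref.copy(), values=values)


def _match(fc: ComplexSFSet, obs: ReflectionSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    index = {tuple(h): i for i, h in enumerate(fc.hkl)}
    rows_obs, rows_fc = [], []
    for i, h in enumerate(obs.hkl):
        j = index.get(tuple(h))
        if j is not None:
            rows_obs.append(i)
            rows_fc.append(j)
    if not rows_obs:
        raise ValueError("no common reflections between model and observations")
    rows_obs = np.array(rows_obs)
    rows_fc = np.array(rows_fc)
    return obs.f_obs[rows_obs], np.abs(fc.values[rows_fc]), obs.free_flag[rows_obs]


def scale_and_rfactor(fc: ComplexSFSet, obs: ReflectionSet) -> RFactorReport:
    """Least-squares scale on the working set, then R_work and R_free.

    ``k = argmin sum_work (|Fo| - k |Fc|)^2`` has the closed form
    ``k = sum |Fo||Fc| / sum |Fc|^2``; R = sum ||Fo| - k|Fc|| / sum |Fo|
    computed separately over working and free reflections.
    """
    fo, fcalc, free = _match(fc, obs)
    work = ~free
    if not np.any(work) or not np.any(free):
        raise ValueError("both working and free subsets must be nonempty")
    k = float(np.sum(fo[work] * fcalc[work]) / np.sum(fcalc[work] ** 2))

    def r(mask: np.ndarray) -> float:
        return float(np.sum(np.abs(fo[mask] - k * fcalc[mask])) / np.sum(fo[mask]))

    return RFactorReport(
        scale=k,
        r_work=r(work),
        r_free=r(free),
        n_work=int(work.sum()),
        n_free=int(free.sum()),
    )


def make_free_flags(refs: ReflectionSet, fraction: float = 0.05, seed: int = 0) -> ReflectionSet:
    """Deterministically flag approximately ``fraction`` of reflections as
    the cross-validation (free) set."""
    if not 0.0 < fraction < 0.5:
        raise ValueError("free fraction must lie in (0, 0.5)")
    rng = np.random.default_rng(seed)
    flags = rng.random(len(refs)) < fraction
    if not flags.any():
        flags[rng.integers(len(refs))] = True
    return replace(refs, free_flag=flags)


def fit_mixture_weight(
    fc_list: Sequence[ComplexSFSet],
    obs: ReflectionSet,
    grid_step: float = 0.01,
) -> tuple[tuple[float, float], RFactorReport]:
    """Grid search for the two-conformer population weight minimizing R_work.

    Returns ``((w, 1-w), report)`` for the best grid point.  Only the
    two-conformer case is supported; more conformers would need a simplex
    grid.
    """
    if len(fc_list) != 2:
        raise ValueError("fit_mixture_weight supports exactly two conformers")
    best: tuple[float, RFactorReport] | None = None
    for w in np.arange(0.0, 1.0 + grid_step / 2, grid_step):
        avg = ensemble_average_sf(fc_list, [w, 1.0 - w])
        report = scale_and_rfactor(avg, obs)
        if best is None or report.r_work < best[1].r_work:
            best = (float(w), report)
    w, report = best
    return (w, 1.0 - w), report


# ---------------------------------------------------------------------------
# plain-text reflection file format
#
#   # CELL a b c alpha beta gamma
#   # SYMM x,y,z                    (one line per operator)
#   # DMIN 2.1
#   h k l fobs sigma free(0/1)
# ---------------------------------------------------------------------------


def write_reflections(refs: ReflectionSet, path: str | Path) -> Path:
    path = Path(path)
    lines = [
        "# CELL %.17g %.17g %.17g %.17g %.17g %.17g"
        % (refs.cell.a, refs.cell.b, refs.cell.c, refs.cell.alpha, refs.cell.beta, refs.cell.gamma)
    ]
    for t in refs.symmetry.triplets:
        lines.append(f"# SYMM {t}")
    lines.append("# DMIN %.17g" % refs.d_min)
    for (h, k, l), fo, sig, free in zip(refs.hkl, refs.f_obs, refs.sigma, refs.free_flag):
        lines.append("%d %d %d %.17g %.17g %d" % (h, k, l, fo, sig, int(free)))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_reflections(path: str | Path) -> ReflectionSet:
    path = Path(path)
    cell = None
    triplets: list[str] = []
    d_min = None
    hkl, fobs, sigma, free = [], [], [], []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if not parts:
                continue
            tag = parts[0].upper()
            if tag == "CELL":
                cell = UnitCell(*(float(x) for x in parts[1:7]))
            elif tag == "SYMM":
                triplets.append(" ".join(parts[1:]))
            elif tag == "DMIN":
                d_min = float(parts[1])
            continue
        parts = line.split()
        if len(parts) != 6:
            raise ValueError(f"{path}: bad reflection line {line!r}")
        hkl.append([int(parts[0]), int(parts[1]), int(parts[2])])
        fobs.append(float(parts[3]))
        sigma.append(float(parts[4]))
        free.append(bool(int(parts[5])))
    if cell is None or d_min is None or not triplets:
        raise ValueError(f"{path}: missing CELL/SYMM/DMIN header")
    return ReflectionSet(
        hkl=np.array(hkl, dtype=int),
        f_obs=np.array(fobs),
        sigma=np.array(sigma),
        free_flag=np.array(free, dtype=bool),
        cell=cell,
        symmetry=SymmetryOps(triplets),
        d_min=d_min,
    )
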