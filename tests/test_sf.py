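"""Structure factors, ensemble averaging, scaling and R factors."""

import numpy as np
import pytest

import gemmi

from mrensemble import (
    P1,
    P212121,
    calc_structure_factors,
    ensemble_average_sf,
    fit_mixture_weight,
    make_free_flags,
    make_helix_protein,
    read_reflections,
    scale_and_rfactor,
    set_rotamer,
    simulate_observed,
    write_reflections,
)
from mrensemble.sf import ComplexSFSet, ReflectionSet, SymmetryOps, generate_hkl, _scattering_factors
from mrensemble.structure import Atom, Structure, UnitCell
from mrensemble.synth import DiffractionSpec, cell_for_structure


def toy_cell():
    return UnitCell(10.0, 12.0, 14.0)


def atom(x, y, z, element="C", b=10.0, occ=1.0, num=1):
    return Atom("A", num, "ALA", "CA", element, np.array([x, y, z]), b_factor=b, occupancy=occ)


def sf_oracle(structure, cell, ops, hkl):
    """Naive scalar double loop over reflections, operators and atoms.

    The 4-Gaussian form factor is evaluated in double precision from the
    raw coefficient table (the library shares the table but not the code
    path)."""
    frac = cell.frac_matrix()
    out = []
    for h in hkl:
        d = 1.0 / np.sqrt(np.array(h, float) @ (frac @ frac.T) @ np.array(h, float))
        stol2 = 1.0 / (4.0 * d * d)
        total = 0j
        for a in structure.atoms:
            coefs = gemmi.Element(a.element).it92.get_coefs()
            f0 = coefs[8] + sum(coefs[i] * np.exp(-coefs[4 + i] * stol2) for i in range(4))
            xf = frac @ a.position
            for rot, tran in ops.matrices():
                xp = rot @ xf + tran
                phase = 2.0 * np.pi * float(np.dot(h, xp))
                total += a.occupancy * f0 * np.exp(-a.b_factor / (4 * d * d)) * np.exp(1j * phase)
        out.append(total)
    return np.array(out)


class TestDirectSummation:
    def test_origin_atom_gives_real_form_factor(self):
        s = Structure(atoms=[atom(0, 0, 0, b=0.0)])
        fc = calc_structure_factors(s, toy_cell(), P1, d_min=2.0)
        assert np.all(np.abs(fc.values.imag) < 1e-10)
        d = 1.0 / np.sqrt(
            np.einsum(
                "ni,ij,nj->n",
                fc.hkl.astype(float),
                toy_cell().frac_matrix() @ toy_cell().frac_matrix().T,
                fc.hkl.astype(float),
            )
        )
        expected = _scattering_factors("C", 1.0 / (4 * d**2))
        np.testing.assert_allclose(fc.values.real, expected, rtol=1e-10)

    def test_screw_axis_absences(self):
        rng = np.random.default_rng(0)
        atoms = [
            atom(*xyz, num=i + 1)
            for i, xyz in enumerate(rng.uniform(1, 8, size=(4, 3)))
        ]
        s = Structure(atoms=atoms)
        cell = UnitCell(15.0, 17.0, 19.0)
        axial = np.array(
            [[1, 0, 0], [2, 0, 0], [3, 0, 0], [4, 0, 0], [5, 0, 0], [6, 0, 0]]
        )
        fc = calc_structure_factors(s, cell, P212121, d_min=2.0, hkl=axial)
        amps = np.abs(fc.values)
        full = calc_structure_factors(s, cell, P212121, d_min=3.0)
        ref = np.abs(full.values).max()
        assert np.all(amps[[0, 2, 4]] < 1e-6 * ref)  # odd h on the screw axis
        assert np.all(amps[[1, 3, 5]] > 1e-6 * ref)

    def test_matches_brute_force_oracle_p1(self):
        s = Structure(atoms=[atom(1.0, 2.0, 3.0), atom(4.0, 1.5, 7.0, "N", b=18.0, num=2),
                             atom(2.5, 6.0, 5.0, "O", b=25.0, occ=0.7, num=3)])
        cell = toy_cell()
        fc = calc_structure_factors(s, cell, P1, d_min=2.0)
        oracle = sf_oracle(s, cell, P1, fc.hkl)
        np.testing.assert_allclose(fc.values, oracle, rtol=1e-10)

    def test_matches_brute_force_oracle_symmetry(self):
        s = Structure(atoms=[atom(1.0, 2.0, 3.0), atom(3.0, 4.0, 5.0, "N", num=2)])
        cell = UnitCell(11.0, 13.0, 15.0)
        hkl = generate_hkl(cell, 3.0)[::5]
        fc = calc_structure_factors(s, cell, P212121, d_min=3.0, hkl=hkl)
        oracle = sf_oracle(s, cell, P212121, hkl)
        # absences are ~0 by symmetry, so scale the tolerance to the
        # largest amplitude instead of each reflection's own magnitude
        scale = np.abs(oracle).max()
        np.testing.assert_allclose(fc.values, oracle, rtol=0, atol=1e-10 * scale)

    def test_friedel_symmetry(self):
        rng = np.random.default_rng(1)
        s = Structure(atoms=[atom(*xyz, num=i + 1) for i, xyz in enumerate(rng.uniform(0, 9, (5, 3)))])
        cell = toy_cell()
        hkl = generate_hkl(cell, 2.5)
        both = np.vstack([hkl, -hkl])
        fc = calc_structure_factors(s, cell, P1, d_min=2.5, hkl=both)
        n = len(hkl)
        np.testing.assert_allclose(
            fc.values[n:], np.conj(fc.values[:n]), rtol=1e-10
        )

    def test_b_doubling_attenuates_high_resolution(self):
        s = make_helix_protein(8, sequence="AEALKAAE")
        cell = cell_for_structure(s)
        hot = s.copy()
        for a in hot.atoms:
            a.b_factor *= 2
        fc_cold = calc_structure_factors(s, cell, P1, d_min=2.0)
        fc_hot = calc_structure_factors(hot, cell, P1, d_min=2.0)
        dsp = ReflectionSet(
            hkl=fc_cold.hkl, f_obs=np.abs(fc_cold.values), sigma=np.ones(len(fc_cold)),
            free_flag=np.zeros(len(fc_cold), bool), cell=cell, symmetry=P1, d_min=2.0,
        ).d_spacings()
        high = dsp < 2.2
        low = dsp > 8.0
        assert np.all(np.abs(fc_hot.values[high]) < np.abs(fc_cold.values[high]))
        ratio_low = np.abs(fc_hot.values[low]) / np.abs(fc_cold.values[low])
        assert np.all(ratio_low > 0.8)  # low-order terms nearly unchanged


class TestEnsembleAverage:
    def setup_method(self):
        rng = np.random.default_rng(2)
        self.hkl = generate_hkl(toy_cell(), 3.0)
        n = len(self.hkl)
        self.a = ComplexSFSet(self.hkl, rng.normal(size=n) + 1j * rng.normal(size=n))
        self.b = ComplexSFSet(self.hkl, rng.normal(size=n) + 1j * rng.normal(size=n))

    def test_identical_sets_fixed_point(self):
        avg = ensemble_average_sf([self.a, self.a, self.a])
        np.testing.assert_allclose(avg.values, self.a.values, rtol=1e-14)

    def test_degenerate_weights(self):
        avg = ensemble_average_sf([self.a, self.b], [1.0, 0.0])
        np.testing.assert_allclose(avg.values, self.a.values, rtol=1e-14)

    def test_triangle_inequality_per_reflection(self):
        avg = ensemble_average_sf([self.a, self.b], [0.5, 0.5])
        lhs = np.abs(avg.values)
        rhs = 0.5 * (np.abs(self.a.values) + np.abs(self.b.values))
        assert np.all(lhs <= rhs + 1e-12)
        phase_diff = np.abs(np.angle(self.a.values / self.b.values)) > 1e-3
        assert np.all(lhs[phase_diff] < rhs[phase_diff])

    def test_index_mismatch_rejected(self):
        other = ComplexSFSet(self.hkl[:-1], self.a.values[:-1])
        with pytest.raises(ValueError, match="indexed"):
            ensemble_average_sf([self.a, other])

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError):
            ensemble_average_sf([self.a, self.b], [0.7, 0.7])


class TestScaleAndR:
    def make_obs(self, amps, free):
        n = len(amps)
        return ReflectionSet(
            hkl=self.hkl[:n], f_obs=np.asarray(amps, float), sigma=np.ones(n),
            free_flag=np.asarray(free, bool), cell=toy_cell(), symmetry=P1, d_min=2.0,
        )

    def setup_method(self):
        self.hkl = generate_hkl(toy_cell(), 2.0)

    def test_exact_model_r_zero_any_scale(self):
        rng = np.random.default_rng(3)
        n = 40
        values = rng.normal(size=n) + 1j * rng.normal(size=n)
        fc = ComplexSFSet(self.hkl[:n], values)
        free = np.zeros(n, bool)
        free[::10] = True
        obs = self.make_obs(2.0 * np.abs(values), free)
        rep = scale_and_rfactor(fc, obs)
        assert rep.scale == pytest.approx(2.0, rel=1e-12)
        assert rep.r_work == pytest.approx(0.0, abs=1e-12)
        assert rep.r_free == pytest.approx(0.0, abs=1e-12)

    def test_three_reflection_hand_value(self):
        # |Fc| = (1, 2, 2); obs = (1, 4, 2), first reflection free
        fc = ComplexSFSet(self.hkl[:3], np.array([1.0, 2.0, 2.0], dtype=complex))
        obs = self.make_obs([1.0, 4.0, 2.0], [True, False, False])
        rep = scale_and_rfactor(fc, obs)
        # work set: k = (4*2 + 2*2)/(4 + 4) = 1.5
        assert rep.scale == pytest.approx(1.5)
        # r_work = (|4-3| + |2-3|)/6 = 1/3 ; r_free = |1-1.5|/1
        assert rep.r_work == pytest.approx(1.0 / 3.0)
        assert rep.r_free == pytest.approx(0.5)
        assert (rep.n_work, rep.n_free) == (2, 1)

    def test_matches_independent_formula(self):
        rng = np.random.default_rng(4)
        n = 60
        values = rng.normal(size=n) + 1j * rng.normal(size=n)
        fc = ComplexSFSet(self.hkl[:n], values)
        amps = np.abs(values) * (1 + rng.normal(scale=0.1, size=n))
        free = rng.random(n) < 0.1
        obs = self.make_obs(np.abs(amps), free)
        rep = scale_and_rfactor(fc, obs)
        fo, fcv = obs.f_obs, np.abs(values)
        w = ~free
        k = np.sum(fo[w] * fcv[w]) / np.sum(fcv[w] ** 2)
        r_work = np.sum(np.abs(fo[w] - k * fcv[w])) / np.sum(fo[w])
        assert rep.r_work == pytest.approx(r_work, rel=1e-12)

    def test_invariant_to_global_rescaling_of_obs(self):
        rng = np.random.default_rng(5)
        n = 50
        values = rng.normal(size=n) + 1j * rng.normal(size=n)
        fc = ComplexSFSet(self.hkl[:n], values)
        amps = np.abs(values) * (1 + rng.normal(scale=0.05, size=n))
        free = rng.random(n) < 0.1
        r1 = scale_and_rfactor(fc, self.make_obs(np.abs(amps), free))
        r2 = scale_and_rfactor(fc, self.make_obs(np.abs(amps) * 7.5, free))
        assert r1.r_work == pytest.approx(r2.r_work, rel=1e-12)
        assert r1.r_free == pytest.approx(r2.r_free, rel=1e-12)


class TestFreeFlags:
    def make_refs(self, n=1000):
        cell = UnitCell(30.0, 30.0, 30.0)
        hkl = generate_hkl(cell, 3.0)[:n]
        return ReflectionSet(
            hkl=hkl, f_obs=np.ones(len(hkl)), sigma=np.ones(len(hkl)),
            free_flag=np.zeros(len(hkl), bool), cell=cell, symmetry=P1, d_min=3.0,
        )

    def test_fraction_and_reproducibility(self):
        refs = self.make_refs()
        a = make_free_flags(refs, 0.05, seed=7)
        b = make_free_flags(refs, 0.05, seed=7)
        np.testing.assert_array_equal(a.free_flag, b.free_flag)
        n = len(refs)
        count = a.free_flag.sum()
        assert abs(count - 0.05 * n) < 3 * np.sqrt(0.05 * 0.95 * n)

    def test_zero_fraction_rejected(self):
        with pytest.raises(ValueError):
            make_free_flags(self.make_refs(), 0.0)

    def test_different_seeds_differ(self):
        refs = self.make_refs()
        a = make_free_flags(refs, 0.05, seed=1)
        b = make_free_flags(refs, 0.05, seed=2)
        assert not np.array_equal(a.free_flag, b.free_flag)


@pytest.fixture(scope="module")
def small_system():
    base = make_helix_protein(20)
    conf_a = base.copy(label="a")
    conf_b = base.copy(label="b")
    # flip the glutamate at position 8 into a different rotamer
    set_rotamer(conf_b, 8, "mm-40°")
    cell = cell_for_structure(base)
    return conf_a, conf_b, cell


class TestMixtureWeight:
    def compute(self, system, weights, noise, seed=13):
        conf_a, conf_b, cell = system
        spec = DiffractionSpec(weights=weights, noise_fraction=noise, d_min=2.5, seed=seed)
        obs = simulate_observed([conf_a, conf_b], cell, P1, spec)
        fcs = [
            calc_structure_factors(c, cell, P1, 2.5, hkl=obs.hkl)
            for c in (conf_a, conf_b)
        ]
        return fit_mixture_weight(fcs, obs)

    def test_noise_free_even_mixture(self, small_system):
        (w, _), rep = self.compute(small_system, (0.5, 0.5), 0.0)
        assert w == pytest.approx(0.5, abs=0.011)
        assert rep.r_work < 1e-6

    def test_single_conformer_limit(self, small_system):
        (w, _), _ = self.compute(small_system, (1.0, 0.0), 0.0)
        assert w == pytest.approx(1.0, abs=0.011)

    def test_noisy_seventy_thirty(self, small_system):
        (w, _), _ = self.compute(small_system, (0.7, 0.3), 0.05)
        assert w == pytest.approx(0.7, abs=0.1)


def test_reflection_file_round_trip(tmp_path):
    rng = np.random.default_rng(6)
    cell = UnitCell(20.0, 22.5, 25.125, 90.0, 95.5, 90.0)
    hkl = generate_hkl(cell, 4.0)
    refs = ReflectionSet(
        hkl=hkl,
        f_obs=np.abs(rng.normal(size=len(hkl))) * 100,
        sigma=np.abs(rng.normal(size=len(hkl))),
        free_flag=rng.random(len(hkl)) < 0.05,
        cell=cell,
        symmetry=SymmetryOps(["x,y,z", "-x,y+1/2,-z"]),
        d_min=4.0,
    )
    path = tmp_path / "refl.txt"
    write_reflections(refs, path)
    back = read_reflections(path)
    np.testing.assert_array_equal(back.hkl, refs.hkl)
    np.testing.assert_array_equal(back.f_obs, refs.f_obs)  # bit-exact
    np.testing.assert_array_equal(back.sigma, refs.sigma)
    np.testing.assert_array_equal(back.free_flag, refs.free_flag)
    assert back.cell.c == refs.cell.c and back.cell.beta == refs.cell.beta
    assert back.symmetry.triplets == refs.symmetry.triplets
    assert back.d_min == refs.d_min
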