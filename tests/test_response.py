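"""Response stage: M matrix, HDA shifts, matrix-free Omega, Davidson,
oscillator strengths, polarizability, and the full-hybrid oracle."""

import numpy as np
import pytest

from tdadft.basis import BasisFunction
from tdadft.constants import HARTREE_EV
from tdadft.fixtures import generate_fixture
from tdadft.functionals import FunctionalSpec, make_functional
from tdadft.response import (
    HDAShift,
    InstabilityError,
    OmegaOperator,
    ResponseEngine,
    davidson,
    dynamic_polarizability,
    hda_shift,
    m_matrix,
    mo_three_center,
    solve_excitations,
)
from tdadft.scf import run_scf


class TestMMatrix:
    def test_equals_naive_transformation(self, systems):
        """In-loop MO-product pathway == naive C^T <mn||k> C, bitwise-level."""
        res, env = systems.scf("h2o", "lda")
        m = m_matrix(res, env.molecule, env.basis, env.aux)
        C = res.mo_coeff
        naive = np.einsum("mnk,mp,np->pk", env.t3.tensor, C, C, optimize=True)
        np.testing.assert_allclose(m.matrix, naive, atol=1e-12)

    def test_mo_sign_flip_invariance(self, systems):
        res, env = systems.scf("h2", "lda")
        import copy

        res2 = copy.deepcopy(res)
        res2.mo_coeff[:, 0] *= -1.0
        m1 = m_matrix(res, env.molecule, env.basis, env.aux)
        m2 = m_matrix(res2, env.molecule, env.basis, env.aux)
        np.testing.assert_allclose(m1.matrix, m2.matrix, atol=1e-14)

    def test_zero_coefficient_vector_gives_zero_row(self, systems):
        res, env = systems.scf("h2", "lda")
        import copy

        res2 = copy.deepcopy(res)
        res2.mo_coeff[:, 1] = 0.0
        m = m_matrix(res2, env.molecule, env.basis, env.aux)
        np.testing.assert_allclose(m.matrix[1], 0.0, atol=1e-16)


class TestHDAShift:
    def test_zero_mixing_gives_zero_shift_and_pure_spectrum(self, systems):
        eng = systems.engine("h2o", "lda")
        assert np.all(eng.shift.delta == 0.0)
        hda = eng.excitations(5, method="dense", approximation="hda")
        pure = eng.excitations(5, method="dense", approximation="pure")
        np.testing.assert_allclose(hda.omega_ev, pure.omega_ev, atol=1e-10)

    def test_rs_with_alpha_one_equals_gh(self, systems):
        """RS variant at (alpha=1, beta=0) degenerates to the GH shift."""
        res, env = systems.scf("h2o", "pbe0", need_4c=True)
        m = m_matrix(res, env.molecule, env.basis, env.aux)
        f_gh = res.functional
        f_rs = FunctionalSpec("rs", c_F=0.25, cam_alpha=1.0, cam_beta=0.0)
        d_gh = hda_shift(m, env.metric, f_gh, res.n_occ, variant="gh")
        d_rs = hda_shift(m, env.metric, f_rs, res.n_occ, variant="rs")
        np.testing.assert_allclose(d_rs.delta, d_gh.delta, atol=1e-12)

    @pytest.mark.parametrize("name", ["h2", "h2o"])
    def test_against_four_center_fitting_oracle(self, systems, name):
        """Delta_ai == c_F x (aa|ii) density-fitted by explicit fitting of the
        MO product densities (brute-force path through the AO tensors)."""
        res, env = systems.scf(name, "pbe0", need_4c=True)
        eng = systems.engine(name, "pbe0", need_4c=True)
        C = res.mo_coeff
        n_occ = res.n_occ
        t3_mo = np.einsum("mnk,mp,np->pk", env.t3.tensor, C, C, optimize=True)
        c_F = res.functional.c_F
        for i in range(n_occ):
            x_ii = env.metric.solve(t3_mo[i])
            for a in range(n_occ, res.n_mo):
                fitted = float(t3_mo[a] @ x_ii)
                assert eng.shift.delta[i, a - n_occ] == pytest.approx(
                    c_F * fitted, abs=1e-10
                )

    def test_shift_positive_for_valence_pairs(self, systems):
        """(aa|ii)-type self-repulsion integrals are positive."""
        eng = systems.engine("h2o", "pbe0", need_4c=True)
        assert np.all(eng.shift.delta > 0)


class TestOmegaOperator:
    def test_apply_matches_dense(self, systems, rng):
        eng = systems.engine("h2o", "pbe0", need_4c=True)
        op = eng.operator()
        dense = op.dense()
        scale = np.linalg.norm(dense, 2)
        for _ in range(5):
            v = rng.normal(size=op.dim)
            ref = dense @ v
            got = op.apply(v)
            assert np.linalg.norm(got - ref) <= 1e-10 * scale * np.linalg.norm(v)

    def test_symmetry_of_matrix_vector_products(self, systems, rng):
        eng = systems.engine("h2o", "pbe0", need_4c=True)
        op = eng.operator()
        scale = np.linalg.norm(op.diagonal())
        for _ in range(20):
            u, v = rng.normal(size=(2, op.dim))
            assert abs(u @ op.apply(v) - v @ op.apply(u)) <= 1e-10 * scale * np.linalg.norm(u) * np.linalg.norm(v)

    def test_zero_shift_reduces_to_pure_operator(self, systems):
        eng = systems.engine("h2o", "lda")
        op_hda = eng.operator(approximation="hda")
        op_pure = eng.operator(approximation="pure")
        np.testing.assert_allclose(op_hda.dense(), op_pure.dense(), atol=0)

    def test_instability_reported_with_pairs(self, systems):
        res, env = systems.scf("h2", "lda")
        eng = systems.engine("h2", "lda")
        huge = HDAShift(np.full((res.n_occ, res.n_virt), 10.0), "gh", 1.0)
        with pytest.raises(InstabilityError, match="pairs"):
            OmegaOperator(
                res.mo_energy[: res.n_occ], res.mo_energy[res.n_occ :],
                huge, eng.t_ia, eng.o_matrices["singlet"],
            )


class TestTwoLevelClosedForm:
    @pytest.mark.parametrize("name,functional", [("h2", "pbe0"), ("heh+", "b3lyp")])
    def test_single_pair_system(self, systems, name, functional):
        """1 occupied x 1 virtual: omega = sqrt((de)(de + 4K)) exactly."""
        res, env = systems.scf(name, functional, need_4c=True)
        eng = systems.engine(name, functional, need_4c=True)
        assert res.n_occ == 1 and res.n_virt == 1
        de = res.mo_energy[1] - res.mo_energy[0] - eng.shift.delta[0, 0]
        t = eng.t_ia.reshape(1, -1)
        K = float((t @ eng.o_matrices["singlet"].matrix @ t.T)[0, 0])
        expected = np.sqrt(de * (de + 4.0 * K))
        exc = eng.excitations(1, method="dense")
        assert exc.omega[0] == pytest.approx(expected, abs=1e-12)


class TestDavidson:
    def test_matches_dense_diagonalization(self, systems):
        """Lowest 10 roots on a 40-dimensional pair space."""
        eng = systems.engine("h2o", "lda", basis="6-31g")
        dense = eng.excitations(10, method="dense")
        dav = eng.excitations(10, method="davidson", tol=1e-10)
        np.testing.assert_allclose(dav.omega_ev, dense.omega_ev, atol=1e-8)

    def test_deterministic_across_runs(self, systems):
        eng = systems.engine("h2o", "lda", basis="6-31g")
        a = eng.excitations(6, method="davidson")
        b = eng.excitations(6, method="davidson")
        np.testing.assert_array_equal(a.omega, b.omega)
        np.testing.assert_array_equal(a.vectors, b.vectors)

    def test_degenerate_diagonal_tie_break(self, systems):
        """Roots from degenerate diagonal guesses are stable and complete."""
        eng = systems.engine("h2o", "lda", basis="6-31g")
        op = eng.operator()
        theta, vecs = davidson(op, 4, tol=1e-9)
        ref = np.linalg.eigvalsh(op.dense())[:4]
        np.testing.assert_allclose(theta, ref, atol=1e-9)


class TestOscillatorStrengths:
    def test_nonnegative_on_all_fixtures(self, systems):
        for name in ("h2", "heh+", "lih", "h2o"):
            eng = systems.engine(name, "lda")
            exc = eng.excitations(min(6, eng.n_occ * eng.n_virt), method="dense")
            assert np.all(exc.oscillator_strengths >= 0.0)

    def test_symmetry_forbidden_root_is_dark(self, systems):
        """Centrosymmetric H2: g->g transitions carry zero oscillator
        strength."""
        eng = systems.engine("h2", "lda", basis="6-31g")
        exc = eng.excitations(4, method="dense")
        assert np.min(exc.oscillator_strengths) <= 1e-10

    def test_rotation_invariance(self, systems):
        ref = _rotated_run(rotate=False)
        rot = _rotated_run(rotate=True)
        np.testing.assert_allclose(rot.omega_ev, ref.omega_ev, atol=1e-8)
        np.testing.assert_allclose(
            rot.oscillator_strengths, ref.oscillator_strengths, atol=1e-8
        )

    def test_triplets_are_spin_forbidden(self, systems):
        eng = systems.engine("h2o", "lda")
        exc = eng.excitations(5, spin="triplet", method="dense")
        assert np.all(exc.oscillator_strengths == 0.0)


def _rotated_run(rotate: bool):
    from scipy.spatial.transform import Rotation

    from tdadft.basis import assign_aux_basis, parse_aux_basis

    fx = generate_fixture("h2o")
    mol = fx.molecule
    aos = fx.ao_basis()
    if rotate:
        rot = Rotation.from_euler("xyz", [0.4, -0.2, 0.9]).as_matrix()
        mol = mol.rotated(rot)
        aos = [
            BasisFunction(b.center, rot @ b.origin, b.lmn, b.exponents, b.coefficients)
            for b in aos
        ]
    aux = assign_aux_basis(mol, {s: parse_aux_basis(fx.aux_text, s) for s in set(mol.symbols)})
    res, env = run_scf(mol, aos, aux, make_functional("pbe0"))
    eng = ResponseEngine(res, env)
    return eng.excitations(5, method="dense")


@pytest.fixture(scope="module")
def full_spectrum(systems):
    eng = systems.engine("h2o", "pbe0", need_4c=True)
    return eng.excitations(eng.n_occ * eng.n_virt, method="dense")


class TestDynamicPolarizability:
    def test_even_in_frequency(self, full_spectrum):
        w = np.array([0.05, 0.11, 0.2])
        _, ap = dynamic_polarizability(full_spectrum, w)
        _, am = dynamic_polarizability(full_spectrum, -w)
        np.testing.assert_allclose(ap, am, atol=1e-14)

    def test_static_value_is_sum_over_states(self, full_spectrum):
        _, a0 = dynamic_polarizability(full_spectrum, [0.0])
        sos = np.sum(
            full_spectrum.oscillator_strengths / full_spectrum.omega ** 2
        )
        assert a0[0] == pytest.approx(sos, rel=1e-12)

    def test_poles_bracket_every_bright_excitation(self, full_spectrum):
        """abar changes sign across each dipole-allowed excitation energy
        within a 1e-4 hartree bracket (the pole-coincidence property)."""
        delta = 1e-7
        for wI, f in zip(full_spectrum.omega, full_spectrum.oscillator_strengths):
            if f < 1e-6:
                continue
            _, lo = dynamic_polarizability(full_spectrum, [wI - delta], pole_guard=1e-10)
            _, hi = dynamic_polarizability(full_spectrum, [wI + delta], pole_guard=1e-10)
            assert lo[0] > 0 > hi[0]
            assert 2 * delta < 1e-4

    def test_pole_guard_warns_and_skips(self, full_spectrum):
        with pytest.warns(RuntimeWarning, match="pole"):
            w, a = dynamic_polarizability(
                full_spectrum, [full_spectrum.omega[0] + 1e-12, 0.01]
            )
        assert len(w) == 1


class TestFullHybridReference:
    def test_diagonal_restriction_reproduces_hda(self, systems):
        """Zeroing the off-diagonal exchange of the fitted-exchange full
        response gives back the HDA spectrum."""
        eng = systems.engine("h2o", "pbe0", need_4c=True)
        n = eng.n_occ * eng.n_virt
        hda = eng.excitations(n, method="dense")
        rst = eng.reference_full_hybrid(n, exchange="fitted", restriction="hda-diagonal")
        np.testing.assert_allclose(rst.omega_ev, hda.omega_ev, atol=1e-10)

    def test_zero_mixing_reproduces_pure_spectrum(self, systems):
        res, env = systems.scf("h2o", "lda", need_4c=True)
        eng = ResponseEngine(res, env)
        pure = eng.excitations(8, method="dense", approximation="pure")
        orc = eng.reference_full_hybrid(8)
        np.testing.assert_allclose(orc.omega_ev, pure.omega_ev, atol=1e-10)

    def test_tda_mode_consistency(self, systems):
        res, env = systems.scf("h2o", "lda", need_4c=True)
        eng = ResponseEngine(res, env)
        tda_pure = eng.excitations(6, method="dense", mode="tda", approximation="pure")
        tda_orc = eng.reference_full_hybrid(6, mode="tda")
        np.testing.assert_allclose(tda_orc.omega_ev, tda_pure.omega_ev, atol=1e-10)

    def test_hda_and_oracle_deviations_are_reported(self, systems):
        """Engine exposes both spectra so the HDA error is measurable; on
        desk-scale fixtures both deviations stay within ~0.5 eV."""
        eng = systems.engine("h2o", "pbe0", need_4c=True)
        hda_s = eng.excitations(5, method="dense")
        orc_s = eng.reference_full_hybrid(5)
        hda_t = eng.excitations(5, spin="triplet", method="dense")
        orc_t = eng.reference_full_hybrid(5, spin="triplet")
        assert np.max(np.abs(hda_s.omega_ev - orc_s.omega_ev)) < 0.5
        assert np.max(np.abs(hda_t.omega_ev - orc_t.omega_ev)) < 0.5


class TestRangeSeparatedPipeline:
    def test_cam_functional_runs_and_shifts_differ_from_gh(self, systems):
        eng = systems.engine("h2o", "cam-b3lyp", need_4c=True)
        exc = eng.excitations(4, method="dense")
        assert np.all(np.diff(exc.omega) >= 0)
        assert np.all(exc.omega > 0)
        eng_gh = systems.engine("h2o", "pbe0", need_4c=True)
        assert not np.allclose(eng.shift.delta, eng_gh.shift.delta)

    def test_inverse_range_separation_runs(self, systems):
        eng = systems.engine("h2o", "hse06", need_4c=True)
        exc = eng.excitations(3, method="dense")
        assert np.all(exc.omega > 0)
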