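"""Integral engine: one-electron matrices, Coulomb metric, three- and
four-center ERIs, operator limits, and the density-fitting bound."""

import math

import numpy as np
import pytest

import oracles
from tdadft.basis import AuxiliaryFunction, BasisFunction
from tdadft.boys import boys
from tdadft.fixtures import generate_fixture
from tdadft.integrals import (
    CapabilityError,
    CoulombOperator,
    coulomb_metric,
    four_center,
    one_electron,
    three_center,
)
from tdadft.molecule import parse_xyz


@pytest.fixture(scope="module")
def h2():
    fx = generate_fixture("h2")
    return fx.molecule, fx.ao_basis()


@pytest.fixture(scope="module")
def random_system(rng):
    """Small randomized geometry with s/p orbitals and s/p/d Hermite aux."""
    mol = parse_xyz("2\n\nHe 0 0 0\nHe 0.9 0.4 -0.6")
    r = rng
    aos = [
        BasisFunction(0, mol.coordinates[0], (0, 0, 0),
                      np.array([1.3, 0.4]), np.array([0.7, 0.5])),
        BasisFunction(1, mol.coordinates[1], (1, 0, 0),
                      np.array([0.9]), np.array([1.1])),
        BasisFunction(1, mol.coordinates[1], (0, 1, 1),
                      np.array([0.75]), np.array([0.8])),
    ]
    aux = [
        AuxiliaryFunction(0, 1.1, (0, 0, 0)),
        AuxiliaryFunction(0, 0.6, (1, 0, 0)),
        AuxiliaryFunction(1, 0.8, (0, 1, 1)),
        AuxiliaryFunction(1, 0.5, (2, 0, 0)),
    ]
    return mol, aos, aux


class TestOneElectron:
    def test_overlap_unit_diagonal_and_symmetry(self, h2):
        mol, aos = h2
        oe = one_electron(mol, aos)
        np.testing.assert_allclose(np.diag(oe.overlap), 1.0, atol=1e-10)
        for m in (oe.overlap, oe.kinetic, oe.nuclear):
            np.testing.assert_allclose(m, m.T, atol=1e-14)

    def test_overlap_against_quadrature_oracle(self, h2):
        mol, aos = h2
        oe = one_electron(mol, aos)
        assert oe.overlap[0, 1] == pytest.approx(
            oracles.overlap(aos[0], aos[1]), abs=1e-12
        )

    def test_dipole_origin_shift(self, h2):
        """Translating the dipole origin by Q shifts matrices by -Q.S."""
        mol, aos = h2
        q = np.array([0.3, -0.2, 0.7])
        oe0 = one_electron(mol, aos)
        oeq = one_electron(mol, aos, origin=q)
        for d in range(3):
            np.testing.assert_allclose(
                oeq.dipole[d], oe0.dipole[d] - q[d] * oe0.overlap, atol=1e-12
            )


class TestCoulombMetric:
    def test_two_s_hermite_against_oracle(self, h2):
        mol, _ = h2
        aux = [AuxiliaryFunction(0, 1.0, (0, 0, 0)), AuxiliaryFunction(1, 0.5, (0, 0, 0))]
        G = coulomb_metric(mol, aux).matrix
        for i in range(2):
            for j in range(2):
                o = oracles.metric_element(aux[i], aux[j], mol.coordinates)
                assert G[i, j] == pytest.approx(o, rel=1e-8)

    def test_symmetric_and_positive_definite(self, random_system):
        mol, _, aux = random_system
        m = coulomb_metric(mol, aux)
        np.testing.assert_allclose(m.matrix, m.matrix.T, atol=1e-13)
        assert np.all(np.linalg.eigvalsh(m.matrix) > 0)
        assert np.isfinite(m.condition_number)

    def test_erf_to_one_limit(self, random_system):
        """omega -> infinity: attenuated metric -> plain metric."""
        mol, _, aux = random_system
        G = coulomb_metric(mol, aux).matrix
        Gb = coulomb_metric(mol, aux, CoulombOperator(0.0, 1.0, 1e5)).matrix
        np.testing.assert_allclose(Gb, G, atol=1e-8)

    def test_erf_to_zero_limit(self, random_system):
        """omega -> 0: attenuated metric -> alpha * plain metric."""
        mol, _, aux = random_system
        G = coulomb_metric(mol, aux).matrix
        Gb = coulomb_metric(mol, aux, CoulombOperator(0.35, 0.5, 1e-10)).matrix
        np.testing.assert_allclose(Gb, 0.35 * G, atol=1e-8)


class TestThreeCenter:
    def test_all_s_closed_form(self):
        """Single-primitive s functions match the basic-integral seed."""
        mol = parse_xyz("2\n\nH 0 0 0\nH 0 0 0.7408481")
        b1 = BasisFunction(0, mol.coordinates[0], (0, 0, 0), np.array([1.1]), np.array([1.0]))
        b2 = BasisFunction(1, mol.coordinates[1], (0, 0, 0), np.array([0.7]), np.array([1.0]))
        aux = [AuxiliaryFunction(0, 0.9, (0, 0, 0))]
        val = three_center(mol, [b1, b2], aux).tensor[0, 1, 0]
        p = 1.1 + 0.7
        P = (1.1 * mol.coordinates[0] + 0.7 * mol.coordinates[1]) / p
        kappa = math.exp(-1.1 * 0.7 / p * np.sum((mol.coordinates[0] - mol.coordinates[1]) ** 2))
        zc = 0.9
        alpha = p * zc / (p + zc)
        T = alpha * float(np.sum(P ** 2))
        closed = 2.0 * math.pi ** 2.5 / (p * zc * math.sqrt(p + zc)) * kappa * boys(0, T)
        assert val == pytest.approx(closed, rel=1e-13)

    @pytest.mark.parametrize("omega", [None, 0.6])
    def test_general_shells_against_oracle(self, random_system, omega):
        mol, aos, aux = random_system
        op = CoulombOperator.plain() if omega is None else CoulombOperator.erf(omega)
        t3 = three_center(mol, aos, aux, op).tensor
        for (i, j, k) in [(0, 1, 0), (1, 2, 2), (0, 2, 3), (2, 2, 1)]:
            o = oracles.three_center_element(aos[i], aos[j], aux[k], mol.coordinates, omega)
            assert t3[i, j, k] == pytest.approx(o, rel=1e-7, abs=1e-12)

    def test_mu_nu_symmetry(self, random_system):
        mol, aos, aux = random_system
        t3 = three_center(mol, aos, aux).tensor
        np.testing.assert_allclose(t3, np.swapaxes(t3, 0, 1), atol=1e-14)

    def test_translation_invariance(self, random_system):
        mol, aos, aux = random_system
        shift = np.array([1.7, -2.3, 0.4])
        mol2 = mol.translated(shift)
        aos2 = [
            BasisFunction(b.center, b.origin + shift, b.lmn, b.exponents, b.coefficients)
            for b in aos
        ]
        t3 = three_center(mol, aos, aux).tensor
        t3b = three_center(mol2, aos2, aux).tensor
        np.testing.assert_allclose(t3b, t3, atol=1e-12)

    def test_attenuated_interpolates_monotonically(self):
        """All-s attenuated 3c integrals grow monotonically in omega from
        alpha*(plain) to (alpha+beta)*(plain)."""
        mol = parse_xyz("2\n\nH 0 0 0\nH 0 0 0.9")
        b = BasisFunction(0, mol.coordinates[0], (0, 0, 0), np.array([0.8]), np.array([1.0]))
        aux = [AuxiliaryFunction(1, 0.6, (0, 0, 0))]
        plain = three_center(mol, [b], aux).tensor[0, 0, 0]
        a, be = 0.2, 0.7
        vals = [
            three_center(mol, [b], aux, CoulombOperator(a, be, w)).tensor[0, 0, 0]
            for w in (1e-4, 0.1, 0.3, 1.0, 3.0, 50.0)
        ]
        assert np.all(np.diff(vals) > 0)
        assert vals[0] >= a * plain - 1e-10
        assert vals[-1] <= (a + be) * plain + 1e-10


class TestFourCenter:
    def test_permutation_symmetry(self, random_system):
        mol, aos, _ = random_system
        eri = four_center(aos)
        np.testing.assert_allclose(eri, eri.transpose(1, 0, 2, 3), atol=1e-12)
        np.testing.assert_allclose(eri, eri.transpose(0, 1, 3, 2), atol=1e-12)
        np.testing.assert_allclose(eri, eri.transpose(2, 3, 0, 1), atol=1e-12)

    def test_schwarz_inequality(self, random_system):
        mol, aos, _ = random_system
        eri = four_center(aos)
        n = len(aos)
        d = np.sqrt(np.abs(np.einsum("mnmn->mn", eri)))
        for m in range(n):
            for nn in range(n):
                for s in range(n):
                    for t in range(n):
                        assert abs(eri[m, nn, s, t]) <= d[m, nn] * d[s, t] + 1e-12

    def test_h2_element_against_oracle(self, h2):
        mol, aos = h2
        eri = four_center(aos)
        o = oracles.four_center_element(aos[0], aos[0], aos[0], aos[0])
        assert eri[0, 0, 0, 0] == pytest.approx(o, abs=1e-12)

    def test_cam_operator_is_linear_combination(self, h2):
        _, aos = h2
        plain = four_center(aos)
        erf = four_center(aos, CoulombOperator.erf(0.5))
        cam = four_center(aos, CoulombOperator(0.3, 0.5, 0.5))
        np.testing.assert_allclose(cam, 0.3 * plain + 0.5 * erf, atol=1e-13)

    def test_size_guard(self, h2):
        _, aos = h2
        with pytest.raises(CapabilityError, match="N_bas"):
            four_center(aos, max_nbas=1)


class TestDensityFittingBound:
    def test_fitted_self_repulsion_below_exact(self, h2, rng):
        """Coulomb-metric fitting is variational: (rho~|rho~) <= (rho|rho)."""
        mol, aos = h2
        fx = generate_fixture("h2")
        aux = fx.aux_basis()
        eri = four_center(aos)
        t3 = three_center(mol, aos, aux).tensor
        metric = coulomb_metric(mol, aux)
        for _ in range(5):
            A = rng.normal(size=(2, 2))
            P = A + A.T
            exact = np.einsum("mn,st,mnst->", P, P, eri)
            J = np.einsum("mn,mnk->k", P, t3)
            fitted = float(J @ metric.solve(J))
            assert fitted <= exact + 1e-10

    def test_residual_monotone_under_extension(self, h2, rng):
        """Adding auxiliary functions never increases the fitting residual."""
        mol, aos = h2
        eri = four_center(aos)
        A = rng.normal(size=(2, 2))
        P = A + A.T
        exact = np.einsum("mn,st,mnst->", P, P, eri)
        base = [AuxiliaryFunction(0, 1.5, (0, 0, 0)), AuxiliaryFunction(1, 1.5, (0, 0, 0))]
        extras = [
            AuxiliaryFunction(0, float(z), tuple(k))
            for z, k in zip(
                rng.uniform(0.3, 4.0, size=10),
                [(0, 0, 0), (0, 0, 1), (1, 0, 0), (0, 0, 2), (0, 1, 0),
                 (0, 0, 0), (2, 0, 0), (0, 1, 1), (0, 0, 1), (1, 0, 1)],
            )
        ]
        prev = np.inf
        aux = list(base)
        for extra in extras:
            aux.append(extra)
            ordered = sorted(aux, key=lambda f: (f.center, -f.exponent, f.index))
            t3 = three_center(mol, aos, ordered).tensor
            metric = coulomb_metric(mol, ordered)
            J = np.einsum("mn,mnk->k", P, t3)
            resid = exact - float(J @ metric.solve(J))
            assert resid <= prev + 1e-9
            assert resid >= -1e-9
            prev = resid
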