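"""MSD_corr, overlapping coefficient, Merritt CC, isotropic scale and bond stats."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import exphar as xp
from exphar.adp_metrics import AdpError, IsotropicAdpError
from conftest import random_positive_definite

# the five printed worked examples of the directional-MSD correlation
MSD_CORR_EXAMPLES = [
    (np.diag([2.0, 1, 1]), np.diag([1.0, 2, 2]), -1.0),
    (np.diag([2.0, 1, 1]), np.diag([1.0, 2, 1]), -0.5),
    (np.diag([2.0, 1, 1]), np.diag([2.0, 2, 1]), 0.5),
    (np.diag([2.0, 1, 1]), np.diag([3.0, 1, 1]), 1.0),
    (np.diag([3.0, 3, 2]), np.diag([3.0, 1, 2]), 0.0),
]


class TestMsdAndUeq:
    def test_diagonal_projections(self):
        u = np.diag([2.0, 1.0, 1.0])
        assert xp.msd(u, [1, 0, 0]) == 2.0
        assert xp.msd(u, [0, 1, 0]) == 1.0
        assert xp.rmsd(u, [1, 0, 0]) == pytest.approx(np.sqrt(2.0))

    def test_random_tensor_matches_double_contraction(self):
        rng = np.random.default_rng(3)
        u = random_positive_definite(rng)
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        expected = sum(n[i] * u[i, j] * n[j] for i in range(3) for j in range(3))
        assert xp.msd(u, n) == pytest.approx(expected, rel=1e-12)

    def test_non_unit_direction_strict_vs_lenient(self):
        u = np.eye(3)
        assert xp.msd(u, [2, 0, 0]) == pytest.approx(1.0)
        with pytest.raises(AdpError):
            xp.msd(u, [2, 0, 0], strict=True)

    def test_u_eq_values_and_quadrature_average(self, sgrid_5810):
        assert xp.u_eq(np.diag([2.0, 1, 1])) == pytest.approx(4.0 / 3.0)
        assert xp.u_eq(np.eye(3)) == 1.0
        u = random_positive_definite(np.random.default_rng(5))
        msd_field = np.einsum("ki,ij,kj->k", sgrid_5810.points, u, sgrid_5810.points)
        assert sgrid_5810.average(msd_field) == pytest.approx(xp.u_eq(u), abs=1e-10)


class TestMsdCorr:
    @pytest.mark.parametrize("u1,u2,expected", MSD_CORR_EXAMPLES)
    def test_worked_examples_analytic(self, u1, u2, expected):
        assert xp.msd_corr(u1, u2) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("u1,u2,expected", MSD_CORR_EXAMPLES)
    def test_worked_examples_quadrature(self, u1, u2, expected, sgrid_5810):
        val = xp.msd_corr(u1, u2, method="quadrature", sgrid=sgrid_5810)
        assert val == pytest.approx(expected, abs=1e-3)

    def test_shift_invariance_and_symmetry(self):
        rng = np.random.default_rng(7)
        u = random_positive_definite(rng)
        c = 0.3 * xp.u_eq(u)
        assert xp.msd_corr(u, u + c * np.eye(3)) == pytest.approx(1.0, abs=1e-9)
        v = random_positive_definite(rng)
        assert xp.msd_corr(u, v) == pytest.approx(xp.msd_corr(v, u), abs=1e-14)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(9)
        u, v = (random_positive_definite(rng) for _ in range(2))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        rotated = xp.msd_corr(q @ u @ q.T, q @ v @ q.T)
        assert rotated == pytest.approx(xp.msd_corr(u, v), abs=1e-12)

    def test_analytic_agrees_with_quadrature(self, sgrid_5810):
        rng = np.random.default_rng(11)
        for _ in range(100):
            u, v = (random_positive_definite(rng) for _ in range(2))
            ana = xp.msd_corr(u, v)
            qua = xp.msd_corr(u, v, method="quadrature", sgrid=sgrid_5810)
            assert qua == pytest.approx(ana, abs=1e-6)
            assert -1.0 - 1e-12 <= ana <= 1.0 + 1e-12

    def test_isotropic_input_is_undefined(self):
        with pytest.raises(IsotropicAdpError):
            xp.msd_corr(np.eye(3), np.diag([2.0, 1, 1]))
        with pytest.raises(IsotropicAdpError):
            xp.msd_corr(np.diag([2.0, 1, 1]), 0.05 * np.eye(3))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_range_bound_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        u, v = (random_positive_definite(rng) for _ in range(2))
        assert -1.0 - 1e-10 <= xp.msd_corr(u, v) <= 1.0 + 1e-10


class TestGaussianOverlap:
    def test_identical_tensors(self):
        u = random_positive_definite(np.random.default_rng(1))
        res = xp.gaussian_overlap(u, u)
        assert res.ovl == pytest.approx(1.0, abs=1e-12)
        assert res.eta == pytest.approx(0.0, abs=1e-12)
        assert res.eta_r == pytest.approx(0.0, abs=1e-10)

    def test_eta_plus_ovl_is_one(self):
        rng = np.random.default_rng(2)
        u, v = (random_positive_definite(rng) for _ in range(2))
        res = xp.gaussian_overlap(u, v)
        assert res.ovl + res.eta == pytest.approx(1.0, abs=1e-10)
        assert res.eta_r == pytest.approx(100.0 * res.eta)

    def test_isotropic_pair_against_radial_oracle(self):
        s1, s2 = 0.02, 0.031  # variances, A^2
        res = xp.gaussian_overlap(s1 * np.eye(3), s2 * np.eye(3))

        def integrand(r):
            p1 = (2 * np.pi * s1) ** -1.5 * np.exp(-0.5 * r**2 / s1)
            p2 = (2 * np.pi * s2) ** -1.5 * np.exp(-0.5 * r**2 / s2)
            return abs(p1 - p2) * r**2

        eta_ref = 0.5 * 4 * np.pi * quad(integrand, 0, 10 * np.sqrt(s2), limit=200)[0]
        assert res.eta == pytest.approx(eta_ref, abs=1e-6)

    def test_monte_carlo_oracle_on_anisotropic_pair(self):
        rng = np.random.default_rng(17)
        u, v = (random_positive_definite(rng) for _ in range(2))
        res = xp.gaussian_overlap(u, v)
        # importance sampling from the equal mixture of p1 and p2:
        # eta = (1/2) E_mix[ |p1 - p2| / p_mix ]
        m = 10**6
        la, lb = np.linalg.cholesky(u), np.linalg.cholesky(v)
        z = rng.standard_normal((m, 3))
        pick = rng.random(m) < 0.5
        samples = np.where(pick[:, None], z @ la.T, z @ lb.T)

        def pdf(cov, x):
            inv = np.linalg.inv(cov)
            det = np.linalg.det(cov)
            expo = -0.5 * np.einsum("ki,ij,kj->k", x, inv, x)
            return (2 * np.pi) ** -1.5 * det**-0.5 * np.exp(expo)

        p1, p2 = pdf(u, samples), pdf(v, samples)
        ratio = np.abs(p1 - p2) / (0.5 * (p1 + p2))
        eta_mc = 0.5 * ratio.mean()
        se = 0.5 * ratio.std() / np.sqrt(m)
        assert abs(res.eta - eta_mc) < 3 * se + 1e-12

    def test_invariance_under_common_rotation_and_scaling(self):
        rng = np.random.default_rng(23)
        u, v = (random_positive_definite(rng) for _ in range(2))
        base = xp.gaussian_overlap(u, v).ovl
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        assert xp.gaussian_overlap(q @ u @ q.T, q @ v @ q.T).ovl == pytest.approx(
            base, abs=1e-9)
        assert xp.gaussian_overlap(2.5 * u, 2.5 * v).ovl == pytest.approx(base, abs=1e-9)

    def test_requires_positive_definite(self):
        with pytest.raises(AdpError):
            xp.gaussian_overlap(np.diag([1.0, 1, -0.1]), np.eye(3))


class TestMerrittCc:
    def test_identical_tensors(self):
        u = random_positive_definite(np.random.default_rng(4))
        cc, s12 = xp.merritt_cc(u, u)
        assert cc == pytest.approx(1.0, abs=1e-12)
        assert s12 == pytest.approx(0.0, abs=1e-10)

    def test_closed_form_matches_bruteforce_quadrature(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            u, v = (random_positive_definite(rng) for _ in range(2))
            cc, s12 = xp.merritt_cc(u, v)
            ref = _gaussian_product_cc_quadrature(u, v)
            assert cc == pytest.approx(ref, abs=1e-8)
            assert s12 == 100.0 * (1.0 - cc)

    def test_scale_sensitivity(self):
        u = random_positive_definite(np.random.default_rng(8))
        assert xp.merritt_cc(u, 1.5 * u).cc < 1.0


def _gauss3d_integral(f, frame_cov, n_nodes=48, half_width=9.0):
    """Tensor-product Gauss–Legendre integral of ``f`` over a box adapted to
    the eigenframe and per-axis widths of ``frame_cov``."""
    evals, evecs = np.linalg.eigh(frame_cov)
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    axes = [x * half_width * np.sqrt(ev) for ev in evals]
    wts3 = [w * half_width * np.sqrt(ev) for ev in evals]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    pts = grid @ evecs.T
    wts = (wts3[0][:, None, None] * wts3[1][None, :, None]
           * wts3[2][None, None, :]).ravel()
    return float(wts @ f(pts))


def _gaussian_product_cc_quadrature(u, v, n_nodes=48, half_width=9.0):
    """CC by brute-force quadrature: each of the three Gaussian integrals is
    evaluated on a grid scaled to its own integrand (the pointwise product of
    two Gaussians is a Gaussian with covariance (U1^-1 + U2^-1)^-1)."""

    def pdf(cov):
        inv = np.linalg.inv(cov)
        det = np.linalg.det(cov)

        def f(pts):
            return (2 * np.pi) ** -1.5 * det**-0.5 * np.exp(
                -0.5 * np.einsum("ki,ij,kj->k", pts, inv, pts))

        return f

    p1, p2 = pdf(u), pdf(v)
    cov_12 = np.linalg.inv(np.linalg.inv(u) + np.linalg.inv(v))
    num = _gauss3d_integral(lambda p: p1(p) * p2(p), cov_12, n_nodes, half_width)
    den1 = _gauss3d_integral(lambda p: p1(p) ** 2, 0.5 * u, n_nodes, half_width)
    den2 = _gauss3d_integral(lambda p: p2(p) ** 2, 0.5 * v, n_nodes, half_width)
    return num / np.sqrt(den1 * den2)


class TestIsotropicScaleAndBonds:
    def test_exact_cases(self):
        rng = np.random.default_rng(10)
        refs = [random_positive_definite(rng) for _ in range(6)]
        assert xp.fit_isotropic_scale(refs, refs) == pytest.approx(1.0, abs=1e-14)
        targets = [u / 0.9 for u in refs]
        assert xp.fit_isotropic_scale(refs, targets) == pytest.approx(0.9, abs=1e-12)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(12)
        refs = [random_positive_definite(rng) for _ in range(5)]
        targets = [u * 1.1 + 0.001 * random_positive_definite(rng) for u in refs]
        q_fit = xp.fit_isotropic_scale(refs, targets)
        qs = np.linspace(q_fit - 0.05, q_fit + 0.05, 100001)
        loss = [sum(np.sum((r - q * t) ** 2) for r, t in zip(refs, targets)) for q in qs]
        assert q_fit == pytest.approx(qs[int(np.argmin(loss))], abs=1e-6)

    def test_ueq_ratio_estimator(self):
        rng = np.random.default_rng(13)
        refs = [random_positive_definite(rng) for _ in range(4)]
        targets = [u / 0.8 for u in refs]
        q = xp.fit_isotropic_scale(refs, targets, estimator="ueq_ratio")
        assert q == pytest.approx(0.8, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(AdpError):
            xp.fit_isotropic_scale([], [])
        with pytest.raises(AdpError):
            xp.fit_isotropic_scale([np.eye(3)], [])

    def test_bond_length_stats(self):
        assert xp.bond_length_stats([1.0, 1.1], [1.0, 1.1]) == (0.0, 0.0)
        mad, md = xp.bond_length_stats([1.010, 0.990], [1.0, 1.0], unit="mangstrom")
        assert mad == pytest.approx(10.0)
        assert md == pytest.approx(0.0, abs=1e-12)
        rng = np.random.default_rng(14)
        x, r = rng.normal(1.0, 0.01, 9), rng.normal(1.0, 0.01, 9)
        mad, md = xp.bond_length_stats(x, r)
        assert mad == pytest.approx(np.mean(np.abs(x - r)))
        assert md == pytest.approx(np.mean(x - r))
        with pytest.raises(AdpError):
            xp.bond_length_stats([1.0], [1.0, 2.0])


class TestConventions:
    def test_ucif_roundtrip(self):
        cell = xp.UnitCell(6.1, 7.2, 8.3, 95.0, 101.0, 78.0)
        u = random_positive_definite(np.random.default_rng(15))
        back = xp.ucif_to_ucart(cell, xp.ucart_to_ucif(cell, u))
        np.testing.assert_allclose(back, u, atol=1e-14)

    def test_orthorhombic_cif_equals_cartesian(self):
        # for an orthorhombic cell the CIF and Cartesian conventions coincide
        cell = xp.UnitCell(6.0, 5.0, 4.0)
        u = random_positive_definite(np.random.default_rng(16))
        np.testing.assert_allclose(xp.ucart_to_ucif(cell, u), u, atol=1e-12)

    def test_adp_tensor_symmetry_enforced(self):
        with pytest.raises(AdpError):
            xp.AdpTensor(np.array([[1.0, 0.1, 0], [0, 1, 0], [0, 0, 1.0]]))
        t = xp.AdpTensor(0.02 * np.eye(3), label="H1")
        assert t.is_isotropic()
        assert not xp.AdpTensor(np.diag([0.02, 0.03, 0.02])).is_isotropic()

    def test_compare_adp_pair_handles_isotropic(self):
        rec = xp.compare_adp_pair(0.02 * np.eye(3), 0.02 * np.eye(3))
        assert rec.msd_corr is None
        assert rec.ovl == pytest.approx(1.0)
        assert rec.ueq_ratio == pytest.approx(1.0)
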