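"""Similarity statistics for anisotropic displacement parameters (ADPs).

An ADP is a symmetric 3x3 tensor U (A^2, Cartesian convention here); the
mean-square displacement projected on a unit direction n is
MSD_n(U) = n^T U n, and U_eq = tr(U)/3 is its average over directions.

The statistics implemented:

- ``msd_corr``: Pearson-style correlation of the two directional MSD fields
  over uniformly distributed directions.  With the isotropic fourth-moment
  identity <n_i n_j n_k n_l> = (d_ij d_kl + d_ik d_jl + d_il d_jk)/15 the
  covariance reduces to cov = (2/45)[3 tr(U1 U2) - tr U1 tr U2], giving the
  closed form used by the analytic path; a Lebedev-class 5810-point
  quadrature path is kept as the independent route.  Scale- and
  shift-invariant (U -> aU + cI), undefined for isotropic tensors.
- ``gaussian_overlap``: overlapping coefficient OVL = 1 - eta of the two
  zero-mean trivariate normal displacement distributions,
  eta = (1/2) int |p1 - p2| d^3u, plus the percent-scaled eta_r = 100 eta.
- ``merritt_cc``: closed-form Gaussian correlation coefficient
  CC = 8^(1/2) (det U1 det U2)^(1/4) / det(U1 + U2)^(1/2) and the
  S12 = 100 (1 - CC) index.
- ``fit_isotropic_scale``: the single scale factor q best mapping one ADP
  set onto a reference set.
- ``bond_length_stats``: <|dd|> and <dd> between aligned bond-length lists.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple, Sequence

import numpy as np
from scipy.special import erf

from .quadrature import SphericalGrid, sphere_grid


class AdpError(ValueError):
    pass


class IsotropicAdpError(AdpError):
    """MSD_corr is undefined for isotropic ADPs (zero directional variance)."""


@dataclasses.dataclass(frozen=True)
class AdpTensor:
    """Symmetric Cartesian displacement tensor U (A^2) with an atom label."""

    u: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        u = np.asarray(self.u, float).reshape(3, 3)
        if not np.allclose(u, u.T, atol=1e-12):
            raise AdpError(f"U must be symmetric to 1e-12 (label {self.label!r})")
        object.__setattr__(self, "u", 0.5 * (u + u.T))

    @property
    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.u)

    @property
    def u_eq(self) -> float:
        return float(np.trace(self.u)) / 3.0

    def is_isotropic(self, tol: float = 1e-9) -> bool:
        ev = self.eigenvalues
        scale = max(abs(self.u_eq), np.max(np.abs(ev)), 1e-300)
        return float(ev[-1] - ev[0]) / scale < tol

    def is_positive_definite(self) -> bool:
        return bool(np.all(self.eigenvalues > 0))


def _as_matrix(u) -> np.ndarray:
    if isinstance(u, AdpTensor):
        return u.u
    m = np.asarray(u, float).reshape(3, 3)
    return AdpTensor(m).u


def msd(u, direction, *, strict: bool = False) -> float:
    """Directional mean-square displacement n^T U n (A^2)."""
    m = _as_matrix(u)
    n = np.asarray(direction, float).reshape(3)
    norm = np.linalg.norm(n)
    if abs(norm - 1.0) > 1e-9:
        if strict:
            raise AdpError(f"direction is not a unit vector (|n| = {norm})")
        n = n / norm
    return float(n @ m @ n)


def rmsd(u, direction, **kw) -> float:
    return float(np.sqrt(msd(u, direction, **kw)))


def u_eq(u) -> float:
    """Equivalent isotropic displacement tr(U)/3: the spherical average of MSD."""
    return float(np.trace(_as_matrix(u))) / 3.0


def _msd_variance(m: np.ndarray) -> float:
    # var over uniform directions: (2/45) [3 tr(U^2) - (tr U)^2]
    return (2.0 / 45.0) * (3.0 * float(np.trace(m @ m)) - float(np.trace(m)) ** 2)


def msd_corr(u1, u2, method: str = "analytic",
             sgrid: SphericalGrid | None = None,
             isotropy_tol: float = 1e-9) -> float:
    """Correlation of the directional MSD fields of two ADPs, in [-1, 1].

    ``method="analytic"`` uses the closed form from the fourth-moment
    identity; ``method="quadrature"`` averages over a 5810-class spherical
    grid.  Raises :class:`IsotropicAdpError` when either tensor is
    isotropic (relative eigenvalue spread below ``isotropy_tol``).
    """
    m1, m2 = _as_matrix(u1), _as_matrix(u2)
    for m in (m1, m2):
        if AdpTensor(m).is_isotropic(isotropy_tol):
            raise IsotropicAdpError("MSD_corr is undefined for isotropic ADPs")
    if method == "analytic":
        cov = (2.0 / 45.0) * (3.0 * float(np.trace(m1 @ m2))
                              - float(np.trace(m1)) * float(np.trace(m2)))
        return cov / np.sqrt(_msd_variance(m1) * _msd_variance(m2))
    if method == "quadrature":
        g = sgrid if sgrid is not None else sphere_grid(5810)
        f1 = np.einsum("ki,ij,kj->k", g.points, m1, g.points)
        f2 = np.einsum("ki,ij,kj->k", g.points, m2, g.points)
        mu1, mu2 = g.weights @ f1, g.weights @ f2
        cov = g.weights @ ((f1 - mu1) * (f2 - mu2))
        v1 = g.weights @ (f1 - mu1) ** 2
        v2 = g.weights @ (f2 - mu2) ** 2
        return float(cov / np.sqrt(v1 * v2))
    raise AdpError(f"unknown msd_corr method {method!r}")


class OverlapResult(NamedTuple):
    ovl: float
    eta: float
    eta_r: float


def _gauss_abs_diff_radial(q: float, log_d: float) -> float:
    """int_0^inf |e^(-r^2/2) - D e^(-q r^2/2)| r^2 dr, D = exp(log_d), q > 0.

    The two Gaussians cross at most once for r > 0; both branch integrals
    are expressed through A(x) = int_0^x t^2 e^(-t^2/2) dt.
    """
    sq2pi = np.sqrt(np.pi / 2.0)

    def a_func(x: float) -> float:
        return sq2pi * erf(x / np.sqrt(2.0)) - x * np.exp(-0.5 * x * x)

    def part(gamma: float, lo: float, hi: float | None) -> float:
        g = np.sqrt(gamma)
        top = sq2pi if hi is None else a_func(g * hi)
        return (top - a_func(g * lo)) / gamma ** 1.5

    d = np.exp(log_d)
    r_cross = None
    if abs(q - 1.0) > 1e-15:
        r2 = 2.0 * log_d / (q - 1.0)
        if r2 > 0:
            r_cross = np.sqrt(r2)
    if r_cross is None:
        return abs(part(1.0, 0.0, None) - d * part(q, 0.0, None))
    lo = abs(part(1.0, 0.0, r_cross) - d * part(q, 0.0, r_cross))
    hi = abs(part(1.0, r_cross, None) - d * part(q, r_cross, None))
    return lo + hi


def eta_r_from_eta(eta: float) -> float:
    """Percent rescaling of the PDF difference norm: eta_r = 100 * eta.

    Isolated here so an alternative rescaling can be swapped in without
    touching callers.
    """
    return 100.0 * eta


def gaussian_overlap(u1, u2, sgrid: SphericalGrid | None = None) -> OverlapResult:
    """Overlapping coefficient of the displacement PDFs of two ADPs.

    p_i is the zero-mean trivariate normal with covariance U_i;
    eta = (1/2) int |p1 - p2|, ovl = 1 - eta, eta_r = 100 eta (percent).

    Evaluated in the frame whitening U1 (p1 becomes standard normal, p2
    becomes N(0, diag(lambda)) with lambda the eigenvalues of
    U1^(-1/2) U2 U1^(-1/2)): the radial factor is integrated exactly through
    the single sign change, the angular factor on a Lebedev-class grid.
    The construction is invariant under any common invertible linear
    transform of both covariances.
    """
    m1, m2 = _as_matrix(u1), _as_matrix(u2)
    w1, v1 = np.linalg.eigh(m1)
    if np.any(w1 <= 0) or np.any(np.linalg.eigvalsh(m2) <= 0):
        raise AdpError("gaussian_overlap requires positive-definite ADPs")
    inv_sqrt = v1 @ np.diag(1.0 / np.sqrt(w1)) @ v1.T
    lam = np.linalg.eigvalsh(inv_sqrt @ m2 @ inv_sqrt)
    g = sgrid if sgrid is not None else sphere_grid(590)
    q = (g.points ** 2) @ (1.0 / lam)          # per-direction decay of whitened p2
    log_d = -0.5 * float(np.sum(np.log(lam)))  # log det Lambda^(-1/2)
    radial = np.array([_gauss_abs_diff_radial(qi, log_d) for qi in q])
    eta = 0.5 * (2.0 * np.pi) ** -1.5 * 4.0 * np.pi * float(g.weights @ radial)
    eta = min(max(eta, 0.0), 1.0)
    return OverlapResult(1.0 - eta, eta, eta_r_from_eta(eta))


class CcResult(NamedTuple):
    cc: float
    s12: float


def merritt_cc(u1, u2) -> CcResult:
    """Gaussian correlation coefficient CC and the S12 = 100(1 - CC) index."""
    m1, m2 = _as_matrix(u1), _as_matrix(u2)
    d1, d2 = np.linalg.det(m1), np.linalg.det(m2)
    if d1 <= 0 or d2 <= 0 or np.any(np.linalg.eigvalsh(m1) <= 0) \
            or np.any(np.linalg.eigvalsh(m2) <= 0):
        raise AdpError("merritt_cc requires positive-definite ADPs")
    cc = np.sqrt(8.0) * (d1 * d2) ** 0.25 / np.sqrt(np.linalg.det(m1 + m2))
    return CcResult(float(cc), 100.0 * (1.0 - float(cc)))


def fit_isotropic_scale(reference_set: Sequence, target_set: Sequence,
                        estimator: str = "frobenius") -> float:
    """Best single factor q minimizing sum ||U_ref - q U_tgt||_F^2.

    ``estimator="frobenius"`` (default) gives
    q = sum tr(U_ref U_tgt) / sum tr(U_tgt^2); ``estimator="ueq_ratio"``
    uses the ratio of mean equivalent isotropic displacements instead.
    """
    if len(reference_set) == 0 or len(reference_set) != len(target_set):
        raise AdpError("reference and target sets must be non-empty and aligned")
    refs = [_as_matrix(u) for u in reference_set]
    tgts = [_as_matrix(u) for u in target_set]
    if estimator == "frobenius":
        num = sum(float(np.trace(r @ t)) for r, t in zip(refs, tgts))
        den = sum(float(np.trace(t @ t)) for t in tgts)
        return num / den
    if estimator == "ueq_ratio":
        return float(np.mean([u_eq(r) for r in refs]) / np.mean([u_eq(t) for t in tgts]))
    raise AdpError(f"unknown estimator {estimator!r}")


def bond_length_stats(bonds_x: Sequence[float], bonds_ref: Sequence[float],
                      *, unit: str = "angstrom") -> tuple[float, float]:
    """(<|dd|>, <dd>) between aligned bond-length lists; ``unit="mangstrom"`` scales by 1000."""
    x = np.asarray(bonds_x, float)
    r = np.asarray(bonds_ref, float)
    if x.size == 0 or x.shape != r.shape:
        raise AdpError("bond lists must be non-empty and aligned")
    scale = 1000.0 if unit == "mangstrom" else 1.0
    d = x - r
    return float(np.mean(np.abs(d))) * scale, float(np.mean(d)) * scale


@dataclasses.dataclass(frozen=True)
class AdpComparison:
    """Full per-pair similarity record; ``msd_corr`` is None for isotropic input."""

    msd_corr: float | None
    ovl: float
    eta: float
    eta_r: float
    cc: float
    s12: float
    ueq_ratio: float


def compare_adp_pair(u_x, u_ref) -> AdpComparison:
    """All shipped similarity indices for one ADP pair (x vs reference)."""
    try:
        mc = msd_corr(u_x, u_ref)
    except IsotropicAdpError:
        mc = None
    ov = gaussian_overlap(u_x, u_ref)
    cc = merritt_cc(u_x, u_ref)
    return AdpComparison(mc, ov.ovl, ov.eta, ov.eta_r, cc.cc, cc.s12,
                         u_eq(u_x) / u_eq(u_ref))


def ucif_to_ucart(cell, u_cif: np.ndarray) -> np.ndarray:
    """Convert a CIF-convention aniso U (reciprocal-basis) to Cartesian A^2.

    U_cart = A N U_cif N^T A^T with A the orthogonalization matrix and
    N = diag(a*, b*, c*).
    """
    a_mat = cell.orth_matrix
    rec = np.linalg.norm(cell.frac_matrix, axis=0)  # a*, b*, c* lengths
    n_mat = np.diag(rec)
    u = np.asarray(u_cif, float).reshape(3, 3)
    return a_mat @ n_mat @ u @ n_mat @ a_mat.T


def ucart_to_ucif(cell, u_cart: np.ndarray) -> np.ndarray:
    a_mat = cell.orth_matrix
    rec = np.linalg.norm(cell.frac_matrix, axis=0)
    inv = np.linalg.inv(a_mat @ np.diag(rec))
    u = np.asarray(u_cart, float).reshape(3, 3)
    return inv @ u @ inv.T
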