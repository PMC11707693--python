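"""Spherical and radial grids for atom-centred numerical integration.

Angular integration uses product grids with the same algebraic exactness as
the classic Lebedev–Laikov grids: ``sphere_grid(nominal_size)`` accepts the
standard Lebedev point counts (590, 5810, ...) and returns a
Gauss–Legendre(cos theta) x uniform(phi) grid that integrates spherical
harmonics exactly up to the order associated with that count (order 41 for
the 590-point grid, 131 for 5810).  The nominal size is kept as a label; the
actual number of nodes differs (it is ``(order//2+1) * (order+1)``).

Radial integration uses the Mura–Knowles Log3 mapping
``r_i = -alpha * ln(1 - (i/(N+1))^3)`` with chain-rule weights; the default
is a 75-point grid with alpha = 5 bohr for every element.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

logger = logging.getLogger(__name__)


class GridError(ValueError):
    """Raised for unsupported grid configurations."""


class NumericalError(ArithmeticError):
    """Raised when an integrand produces non-finite values."""


#: Standard Lebedev grid sizes and their polynomial exactness orders.
LEBEDEV_ORDER = {
    6: 3, 14: 5, 26: 7, 38: 9, 50: 11, 74: 13, 86: 15, 110: 17,
    146: 19, 170: 21, 194: 23, 230: 25, 266: 27, 302: 29, 350: 31,
    434: 35, 590: 41, 770: 47, 974: 53, 1202: 59, 1454: 65, 1730: 71,
    2030: 77, 2354: 83, 2702: 89, 3074: 95, 3470: 101, 3890: 107,
    4334: 113, 4802: 119, 5294: 125, 5810: 131,
}


@dataclasses.dataclass(frozen=True)
class SphericalGrid:
    """Unit-sphere quadrature: ``sum w_j f(n_j)`` approximates the spherical average."""

    points: np.ndarray   # (m, 3) unit vectors
    weights: np.ndarray  # (m,), positive, sum to 1
    nominal_size: int
    degree: int

    @property
    def size(self) -> int:
        return len(self.weights)

    def average(self, values: np.ndarray) -> float:
        """Spherical average of ``values`` sampled on the grid points."""
        return float(self.weights @ np.asarray(values, float))


@dataclasses.dataclass(frozen=True)
class RadialGrid:
    """Semi-infinite radial quadrature: ``sum w_i f(r_i)`` approximates ``int_0^inf f dr``."""

    radii: np.ndarray
    weights: np.ndarray
    alpha: float
    size: int


def sphere_grid(nominal_size: int = 590, *, strict: bool = False) -> SphericalGrid:
    """Build a spherical grid with the exactness of the named Lebedev size.

    Unsupported sizes snap to the nearest supported one (with a logged note),
    or raise :class:`GridError` when ``strict`` is set.
    """
    if nominal_size not in LEBEDEV_ORDER:
        if strict:
            raise GridError(
                f"unsupported nominal size {nominal_size}; "
                f"supported: {sorted(LEBEDEV_ORDER)}")
        nearest = min(LEBEDEV_ORDER, key=lambda s: (abs(s - nominal_size), s))
        logger.info("spherical grid size %d unsupported, using %d", nominal_size, nearest)
        nominal_size = nearest
    degree = LEBEDEV_ORDER[nominal_size]
    n_theta = degree // 2 + 1          # Gauss-Legendre exact to 2*n_theta - 1 >= degree
    n_phi = degree + 1                 # uniform azimuth exact for |m| <= degree
    ct, wt = np.polynomial.legendre.leggauss(n_theta)
    st = np.sqrt(1.0 - ct**2)
    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    cp, sp = np.cos(phi), np.sin(phi)
    pts = np.empty((n_theta * n_phi, 3))
    pts[:, 0] = np.outer(st, cp).ravel()
    pts[:, 1] = np.outer(st, sp).ravel()
    pts[:, 2] = np.repeat(ct, n_phi)
    wts = np.repeat(wt / 2.0 / n_phi, n_phi)
    return SphericalGrid(pts, wts, nominal_size, degree)


def radial_grid(size: int = 75, alpha: float = 5.0) -> RadialGrid:
    """Mura–Knowles Log3 radial grid with ``size`` nodes and map length ``alpha`` (bohr)."""
    if size < 2:
        raise GridError("radial grid needs at least 2 nodes")
    if alpha <= 0:
        raise GridError("alpha must be positive")
    i = np.arange(1, size + 1, dtype=float)
    x = i / (size + 1)
    radii = -alpha * np.log1p(-x**3)
    weights = alpha * 3.0 * x**2 / ((size + 1) * (1.0 - x**3))
    return RadialGrid(radii, weights, float(alpha), size)


def product_grid(center, sgrid: SphericalGrid, rgrid: RadialGrid):
    """Atom-centred 3D nodes and volume weights.

    Returns ``(points, weights)`` with ``points`` of shape (n_rad*n_ang, 3)
    and ``weights`` such that ``sum w_k f(points_k)`` approximates the
    integral of f over all space.
    """
    center = np.asarray(center, float).reshape(3)
    pts = center + rgrid.radii[:, None, None] * sgrid.points[None, :, :]
    w = 4.0 * np.pi * (rgrid.weights * rgrid.radii**2)[:, None] * sgrid.weights[None, :]
    return pts.reshape(-1, 3), w.ravel()


def atom_centered_integrate(f, center, sgrid: SphericalGrid | None = None,
                            rgrid: RadialGrid | None = None) -> float:
    """Integrate the scalar field ``f`` over all space on a grid centred at ``center``.

    ``f`` must accept an (m, 3) array of Cartesian points and return (m,)
    values; non-finite values raise :class:`NumericalError` naming the first
    offending point.
    """
    sgrid = sgrid if sgrid is not None else sphere_grid(590)
    rgrid = rgrid if rgrid is not None else radial_grid(75, 5.0)
    pts, w = product_grid(center, sgrid, rgrid)
    vals = np.asarray(f(pts), dtype=float)
    bad = ~np.isfinite(vals)
    if bad.any():
        k = int(np.flatnonzero(bad)[0])
        raise NumericalError(f"integrand non-finite ({vals[k]!r}) at point {pts[k]}")
    return float(w @ vals)
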