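"""Analytic atomic and toy molecular electron densities.

The promolecule — a superposition of spherically averaged isolated-atom
densities placed at the nuclear positions — is the raw material of every
stockholder partition.  This module ships a single-zeta Slater 1s family as
the default isolated-atom model (densities are source-agnostic: anything
exposing the :class:`RadialDensity` protocol can be dropped in), plus the
two-centre one-electron bonding density used throughout the test suite to
exercise partition behaviour between a bonded pair.

All densities work in atomic units internally: positions and radii in bohr,
densities in e/bohr^3.  Conversion to angstrom happens only at the
crystallographic boundary (see :mod:`exphar.form_factors`).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import math
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

#: CODATA bohr radius in angstrom.
BOHR_IN_ANGSTROM = 0.529177210903


class DensityError(ValueError):
    """Raised for invalid density evaluations or configurations."""


@runtime_checkable
class RadialDensity(Protocol):
    """Spherically averaged isolated-atom density rho°(r), r in bohr."""

    element: str
    electron_count: float
    unit_system: str

    def __call__(self, r: np.ndarray) -> np.ndarray: ...

    def log_density(self, r: np.ndarray) -> np.ndarray: ...


def _check_radius(r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise DensityError("radius must be non-negative")
    return r


@dataclasses.dataclass(frozen=True)
class SlaterDensity:
    """Single-zeta Slater 1s density, ``N (zeta^3/pi) exp(-2 zeta r)``.

    Parameters
    ----------
    element:
        Element label (used for lookups, e.g. in zeta tables).
    zeta:
        Screening exponent in bohr^-1; must be positive.
    electron_count:
        Number of electrons N the density integrates to.
    nuclear_charge:
        Z used for atomic charges; defaults to ``electron_count``.
    """

    element: str
    zeta: float
    electron_count: float = 1.0
    nuclear_charge: float | None = None
    unit_system: str = "bohr"

    def __post_init__(self) -> None:
        if self.zeta <= 0:
            raise DensityError(f"zeta must be positive, got {self.zeta}")
        if self.electron_count < 0:
            raise DensityError("electron_count must be non-negative")
        if self.nuclear_charge is None:
            object.__setattr__(self, "nuclear_charge", float(self.electron_count))

    def __call__(self, r: np.ndarray) -> np.ndarray:
        r = _check_radius(r)
        return self.electron_count * (self.zeta**3 / np.pi) * np.exp(-2.0 * self.zeta * r)

    def log_density(self, r: np.ndarray) -> np.ndarray:
        """log rho°(r), exact for arbitrarily large r (no underflow)."""
        r = _check_radius(r)
        if self.electron_count == 0:
            return np.full_like(r, -np.inf)
        return math.log(self.electron_count * self.zeta**3 / np.pi) - 2.0 * self.zeta * r


def radial_density(element: str, zeta: float, r, *, electron_count: float = 1.0):
    """Evaluate the single-zeta Slater 1s density for ``element`` at radius ``r``."""
    return SlaterDensity(element, zeta, electron_count)(r)


def load_zeta_table() -> dict[str, tuple[float, float, float]]:
    """Packaged per-element defaults: ``{element: (zeta, electrons, Z)}``."""
    table: dict[str, tuple[float, float, float]] = {}
    text = (importlib.resources.files("exphar") / "data" / "slater_zeta.txt").read_text()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        el, zeta, nel, z = line.split()
        table[el] = (float(zeta), float(nel), float(z))
    return table


def element_density(element: str, *, zeta: float | None = None,
                    table: dict | None = None) -> SlaterDensity:
    """Build the default isolated-atom density for ``element``.

    ``zeta`` overrides the packaged value; unknown elements require an
    explicit ``zeta`` (electron count then defaults to 1).
    """
    tab = table if table is not None else load_zeta_table()
    if element in tab:
        z0, nel, z = tab[element]
        return SlaterDensity(element, zeta if zeta is not None else z0, nel, z)
    if zeta is None:
        raise DensityError(f"no zeta default for element {element!r}; pass zeta=")
    return SlaterDensity(element, zeta, 1.0)


@dataclasses.dataclass(frozen=True)
class PlacedAtom:
    """A radial density placed at a Cartesian position (bohr)."""

    density: RadialDensity
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float).reshape(3)
        object.__setattr__(self, "position", pos)


class PromoleculeDensity:
    """Sum of placed isolated-atom densities: rho_pro(r) = sum_A rho°_A(|r - x_A|)."""

    def __init__(self, sites: Sequence[PlacedAtom]):
        if len(sites) == 0:
            raise DensityError("promolecule requires at least one site")
        self.sites = tuple(sites)

    @property
    def electron_count(self) -> float:
        return float(sum(s.density.electron_count for s in self.sites))

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Total promolecule density at Cartesian ``points`` (..., 3) in bohr."""
        pts = np.asarray(points, dtype=float)
        out = np.zeros(pts.shape[:-1])
        for site in self.sites:
            r = np.linalg.norm(pts - site.position, axis=-1)
            out += site.density(r)
        return out


def promolecule_density(sites: Sequence[PlacedAtom], point) -> np.ndarray:
    """Convenience wrapper: promolecule density at ``point``."""
    return PromoleculeDensity(sites).evaluate(point)


def slater_overlap_1s(zeta: float, separation: float) -> float:
    """Closed-form 1s–1s overlap integral S for equal exponents.

    S(R) = exp(-zeta R) (1 + zeta R + (zeta R)^2 / 3), R in bohr.
    """
    x = zeta * separation
    return math.exp(-x) * (1.0 + x + x * x / 3.0)


def slater_overlap_1s_quadrature(zeta: float, separation: float, size: int = 60) -> float:
    """1s–1s overlap by numerical quadrature in prolate spheroidal coordinates.

    With nuclei a distance R apart and a = R/2, the orbital product depends
    only on lambda = (r_A + r_B)/R, so
    S = 2 zeta^3 a^3 int_1^inf exp(-2 zeta a lambda) (2 lambda^2 - 2/3) dlambda,
    evaluated with Gauss–Legendre nodes on an exponentially mapped interval.
    Single-centre spherical grids converge slowly on this cuspy two-centre
    product; the spheroidal frame removes the cusp entirely.
    """
    if zeta <= 0 or separation <= 0:
        raise DensityError("zeta and separation must be positive")
    a = 0.5 * separation
    beta = 2.0 * zeta * a
    # substitute u = beta (lambda - 1): S = C int_0^inf e^-u (2(1+u/beta)^2 - 2/3) du
    u, wu = np.polynomial.laguerre.laggauss(size)
    integrand = 2.0 * (1.0 + u / beta) ** 2 - 2.0 / 3.0
    return float(2.0 * zeta**3 * a**3 * math.exp(-beta) / beta * np.sum(wu * integrand))


class TwoCenterDensity:
    """One-electron two-centre bonding density, |N(phi_A + phi_B)|^2.

    phi are 1s orbitals with exponent ``zeta`` on nuclei A and B separated by
    ``separation`` bohr along ``axis``; N^2 = 1/[2(1+S)] with S the 1s–1s
    overlap, so the density integrates to one electron.  This is the simplest
    model of a covalently bonded pair and drives most partition tests.
    """

    electron_count = 1.0

    def __init__(self, separation: float, *, zeta: float = 1.0,
                 center: np.ndarray | None = None, axis: np.ndarray | None = None):
        if separation <= 0:
            raise DensityError("internuclear separation must be positive")
        if zeta <= 0:
            raise DensityError("zeta must be positive")
        self.separation = float(separation)
        self.zeta = float(zeta)
        c = np.zeros(3) if center is None else np.asarray(center, float).reshape(3)
        ax = np.array([0.0, 0.0, 1.0]) if axis is None else np.asarray(axis, float)
        ax = ax / np.linalg.norm(ax)
        self.position_a = c - 0.5 * separation * ax
        self.position_b = c + 0.5 * separation * ax
        self.overlap = slater_overlap_1s(self.zeta, self.separation)
        self._norm_sq = 1.0 / (2.0 * (1.0 + self.overlap))
        # Sites advertise half an electron each so a promolecule spec built
        # from them carries the correct total electron count.
        half = SlaterDensity("H", self.zeta, 0.5, nuclear_charge=1.0)
        self.sites = (PlacedAtom(half, self.position_a), PlacedAtom(half, self.position_b))

    def _orbital(self, points: np.ndarray, center: np.ndarray) -> np.ndarray:
        r = np.linalg.norm(np.asarray(points, float) - center, axis=-1)
        return math.sqrt(self.zeta**3 / np.pi) * np.exp(-self.zeta * r)

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        psi = self._orbital(points, self.position_a) + self._orbital(points, self.position_b)
        return self._norm_sq * psi**2


def toy_two_center_density(separation: float, point) -> np.ndarray:
    """H2+-like density at ``point`` for nuclei ``separation`` bohr apart (z axis)."""
    return TwoCenterDensity(separation).evaluate(point)
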