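"""Aspherical atomic form factors and .tsc scattering-factor tables.

An atomic form factor here is the Fourier transform of a stockholder-
partitioned static atomic density, evaluated about the atom's own nucleus
(atom-local phase convention):

    f_A(h) = int w_A(r) rho(r) exp(2 pi i h . (r - x_A)) d^3 r

The lattice phase exp(2 pi i h . x_A) is applied later, in the structure-
factor engine, which matches how .tsc files are consumed: per-atom,
position-free complex scattering factors tabulated on a reflection list.

Integration uses the atom-centred product grid of :mod:`exphar.quadrature`;
the hot phase sum is compiled with numba and shared across sites (the grid
offsets, hence the phase matrix, are site-independent).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import gemmi
import numba
import numpy as np

from .atomic_densities import (BOHR_IN_ANGSTROM, PlacedAtom, RadialDensity,
                               element_density, load_zeta_table)
from .partition import PartitionSpec, stockholder_weights
from .quadrature import RadialGrid, SphericalGrid, product_grid, radial_grid, sphere_grid


class FormFactorError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class UnitCell:
    """Crystallographic unit cell (lengths in angstrom, angles in degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def _gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def volume(self) -> float:
        return self._gemmi().volume

    @property
    def orth_matrix(self) -> np.ndarray:
        """Fractional -> Cartesian (angstrom) transform."""
        return np.array(self._gemmi().orth.mat.tolist())

    @property
    def frac_matrix(self) -> np.ndarray:
        return np.array(self._gemmi().frac.mat.tolist())

    def orthogonalize(self, frac) -> np.ndarray:
        return np.asarray(frac, float) @ self.orth_matrix.T

    def fractionalize(self, cart) -> np.ndarray:
        return np.asarray(cart, float) @ self.frac_matrix.T

    def reciprocal_vectors(self, hkl) -> np.ndarray:
        """Cartesian reciprocal vectors (A^-1) for integer triples ``hkl``."""
        return np.atleast_2d(np.asarray(hkl, float)) @ self.frac_matrix

    def d_spacing(self, hkl) -> np.ndarray:
        s = np.linalg.norm(self.reciprocal_vectors(hkl), axis=-1)
        return 1.0 / s


def spherical_form_factor(rho: RadialDensity, s, rgrid: RadialGrid | None = None,
                          *, units: str = "angstrom") -> np.ndarray:
    """Form factor of a spherical density: f(s) = 4 pi int rho sinc(2 pi s r) r^2 dr.

    ``s`` is |h| in A^-1 by default (``units="au"`` for bohr^-1); the radial
    integral runs over bohr, matching the density's unit system.  f(0) is the
    electron count.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise FormFactorError("s must be non-negative")
    s_au = s * BOHR_IN_ANGSTROM if units == "angstrom" else s
    rgrid = rgrid if rgrid is not None else radial_grid(150, 5.0)
    r, w = rgrid.radii, rgrid.weights
    # np.sinc(x) = sin(pi x)/(pi x), so sinc(2 pi s r) = np.sinc(2 s r)
    kern = np.sinc(2.0 * np.multiply.outer(s_au, r))
    vals = 4.0 * np.pi * kern @ (w * r**2 * rho(r))
    return vals if vals.shape else float(vals)


@numba.njit(fastmath=True, cache=False)
def _phase_sum(h_ang: np.ndarray, offsets_ang: np.ndarray, coeff: np.ndarray) -> np.ndarray:
    """out[a, i] = sum_j coeff[a, j] * exp(2 pi i h_i . offset_j)."""
    nh = h_ang.shape[0]
    npts = offsets_ang.shape[0]
    nsites = coeff.shape[0]
    out = np.zeros((nsites, nh), dtype=np.complex128)
    for i in range(nh):
        hx, hy, hz = h_ang[i, 0], h_ang[i, 1], h_ang[i, 2]
        for j in range(npts):
            arg = 2.0 * np.pi * (hx * offsets_ang[j, 0] + hy * offsets_ang[j, 1]
                                 + hz * offsets_ang[j, 2])
            ph = complex(math.cos(arg), math.sin(arg))
            for a in range(nsites):
                out[a, i] += coeff[a, j] * ph
    return out


def _partition_coefficients(spec: PartitionSpec, total, site_indices, offsets_bohr,
                            grid_weights) -> np.ndarray:
    """Quadrature coefficients w_grid * w_A * rho for each requested site.

    The same offset cloud is recentred on every site, so the phase matrix in
    the Fourier sum can be shared.
    """
    coeff = np.empty((len(site_indices), len(grid_weights)))
    for k, a in enumerate(site_indices):
        pts = spec.sites[a].position + offsets_bohr
        w = np.atleast_2d(stockholder_weights(pts, spec))[:, a]
        coeff[k] = grid_weights * w * np.asarray(total.evaluate(pts), float)
    return coeff


def aspherical_form_factors(site_indices: Sequence[int], spec: PartitionSpec, total,
                            h_cart: np.ndarray,
                            sgrid: SphericalGrid | None = None,
                            rgrid: RadialGrid | None = None) -> np.ndarray:
    """Numerical f_A(h) for several sites on a shared reflection list.

    ``h_cart``: (m, 3) Cartesian reciprocal vectors in A^-1.  Returns an
    (nsites, m) complex array in the atom-local phase convention.
    """
    sgrid = sgrid if sgrid is not None else sphere_grid(590)
    rgrid = rgrid if rgrid is not None else radial_grid(75, 5.0)
    h_cart = np.atleast_2d(np.asarray(h_cart, float))
    if not np.all(np.isfinite(h_cart)):
        raise FormFactorError("non-finite reciprocal vector")
    offsets, gw = product_grid(np.zeros(3), sgrid, rgrid)
    coeff = _partition_coefficients(spec, total, list(site_indices), offsets, gw)
    return _phase_sum(np.ascontiguousarray(h_cart),
                      np.ascontiguousarray(offsets * BOHR_IN_ANGSTROM), coeff)


def aspherical_form_factor(site_index: int, spec: PartitionSpec, total, h_cart,
                           sgrid: SphericalGrid | None = None,
                           rgrid: RadialGrid | None = None):
    """Single-site convenience wrapper around :func:`aspherical_form_factors`."""
    h = np.asarray(h_cart, float)
    single = h.ndim == 1
    out = aspherical_form_factors([site_index], spec, total, np.atleast_2d(h),
                                  sgrid, rgrid)[0]
    return complex(out[0]) if single else out


@dataclasses.dataclass
class FormFactorTable:
    """Per-site complex form factors on an hkl list (the .tsc model)."""

    site_labels: tuple[str, ...]
    hkl: np.ndarray            # (m, 3) int
    values: np.ndarray         # (nsites, m) complex
    title: str = "exphar"

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, int).reshape(-1, 3)
        self.values = np.asarray(self.values, complex)
        if self.values.shape != (len(self.site_labels), len(self.hkl)):
            raise FormFactorError("values shape does not match labels x hkl")

    def for_site(self, label: str) -> np.ndarray:
        return self.values[self.site_labels.index(label)]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"TITLE: {self.title}\n")
            fh.write("SYMM: expanded\n")
            fh.write("SCATTERERS: " + " ".join(self.site_labels) + "\n")
            fh.write("DATA:\n")
            for row, vals in zip(self.hkl, self.values.T):
                cells = " ".join(f"{v.real:.10e},{v.imag:.10e}" for v in vals)
                fh.write(f"{row[0]} {row[1]} {row[2]} {cells}\n")

    @classmethod
    def read(cls, path) -> "FormFactorTable":
        labels: tuple[str, ...] = ()
        title = ""
        hkl: list[list[int]] = []
        vals: list[list[complex]] = []
        in_data = False
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if in_data:
                    parts = line.split()
                    hkl.append([int(p) for p in parts[:3]])
                    row = []
                    for cell in parts[3:]:
                        re, im = cell.split(",")
                        row.append(complex(float(re), float(im)))
                    vals.append(row)
                elif line.startswith("TITLE:"):
                    title = line[6:].strip()
                elif line.startswith("SCATTERERS:"):
                    labels = tuple(line.split(":", 1)[1].split())
                elif line.startswith("DATA:"):
                    in_data = True
                # other header keys are accepted and ignored
        return cls(labels, np.array(hkl, int), np.array(vals, complex).T, title)


def structure_partition_spec(structure, exponent: float,
                             zeta_overrides: dict[str, float] | None = None,
                             table: dict | None = None) -> PartitionSpec:
    """Promolecule partition spec for a structure's sites (positions in bohr)."""
    tab = table if table is not None else load_zeta_table()
    over = zeta_overrides or {}
    placed = []
    for site in structure.sites:
        cart_ang = structure.cell.orthogonalize(site.frac)
        dens = element_density(site.element, zeta=over.get(site.element), table=tab)
        placed.append(PlacedAtom(dens, cart_ang / BOHR_IN_ANGSTROM))
    return PartitionSpec(exponent, tuple(placed))


def build_tsc(structure, hkl_list, spec: PartitionSpec, total=None,
              sgrid: SphericalGrid | None = None,
              rgrid: RadialGrid | None = None) -> FormFactorTable:
    """Form-factor table for every (site, hkl) of a structure.

    ``total`` defaults to the promolecule of ``spec``; pass a different
    molecular density to partition, e.g., a bonding density.
    """
    hkl = np.asarray(hkl_list, int).reshape(-1, 3)
    if len(hkl) == 0:
        raise FormFactorError("empty hkl list")
    if len(np.unique(hkl, axis=0)) != len(hkl):
        raise FormFactorError("duplicate hkl in reflection list")
    if len(spec.sites) != len(structure.sites):
        raise FormFactorError("partition spec does not cover all structure sites")
    total = total if total is not None else spec.promolecule
    h_cart = structure.cell.reciprocal_vectors(hkl)
    values = aspherical_form_factors(range(len(spec.sites)), spec, total,
                                     h_cart, sgrid, rgrid)
    labels = tuple(s.label for s in structure.sites)
    return FormFactorTable(labels, hkl, values)
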