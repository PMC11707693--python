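"""Minimal aspherical-atom least-squares refinement against F^2.

The engine mirrors the outer/inner loop of Hirshfeld atom refinement on toy
P1 structures: a provider regenerates the per-atom form-factor table from
the current geometry (the macro-cycle), an inner Gauss–Newton loop refines
the free parameters against F^2 with SHELX-type weights, and the procedure
repeats until the maximum parameter shift divided by its standard
uncertainty drops below a threshold (0.1 by default).

Model:  F(h) = k sum_A occ_A f_A(h) exp(-2 pi^2 s^T U_A s) exp(2 pi i h.x_A)

with f_A the tabulated aspherical form factors (atom-local phase
convention), s the Cartesian reciprocal vector in A^-1 and U_A the
Cartesian ADP.  Derivatives are analytic.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

from .adp_metrics import ucart_to_ucif, ucif_to_ucart
from .form_factors import FormFactorTable, UnitCell


class RefinementError(ValueError):
    pass


class RankDeficiencyError(RefinementError):
    """Normal matrix is singular; carries the null-space parameter names."""

    def __init__(self, params: Sequence[str]):
        self.params = list(params)
        super().__init__(f"singular normal matrix; null-space parameters: {self.params}")


@dataclasses.dataclass
class Site:
    label: str
    element: str
    frac: np.ndarray
    u_cart: np.ndarray           # 3x3 Cartesian ADP, A^2
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.frac = np.mod(np.asarray(self.frac, float).reshape(3), 1.0)
        self.u_cart = np.asarray(self.u_cart, float).reshape(3, 3)
        if not 0.0 < self.occupancy <= 1.0:
            raise RefinementError(f"occupancy must be in (0, 1], got {self.occupancy}")


@dataclasses.dataclass
class ToyStructure:
    """P1 toy crystal: unit cell plus a list of sites."""

    cell: UnitCell
    sites: list[Site]

    def site(self, label: str) -> Site:
        for s in self.sites:
            if s.label == label:
                return s
        raise KeyError(label)

    def cart_positions(self) -> np.ndarray:
        """Cartesian site positions in angstrom."""
        return np.array([self.cell.orthogonalize(s.frac) for s in self.sites])

    def copy(self) -> "ToyStructure":
        return ToyStructure(self.cell, [
            Site(s.label, s.element, s.frac.copy(), s.u_cart.copy(), s.occupancy)
            for s in self.sites])


@dataclasses.dataclass
class ReflectionData:
    """SHELX-style F^2 data: unique hkl with intensities and uncertainties."""

    hkl: np.ndarray
    f_obs_sq: np.ndarray
    sigma: np.ndarray
    d_spacing: np.ndarray

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, int).reshape(-1, 3)
        self.f_obs_sq = np.asarray(self.f_obs_sq, float)
        self.sigma = np.asarray(self.sigma, float)
        self.d_spacing = np.asarray(self.d_spacing, float)
        if len(np.unique(self.hkl, axis=0)) != len(self.hkl):
            raise RefinementError("duplicate hkl")
        if np.any(self.sigma <= 0):
            raise RefinementError("sigma must be positive")

    @classmethod
    def from_cell(cls, cell: UnitCell, hkl, f_obs_sq, sigma) -> "ReflectionData":
        hkl = np.asarray(hkl, int).reshape(-1, 3)
        return cls(hkl, f_obs_sq, sigma, cell.d_spacing(hkl))

    def __len__(self) -> int:
        return len(self.f_obs_sq)

    def cut(self, d_min: float) -> "ReflectionData":
        """Keep exactly the reflections with d >= d_min."""
        keep = self.d_spacing >= d_min
        return ReflectionData(self.hkl[keep], self.f_obs_sq[keep],
                              self.sigma[keep], self.d_spacing[keep])


def structure_factor(structure: ToyStructure, fftable: FormFactorTable,
                     scale: float = 1.0, hkl=None) -> np.ndarray:
    """Complex F for every reflection of the table (or a subset ``hkl``)."""
    tab_hkl = fftable.hkl
    if hkl is not None:
        hkl = np.atleast_2d(np.asarray(hkl, int))
        idx = []
        lookup = {tuple(row): i for i, row in enumerate(tab_hkl)}
        for row in hkl:
            key = tuple(int(v) for v in row)
            if key not in lookup:
                raise RefinementError(f"form factors missing for hkl {key}")
            idx.append(lookup[key])
        sel = np.asarray(idx, int)
    else:
        hkl = tab_hkl
        sel = slice(None)
    for s in structure.sites:
        if s.label not in fftable.site_labels:
            raise RefinementError(f"form factors missing for site {s.label!r}")
    s_cart = structure.cell.reciprocal_vectors(hkl)
    f = np.zeros(len(hkl), complex)
    for site in structure.sites:
        fa = fftable.for_site(site.label)[sel]
        dw = np.exp(-2.0 * np.pi**2 * np.einsum("ki,ij,kj->k", s_cart, site.u_cart, s_cart))
        phase = np.exp(2j * np.pi * (hkl @ site.frac))
        f += site.occupancy * fa * dw * phase
    return scale * f


def shelx_weight(f_obs_sq, sigma, f_calc_sq, a: float = 0.0, b: float = 0.0,
                 p_convention: str = "literal") -> np.ndarray:
    """SHELX-type weights w = 1 / (sigma^2 + (aP)^2 + bP).

    ``p_convention="literal"`` uses P = 2 Fc^2 + max(Fo^2, 0) (the formula as
    commonly printed, without the /3); ``"shelx"`` uses the conventional
    P = (2 Fc^2 + max(Fo^2, 0)) / 3.
    """
    fo = np.asarray(f_obs_sq, float)
    sig = np.asarray(sigma, float)
    fc = np.asarray(f_calc_sq, float)
    if np.any(sig <= 0):
        raise RefinementError("sigma must be positive")
    if a < 0 or b < 0:
        raise RefinementError("a and b must be non-negative")
    p = 2.0 * fc + np.maximum(fo, 0.0)
    if p_convention == "shelx":
        p = p / 3.0
    elif p_convention != "literal":
        raise RefinementError(f"unknown P convention {p_convention!r}")
    return 1.0 / (sig**2 + (a * p) ** 2 + b * p)


@dataclasses.dataclass(frozen=True)
class AgreementStats:
    r1: float
    wr2: float
    goof: float


def agreement_stats(data: ReflectionData, f_calc_sq, weights,
                    n_params: int = 0) -> AgreementStats:
    """Conventional agreement factors.

    R1 = sum ||Fo| - |Fc|| / sum |Fo| over reflections with Fo^2 > 0;
    wR2 = [sum w (Fo^2 - Fc^2)^2 / sum w Fo^4]^(1/2);
    GooF = [sum w (Fo^2 - Fc^2)^2 / (n_obs - n_params)]^(1/2).
    """
    if len(data) == 0:
        raise RefinementError("empty reflection data")
    fc2 = np.asarray(f_calc_sq, float)
    w = np.asarray(weights, float)
    fo2 = data.f_obs_sq
    pos = fo2 > 0
    r1 = float(np.sum(np.abs(np.sqrt(fo2[pos]) - np.sqrt(np.maximum(fc2[pos], 0.0))))
               / np.sum(np.sqrt(fo2[pos])))
    chi = w * (fo2 - fc2) ** 2
    wr2 = float(np.sqrt(np.sum(chi) / np.sum(w * fo2**2)))
    dof = max(len(data) - n_params, 1)
    goof = float(np.sqrt(np.sum(chi) / dof))
    return AgreementStats(r1, wr2, goof)


@dataclasses.dataclass
class RefinementOptions:
    free_xyz: tuple[str, ...] = ()
    free_uij: tuple[str, ...] = ()
    refine_scale: bool = True
    a: float = 0.0
    b: float = 0.0
    p_convention: str = "literal"
    shift_su_threshold: float = 0.1
    max_macro_cycles: int = 10
    max_inner_iterations: int = 20
    d_min: float | None = None


@dataclasses.dataclass
class RefinementResult:
    structure: ToyStructure
    scale: float
    su: dict[str, float]
    r1: float
    wr2: float
    goof: float
    macro_cycles: int
    converged: bool
    max_shift_su: float
    weight_params: tuple[float, float]


_UIDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


class _ParamMap:
    """Flat parameter vector <-> structure fields."""

    def __init__(self, structure: ToyStructure, options: RefinementOptions):
        self.names: list[str] = []
        self.options = options
        if options.refine_scale:
            self.names.append("scale")
        for lbl in options.free_xyz:
            structure.site(lbl)
            self.names += [f"{lbl}.{ax}" for ax in "xyz"]
        for lbl in options.free_uij:
            structure.site(lbl)
            self.names += [f"{lbl}.U{i+1}{j+1}" for i, j in _UIDX]

    def get(self, structure: ToyStructure, scale: float) -> np.ndarray:
        p = []
        if self.options.refine_scale:
            p.append(scale)
        for lbl in self.options.free_xyz:
            p.extend(structure.site(lbl).frac)
        for lbl in self.options.free_uij:
            u = structure.site(lbl).u_cart
            p.extend(u[i, j] for i, j in _UIDX)
        return np.asarray(p, float)

    def set(self, structure: ToyStructure, p: np.ndarray) -> float:
        k = 0
        scale = 1.0
        if self.options.refine_scale:
            scale = float(p[k]); k += 1
        for lbl in self.options.free_xyz:
            structure.site(lbl).frac = np.asarray(p[k:k + 3], float)
            k += 3
        for lbl in self.options.free_uij:
            u = np.zeros((3, 3))
            for (i, j), v in zip(_UIDX, p[k:k + 6]):
                u[i, j] = u[j, i] = v
            structure.site(lbl).u_cart = u
            k += 6
        return scale


def _design_matrix(structure: ToyStructure, fftable: FormFactorTable, scale: float,
                   pmap: _ParamMap) -> tuple[np.ndarray, np.ndarray]:
    """(f_calc_sq, Jacobian of F^2 w.r.t. the free parameters)."""
    hkl = fftable.hkl
    s_cart = structure.cell.reciprocal_vectors(hkl)
    contrib = {}
    f = np.zeros(len(hkl), complex)
    for site in structure.sites:
        fa = fftable.for_site(site.label)
        dw = np.exp(-2.0 * np.pi**2 * np.einsum("ki,ij,kj->k", s_cart, site.u_cart, s_cart))
        phase = np.exp(2j * np.pi * (hkl @ site.frac))
        contrib[site.label] = site.occupancy * fa * dw * phase
        f += contrib[site.label]
    f_total = scale * f
    cols = []
    opt = pmap.options
    if opt.refine_scale:
        cols.append(f)                                   # dF/dscale
    for lbl in opt.free_xyz:
        for ax in range(3):
            cols.append(scale * contrib[lbl] * 2j * np.pi * hkl[:, ax])
    for lbl in opt.free_uij:
        base = scale * contrib[lbl]
        for i, j in _UIDX:
            mult = 1.0 if i == j else 2.0
            cols.append(base * (-2.0 * np.pi**2 * mult * s_cart[:, i] * s_cart[:, j]))
    jac = 2.0 * np.real(np.conj(f_total)[:, None] * np.column_stack(cols)) \
        if cols else np.zeros((len(hkl), 0))
    return np.abs(f_total) ** 2, jac


def refine(structure: ToyStructure, data: ReflectionData,
           fftable_provider: Callable[[ToyStructure, np.ndarray], FormFactorTable],
           options: RefinementOptions | None = None) -> RefinementResult:
    """Gauss–Newton refinement on F^2 with macro-cycle form-factor updates.

    ``fftable_provider(structure, hkl)`` must return a
    :class:`FormFactorTable` for the current geometry; it is called once per
    macro-cycle, mimicking the HAR outer loop.  Non-convergence within
    ``max_macro_cycles`` is reported through the ``converged`` flag, not an
    exception; a singular normal matrix raises :class:`RankDeficiencyError`.
    """
    options = options or RefinementOptions()
    work = structure.copy()
    if options.d_min is not None:
        data = data.cut(options.d_min)
    pmap = _ParamMap(work, options)
    n_par = len(pmap.names)
    if n_par == 0:
        raise RefinementError("no free parameters")
    if len(data) < n_par:
        raise RefinementError(f"{len(data)} reflections < {n_par} parameters")

    scale = 1.0
    su = np.zeros(n_par)
    max_shift_su = np.inf
    converged = False
    normal_inv = None
    macro = 0
    for macro in range(1, options.max_macro_cycles + 1):
        table = fftable_provider(work, data.hkl)
        p_start = pmap.get(work, scale)
        # scale initialisation on the first evaluation keeps GN well-posed
        fc2, _ = _design_matrix(work, table, scale, pmap)
        if options.refine_scale and macro == 1 and np.sum(fc2**2) > 0:
            k2 = float(np.sum(data.f_obs_sq * fc2) / np.sum(fc2**2))
            if k2 > 0:
                scale *= np.sqrt(k2)
        for _ in range(options.max_inner_iterations):
            fc2, jac = _design_matrix(work, table, scale, pmap)
            w = shelx_weight(data.f_obs_sq, data.sigma, fc2, options.a, options.b,
                             options.p_convention)
            resid = data.f_obs_sq - fc2
            jw = jac * w[:, None]
            normal = jw.T @ jac
            rhs = jw.T @ resid
            ev, evec = np.linalg.eigh(normal)
            tiny = ev < max(ev.max(), 1e-300) * 1e-12
            if tiny.any():
                null = []
                for v in evec.T[tiny]:
                    null.append(pmap.names[int(np.argmax(np.abs(v)))])
                raise RankDeficiencyError(null)
            delta = np.linalg.solve(normal, rhs)
            chi0 = float(np.sum(w * resid**2))
            p_cur = pmap.get(work, scale)
            step = 1.0
            for _try in range(8):
                scale = pmap.set(work, p_cur + step * delta)
                fc2_new, _ = _design_matrix(work, table, scale, pmap)
                w_new = shelx_weight(data.f_obs_sq, data.sigma, fc2_new,
                                     options.a, options.b, options.p_convention)
                chi = float(np.sum(w_new * (data.f_obs_sq - fc2_new) ** 2))
                if chi <= chi0 or chi0 == 0.0:
                    break
                step *= 0.5
            else:
                scale = pmap.set(work, p_cur)  # no improving step: stay put
                break
            if np.max(np.abs(step * delta)) < 1e-14 * (1.0 + np.max(np.abs(p_cur))):
                break
        fc2, jac = _design_matrix(work, table, scale, pmap)
        w = shelx_weight(data.f_obs_sq, data.sigma, fc2, options.a, options.b,
                         options.p_convention)
        stats = agreement_stats(data, fc2, w, n_params=n_par)
        normal_inv = np.linalg.inv((jac * w[:, None]).T @ jac)
        su_unscaled = np.sqrt(np.clip(np.diag(normal_inv), 0.0, None))
        su = su_unscaled * stats.goof
        # The convergence ratio uses the unscaled (sigma-based) uncertainties:
        # on noise-free data the goof tracks the residual, which contracts at
        # the same rate as the shifts, so a goof-scaled ratio would stall.
        shift = pmap.get(work, scale) - p_start
        ratios = np.abs(shift) / np.maximum(su_unscaled, 1e-12)
        max_shift_su = float(np.max(ratios))
        if max_shift_su < options.shift_su_threshold or np.max(np.abs(shift)) < 1e-12:
            converged = True
            break

    fc2, _ = _design_matrix(work, fftable_provider(work, data.hkl), scale, pmap)
    w = shelx_weight(data.f_obs_sq, data.sigma, fc2, options.a, options.b,
                     options.p_convention)
    stats = agreement_stats(data, fc2, w, n_params=n_par)
    return RefinementResult(
        structure=work, scale=scale,
        su=dict(zip(pmap.names, su)),
        r1=stats.r1, wr2=stats.wr2, goof=stats.goof,
        macro_cycles=macro, converged=converged, max_shift_su=max_shift_su,
        weight_params=(options.a, options.b))


# ---------------------------------------------------------------------------
# SHELX-style .hkl and minimal CIF input/output


def read_shelx_hkl(path, cell: UnitCell) -> ReflectionData:
    """Read 'h k l Fo^2 sigma' lines (fixed-width or whitespace); 0 0 0 terminates."""
    hkl, fo2, sig = [], [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            try:
                parts = line.split()
                h, k, l = int(parts[0]), int(parts[1]), int(parts[2])
                f, s = float(parts[3]), float(parts[4])
            except (ValueError, IndexError):
                h = int(line[0:4]); k = int(line[4:8]); l = int(line[8:12])
                f = float(line[12:20]); s = float(line[20:28])
            if h == 0 and k == 0 and l == 0:
                break
            hkl.append((h, k, l)); fo2.append(f); sig.append(s)
    return ReflectionData.from_cell(cell, np.array(hkl, int), fo2, sig)


def write_shelx_hkl(data: ReflectionData, path) -> None:
    with open(path, "w") as fh:
        for (h, k, l), f, s in zip(data.hkl, data.f_obs_sq, data.sigma):
            fh.write(f"{h:4d}{k:4d}{l:4d}{f:8.2f}{s:8.2f}\n")
        fh.write(f"{0:4d}{0:4d}{0:4d}{0.0:8.2f}{0.0:8.2f}\n")


def write_cif(structure: ToyStructure, path, data_name: str = "toy") -> None:
    """Minimal P1 CIF with atom_site and atom_site_aniso loops (CIF U convention)."""
    c = structure.cell
    lines = [
        f"data_{data_name}",
        f"_cell_length_a {c.a:.6f}",
        f"_cell_length_b {c.b:.6f}",
        f"_cell_length_c {c.c:.6f}",
        f"_cell_angle_alpha {c.alpha:.4f}",
        f"_cell_angle_beta {c.beta:.4f}",
        f"_cell_angle_gamma {c.gamma:.4f}",
        "_space_group_name_H-M_alt 'P 1'",
        "_space_group_IT_number 1",
        "loop_",
        "_space_group_symop_operation_xyz",
        "x,y,z",
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
        "_atom_site_occupancy",
        "_atom_site_adp_type",
        "_atom_site_U_iso_or_equiv",
    ]
    for s in structure.sites:
        ueq = float(np.trace(s.u_cart)) / 3.0
        lines.append(f"{s.label} {s.element} {s.frac[0]:.8f} {s.frac[1]:.8f} "
                     f"{s.frac[2]:.8f} {s.occupancy:.4f} Uani {ueq:.8f}")
    lines += [
        "loop_",
        "_atom_site_aniso_label",
        "_atom_site_aniso_U_11",
        "_atom_site_aniso_U_22",
        "_atom_site_aniso_U_33",
        "_atom_site_aniso_U_12",
        "_atom_site_aniso_U_13",
        "_atom_site_aniso_U_23",
    ]
    for s in structure.sites:
        u = ucart_to_ucif(c, s.u_cart)
        lines.append(f"{s.label} {u[0,0]:.8f} {u[1,1]:.8f} {u[2,2]:.8f} "
                     f"{u[0,1]:.8f} {u[0,2]:.8f} {u[1,2]:.8f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_cif(path) -> ToyStructure:
    """Read a minimal P1 small-molecule CIF (via gemmi) into a ToyStructure."""
    import gemmi

    small = gemmi.read_small_structure(str(path))
    gc = small.cell
    cell = UnitCell(gc.a, gc.b, gc.c, gc.alpha, gc.beta, gc.gamma)
    sites = []
    for s in small.sites:
        if s.aniso.nonzero():
            u_cif = np.array([[s.aniso.u11, s.aniso.u12, s.aniso.u13],
                              [s.aniso.u12, s.aniso.u22, s.aniso.u23],
                              [s.aniso.u13, s.aniso.u23, s.aniso.u33]])
            u_cart = ucif_to_ucart(cell, u_cif)
        else:
            u_cart = np.eye(3) * s.u_iso
        frac = np.array([s.fract.x, s.fract.y, s.fract.z])
        occ = s.occ if s.occ > 0 else 1.0
        sites.append(Site(s.label, s.type_symbol, frac, u_cart, occ))
    return ToyStructure(cell, sites)
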