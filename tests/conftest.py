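"""Shared fixtures: grids, toy densities and a cached refinement scenario."""

from __future__ import annotations

import numpy as np
import pytest

import exphar as xp


@pytest.fixture(scope="session")
def sgrid_590():
    return xp.sphere_grid(590)


@pytest.fixture(scope="session")
def sgrid_5810():
    return xp.sphere_grid(5810)


@pytest.fixture(scope="session")
def rgrid_75():
    return xp.radial_grid(75, 5.0)


@pytest.fixture(scope="session")
def h2plus():
    """Two-centre one-electron toy at the typical bond separation (2 bohr)."""
    return xp.TwoCenterDensity(2.0)


@pytest.fixture(scope="session")
def hetero_pair():
    """Heteronuclear promolecule: compact 'Y' (zeta 2.0) and H 2.5 bohr apart."""
    heavy = xp.SlaterDensity("Y", 2.0, electron_count=2.0, nuclear_charge=2.0)
    light = xp.SlaterDensity("H", 1.0)
    sites = (xp.PlacedAtom(heavy, [0.0, 0.0, 0.0]),
             xp.PlacedAtom(light, [0.0, 0.0, 2.5]))
    return xp.PromoleculeDensity(sites)


@pytest.fixture(scope="session")
def toy_structure():
    return xp.make_structure("diatomic_XH", 7)


@pytest.fixture(scope="session")
def toy_refinement(toy_structure):
    """Noise-free diatomic data plus a form-factor provider (exponent 2)."""
    from exphar.form_factors import build_tsc, structure_partition_spec

    spec = structure_partition_spec(toy_structure, 2.0)
    data = xp.simulate_intensities(toy_structure, spec, d_min=0.9, seed=3)

    def provider(structure, hkl):
        return build_tsc(structure, hkl, structure_partition_spec(structure, 2.0))

    return toy_structure, data, provider


def random_positive_definite(rng: np.random.Generator, scale: float = 0.02) -> np.ndarray:
    """Random anisotropic positive-definite 3x3 displacement-like tensor."""
    a = rng.normal(size=(3, 3))
    m = a @ a.T * scale / 3.0
    return m + scale * 0.1 * np.eye(3)
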