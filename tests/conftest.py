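import numpy as np
import pytest

from rmakit import default_array, generate_dataset
from rmakit.cantilever import CantileverGeometry, MaterialLayer
from rmakit.presets import reference_geometries, reference_layers, silicon_only_layers

# Silicon (110) single-crystal constants used throughout the tests.
E_SI = 169e9
RHO_SI = 2329.0


@pytest.fixture(scope="session")
def si_layer():
    return MaterialLayer("Si", 5e-6, E_SI, RHO_SI)


@pytest.fixture(scope="session")
def ref_geometries():
    return reference_geometries()


@pytest.fixture(scope="session")
def ref_layers():
    return reference_layers()


@pytest.fixture(scope="session")
def si_layers():
    return silicon_only_layers()


@pytest.fixture(scope="session")
def array8():
    return default_array()


@pytest.fixture(scope="session")
def small_dataset():
    """Balanced 12+12 synthetic dataset, 2 breath cycles per recording."""
    return generate_dataset(12, 12, seed=7, n_cycles=2)


def uniform_geometry(l=3.0e-3, c=2.0e-3, l_n=1.2e-3, h=5e-6):
    """Degenerate stepped geometry whose two segments are identical."""
    return CantileverGeometry(l=l, c=c, l_n=l_n, c_n=c / 2, h=h, n_support_beams=2)


def fem_modes(geometry, ei1, m1, ei2, m2, n_elements=400, n_modes=3):
    """Independent oracle: Hermite-element Euler-Bernoulli eigensolver.

    Assembles consistent stiffness/mass matrices for the stepped clamped-free
    beam and solves the generalised eigenproblem directly; shares no code
    with the transcendental-determinant solver under test.
    """
    from scipy.linalg import eigh

    xn = np.linspace(0.0, geometry.l, n_elements + 1)
    ndof = 2 * (n_elements + 1)
    stiff = np.zeros((ndof, ndof))
    mass = np.zeros((ndof, ndof))
    for e in range(n_elements):
        le = xn[e + 1] - xn[e]
        mid = 0.5 * (xn[e] + xn[e + 1])
        ei, m = (ei1, m1) if mid <= geometry.l_n else (ei2, m2)
        k_el = ei / le**3 * np.array(
            [[12, 6 * le, -12, 6 * le],
             [6 * le, 4 * le**2, -6 * le, 2 * le**2],
             [-12, -6 * le, 12, -6 * le],
             [6 * le, 2 * le**2, -6 * le, 4 * le**2]]
        )
        m_el = m * le / 420 * np.array(
            [[156, 22 * le, 54, -13 * le],
             [22 * le, 4 * le**2, 13 * le, -3 * le**2],
             [54, 13 * le, 156, -22 * le],
             [-13 * le, -3 * le**2, -22 * le, 4 * le**2]]
        )
        idx = [2 * e, 2 * e + 1, 2 * e + 2, 2 * e + 3]
        stiff[np.ix_(idx, idx)] += k_el
        mass[np.ix_(idx, idx)] += m_el
    keep = np.arange(2, ndof)  # clamp w and w' at the root
    w2 = eigh(stiff[np.ix_(keep, keep)], mass[np.ix_(keep, keep)], eigvals_only=True)
    return np.sqrt(w2[:n_modes]) / (2 * np.pi)
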