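"""Width-stepped cantilever modal analysis and Mel-grid array design.

A width-stepped cantilever is a thin plate suspended on one or more narrow
support beams: the cross-section steps from the narrow beams (segment 1,
clamped at the substrate) to the wide plate (segment 2, free end).  The step
concentrates bending stress in the support beams, which is where the
piezoelectric film sits, so the design trades stiffness for output voltage.

The modal model is a two-segment Euler--Bernoulli beam:

    W_i''''(x) - beta_i^4 W_i(x) = 0,   beta_i^4 = m_i omega^2 / (E_i I_i)

with clamped conditions at the root, continuity of displacement, slope,
bending moment ``EI W''`` and shear ``EI W'''`` at the step, and a free tip.
Eigenfrequencies are roots of the 8x8 boundary-condition determinant in
``omega``; the resonance frequency follows as

    f = beta_1^2 / (2 pi) * sqrt(E1 I1 / m1) = beta_2^2 / (2 pi) * sqrt(E2 I2 / m2).

Multiple support beams are lumped into a single equivalent segment (their
mass per length and flexural rigidity are summed); the rocking/torsional
modes that distinguish centre-beam from edge-beam layouts are outside a 1-D
beam model and are not computed here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "VACUUM_PERMITTIVITY",
    "CantileverGeometry",
    "MaterialLayer",
    "SegmentProperties",
    "ModalSolution",
    "MelGrid",
    "composite_section",
    "compose_segment_properties",
    "solve_stepped_modes",
    "uniform_cantilever_frequency",
    "mel_forward",
    "mel_inverse",
    "mel_spaced_frequencies",
    "piezo_open_circuit_voltage",
    "estimate_root_stress",
]

#: Vacuum permittivity epsilon_0 (F/m).
VACUUM_PERMITTIVITY = 8.854e-12

# Clamped-free beam eigenvalue constants lambda_k (roots of 1 + cos(l)cosh(l) = 0).
_CLAMPED_FREE_LAMBDA = (
    1.87510407,
    4.69409113,
    7.85475744,
    10.99554073,
    14.13716839,
)


class ValidationError(ValueError):
    """Raised for physically inconsistent geometry or material input."""


@dataclass(frozen=True)
class CantileverGeometry:
    """Planar outline and thickness of one width-stepped cantilever.

    Parameters
    ----------
    l : float
        Total outline length (m), root to free tip.
    c : float
        Outline (plate) width (m).
    l_n : float
        Length of the narrow support segment (m), measured from the root.
    c_n : float
        Width of EACH narrow support beam (m).
    h : float
        Structural-layer thickness (m).
    n_support_beams : int
        Number of parallel support beams (default 2).
    """

    l: float
    c: float
    l_n: float
    c_n: float
    h: float
    n_support_beams: int = 2

    def __post_init__(self) -> None:
        for name in ("l", "c", "l_n", "c_n", "h"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"dimension {name!r} must be > 0")
        if self.n_support_beams < 1:
            raise ValidationError("n_support_beams must be >= 1")
        if not self.l_n < self.l:
            raise ValidationError("narrow-segment length l_n must be < outline length l")
        if self.n_support_beams * self.c_n > self.c * (1 + 1e-12):
            raise ValidationError("support beams wider than the plate outline")
        if self.h / self.l > 0.05:
            warnings.warn(
                f"h/l = {self.h / self.l:.3f} > 0.05: outside the thin-beam regime, "
                "Euler-Bernoulli results may be inaccurate",
                stacklevel=2,
            )

    @property
    def plate_length(self) -> float:
        """Length of the wide plate segment (m)."""
        return self.l - self.l_n


@dataclass(frozen=True)
class MaterialLayer:
    """One layer of the cantilever stack.

    ``narrow_only`` marks layers deposited only over the support beams
    (electrodes, piezo film, insulators); they contribute to segment 1 but
    not to the plate.  ``d31`` and ``relative_permittivity`` are required
    only on the piezoelectric layer.
    """

    name: str
    thickness: float
    young_modulus: float
    density: float
    d31: float | None = None
    relative_permittivity: float | None = None
    narrow_only: bool = False

    def __post_init__(self) -> None:
        if self.thickness < 0:
            raise ValidationError(f"layer {self.name!r}: thickness must be >= 0")
        if self.thickness > 0 and (self.young_modulus <= 0 or self.density <= 0):
            raise ValidationError(f"layer {self.name!r}: E and rho must be > 0")
        if self.relative_permittivity is not None and self.relative_permittivity <= 1:
            raise ValidationError(f"layer {self.name!r}: relative permittivity must be > 1")

    @property
    def is_piezo(self) -> bool:
        return self.d31 is not None


@dataclass(frozen=True)
class SegmentProperties:
    """Per-segment mass per unit length and flexural rigidity.

    Segment 1 is the narrow support segment (values summed over all support
    beams), segment 2 the wide plate.
    """

    m1: float
    m2: float
    EI1: float
    EI2: float

    def __post_init__(self) -> None:
        if min(self.m1, self.m2, self.EI1, self.EI2) <= 0:
            raise ValidationError("segment properties must all be > 0")


@dataclass(frozen=True)
class ModalSolution:
    """One eigenmode of the stepped beam.

    ``coefficients`` holds the eight mode-shape amplitudes
    ``(A1..A4, B1..B4)`` multiplying ``sin, cos, sinh, cosh`` in
    ``beta_1 x`` (segment 1, root coordinate) and ``beta_2 xi`` (segment 2,
    coordinate from the step), normalised to unit Euclidean norm.
    """

    mode_index: int
    frequency: float
    beta1: float
    beta2: float
    omega: float
    coefficients: np.ndarray = field(repr=False)


def composite_section(layers: list[MaterialLayer]) -> tuple[float, float]:
    """Transformed-section flexural rigidity and mass, per unit width.

    Layers are stacked bottom-up in list order.  Rigidity is taken about
    the modulus-weighted (composite) neutral axis; with a single layer this
    reduces to ``E h^3 / 12`` and ``rho h``.

    Returns
    -------
    (EI_per_width, m_per_width) : tuple of float
        N.m^2 per metre of width and kg/m^2.
    """
    active = [ly for ly in layers if ly.thickness > 0]
    if not active:
        raise ValidationError("at least one layer with positive thickness is required")
    z = 0.0
    spans = []
    for ly in active:
        spans.append((z, z + ly.thickness, ly))
        z += ly.thickness
    ea = sum(ly.young_modulus * (z1 - z0) for z0, z1, ly in spans)
    zbar = sum(ly.young_modulus * (z1 - z0) * (z0 + z1) / 2 for z0, z1, ly in spans) / ea
    ei = sum(
        ly.young_modulus * ((z1 - zbar) ** 3 - (z0 - zbar) ** 3) / 3 for z0, z1, ly in spans
    )
    m = sum(ly.density * (z1 - z0) for z0, z1, ly in spans)
    return ei, m


def compose_segment_properties(
    geometry: CantileverGeometry, layers: list[MaterialLayer]
) -> SegmentProperties:
    """Build per-segment beam properties from the layer stack.

    The narrow segment carries the full stack over a total width of
    ``n_support_beams * c_n``; the plate carries only the layers not marked
    ``narrow_only`` over width ``c``.
    """
    if not layers:
        raise ValidationError("empty layer list")
    ei1_w, m1_w = composite_section(layers)
    plate_layers = [ly for ly in layers if not ly.narrow_only]
    ei2_w, m2_w = composite_section(plate_layers)
    w1 = geometry.n_support_beams * geometry.c_n
    w2 = geometry.c
    return SegmentProperties(m1=m1_w * w1, m2=m2_w * w2, EI1=ei1_w * w1, EI2=ei2_w * w2)


def _boundary_matrix(
    omega: float, props: SegmentProperties, l_n: float, l2: float
) -> np.ndarray:
    """Assemble the 8x8 boundary-condition matrix at angular frequency omega.

    Rows: clamp (displacement, slope) at the root; continuity of
    displacement, slope, moment and shear at the step; zero moment and shear
    at the free tip.  Columns: (A1..A4, B1..B4).  Rows are rescaled to unit
    max-abs so the determinant stays well conditioned when the hyperbolic
    terms grow.
    """
    b1 = (props.m1 * omega**2 / props.EI1) ** 0.25
    b2 = (props.m2 * omega**2 / props.EI2) ** 0.25
    x = b1 * l_n
    s1, c1, sh1, ch1 = math.sin(x), math.cos(x), math.sinh(x), math.cosh(x)
    y = b2 * l2
    s2, c2, sh2, ch2 = math.sin(y), math.cos(y), math.sinh(y), math.cosh(y)
    m = np.zeros((8, 8))
    m[0, :4] = (0, 1, 0, 1)
    m[1, :4] = (1, 0, 1, 0)  # slope row, common factor beta1 dropped
    m[2, :4] = (s1, c1, sh1, ch1)
    m[2, 4:] = (0, -1, 0, -1)
    m[3, :4] = np.array((c1, -s1, ch1, sh1)) * b1
    m[3, 4:] = np.array((1, 0, 1, 0)) * -b2
    m[4, :4] = np.array((-s1, -c1, sh1, ch1)) * props.EI1 * b1**2
    m[4, 4:] = np.array((0, -1, 0, 1)) * -props.EI2 * b2**2
    m[5, :4] = np.array((-c1, s1, ch1, sh1)) * props.EI1 * b1**3
    m[5, 4:] = np.array((-1, 0, 1, 0)) * -props.EI2 * b2**3
    m[6, 4:] = np.array((-s2, -c2, sh2, ch2)) * b2**2
    m[7, 4:] = np.array((-c2, s2, ch2, sh2)) * b2**3
    scale = np.abs(m).max(axis=1)
    return m / scale[:, None]


def _det(omega: float, props: SegmentProperties, l_n: float, l2: float) -> float:
    return float(np.linalg.det(_boundary_matrix(omega, props, l_n, l2)))


def solve_stepped_modes(
    props: SegmentProperties,
    geometry: CantileverGeometry,
    n_modes: int = 3,
    *,
    f_min: float = 1.0,
    f_max: float = 5.0e4,
    n_scan: int = 2000,
) -> list[ModalSolution]:
    """Solve the two-segment clamped-free eigenproblem.

    The determinant of the boundary-condition matrix is scanned for sign
    changes on a log-spaced frequency grid (``n_scan`` points between
    ``f_min`` and ``f_max``) and each bracket is refined by Brent bisection
    to 1e-12 relative.  Returns the lowest ``n_modes`` modes in ascending
    frequency order.

    Raises
    ------
    RuntimeError
        If fewer than ``n_modes`` sign changes exist in the scan range
        ("scan range exhausted") or a refined root has an inconsistent
        residual.
    """
    if n_modes < 1:
        raise ValidationError("n_modes must be >= 1")
    l_n, l2 = geometry.l_n, geometry.plate_length
    grid = np.logspace(math.log10(f_min), math.log10(f_max), n_scan)
    modes: list[ModalSolution] = []
    d_prev = _det(2 * math.pi * grid[0], props, l_n, l2)
    for i in range(1, len(grid)):
        d_cur = _det(2 * math.pi * grid[i], props, l_n, l2)
        if d_prev * d_cur < 0:
            f_root = brentq(
                lambda f: _det(2 * math.pi * f, props, l_n, l2),
                grid[i - 1],
                grid[i],
                xtol=1e-10 * grid[i - 1],
                rtol=1e-12,
            )
            omega = 2 * math.pi * f_root
            mat = _boundary_matrix(omega, props, l_n, l2)
            _, sv, vt = np.linalg.svd(mat)
            coeffs = vt[-1]
            residual = sv[-1] / sv[0]
            if residual > 1e-6:
                raise RuntimeError(
                    f"ill-conditioned eigenvector at f={f_root:.3f} Hz "
                    f"(relative residual {residual:.2e})"
                )
            b1 = (props.m1 * omega**2 / props.EI1) ** 0.25
            b2 = (props.m2 * omega**2 / props.EI2) ** 0.25
            modes.append(
                ModalSolution(
                    mode_index=len(modes) + 1,
                    frequency=f_root,
                    beta1=b1,
                    beta2=b2,
                    omega=omega,
                    coefficients=coeffs,
                )
            )
            if len(modes) == n_modes:
                return modes
        d_prev = d_cur
    raise RuntimeError(
        f"scan range exhausted: found {len(modes)} of {n_modes} requested modes in "
        f"[{f_min:g}, {f_max:g}] Hz; widen f_max or increase n_scan"
    )


def uniform_cantilever_frequency(
    length: float, EI: float, m: float, mode_index: int = 1
) -> float:
    """Closed-form clamped-free frequency of a uniform beam.

    ``f_k = lambda_k^2 / (2 pi) * sqrt(EI / (m L^4))`` with the tabulated
    clamped-free eigenvalue constants (modes 1..5).  Serves as the exact
    oracle for the stepped solver in the equal-segment limit.
    """
    if min(length, EI, m) <= 0:
        raise ValidationError("length, EI and m must all be > 0")
    if not 1 <= mode_index <= len(_CLAMPED_FREE_LAMBDA):
        raise ValidationError(
            f"mode_index must be in 1..{len(_CLAMPED_FREE_LAMBDA)}"
        )
    lam = _CLAMPED_FREE_LAMBDA[mode_index - 1]
    return lam**2 / (2 * math.pi) * math.sqrt(EI / (m * length**4))


def mel_forward(f):
    """Hz -> Mel, HTK convention ``m = 2595 log10(1 + f/700)``."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValidationError("frequency must be >= 0")
    out = 2595.0 * np.log10(1.0 + f / 700.0)
    return float(out) if out.ndim == 0 else out


def mel_inverse(m):
    """Mel -> Hz, exact analytic inverse of :func:`mel_forward`."""
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise ValidationError("mel value must be >= 0")
    out = 700.0 * (10.0 ** (m / 2595.0) - 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class MelGrid:
    """Frequencies uniformly spaced on the Mel scale."""

    hz: np.ndarray
    hz_rounded: np.ndarray

    def __len__(self) -> int:
        return len(self.hz)


def mel_spaced_frequencies(f_lo: float, f_hi: float, n: int) -> MelGrid:
    """``n`` frequencies whose Mel images are uniform between f_lo and f_hi.

    Endpoints are returned exactly; ``hz_rounded`` rounds to the nearest Hz,
    which is how array design frequencies are quoted.
    """
    if not 0 < f_lo < f_hi:
        raise ValidationError("need 0 < f_lo < f_hi")
    if n < 2:
        raise ValidationError("need n >= 2")
    mels = np.linspace(mel_forward(f_lo), mel_forward(f_hi), n)
    hz = mel_inverse(mels)
    hz[0], hz[-1] = f_lo, f_hi
    return MelGrid(hz=hz, hz_rounded=np.round(hz))


def piezo_open_circuit_voltage(stress_avg: float, piezo: MaterialLayer) -> float:
    """Open-circuit voltage across the piezo film under average in-plane stress.

    ``V = sigma d31 t / (eps_0 eps_r)`` -- the plate-capacitor charge model:
    the film area cancels between generated charge and capacitance, leaving
    only the film thickness.  Sign follows ``sigma * d31``.
    """
    if piezo.d31 is None or piezo.relative_permittivity is None:
        raise ValidationError(
            f"layer {piezo.name!r} is missing d31 and/or relative permittivity"
        )
    return (
        stress_avg
        * piezo.d31
        * piezo.thickness
        / (VACUUM_PERMITTIVITY * piezo.relative_permittivity)
    )


def estimate_root_stress(geometry: CantileverGeometry, pressure: float) -> float:
    """Static bending stress at the support-beam roots under uniform pressure.

    Deliberately the crudest statics model: the plate is rigid, the total
    force ``p l c`` acts at the area centroid, and the resulting root moment
    is shared equally by the support beams.  Only stress *ratios* between
    geometries are meaningful; absolute values underestimate a full elastic
    solution.
    """
    g = geometry
    a_narrow = g.n_support_beams * g.c_n * g.l_n
    a_plate = g.c * g.plate_length
    x_centroid = (
        a_narrow * g.l_n / 2 + a_plate * (g.l_n + g.plate_length / 2)
    ) / (a_narrow + a_plate)
    force = pressure * g.l * g.c
    moment_per_beam = force * x_centroid / g.n_support_beams
    i_beam = g.c_n * g.h**3 / 12
    return moment_per_beam * (g.h / 2) / i_beam
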