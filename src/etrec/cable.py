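"""Passive SENN-style nodal cable model of a myelinated A-beta fiber.

The fiber is a chain of nodes of Ranvier coupled by internodal axial
conductances.  Each node obeys

    Cm dVn/dt = Ga * Delta2(Vn + Ve,n) - Gm * Vn

where Vn is the membrane-potential deviation from rest, Ve,n the
extracellular potential sampled at node n, and Delta2 the second spatial
difference along the fiber; the extracellular second difference
(Ve,n-1 - 2 Ve,n + Ve,n+1) is the classical activating function and
enters as the effective source.  Terminal nodes are sealed (zero axial
flux).  The membrane is passive and linear; "activation" is defined as
the absolute potential v_rest + Vn crossing a fixed threshold
(Vth = -55 mV with v_rest = -70 mV, i.e. 15 mV of depolarisation).

Nodal constants follow classical SENN parameterisations: axoplasm
resistivity 110 Ohm*cm, nodal membrane capacitance 2 uF/cm^2, nodal
membrane conductance 30.4 mS/cm^2, nodal gap length 2.5 um, internode
spacing 100 x fiber diameter.  These are defaults recorded in
:class:`CableParams.from_geometry`, not assertions about any particular
tissue preparation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm, solve as dense_solve

from .config_space import ArrayLayout
from .field import PotentialField, sample_potential_along_path

DERMIS_SPAN_MM = (0.118, 1.498)  # depth interval of the dermis layer


@dataclass(frozen=True)
class FiberGeometry:
    """Placement and discretisation of one straight fiber in the dermis."""

    diameter_um: float = 9.0
    internode_mm: float = 0.9  # 100 x diameter
    n_nodes: int = 21
    depth_mm: float = 0.8
    orientation: str = "y"  # along the 3-electrode axis
    nodal_gap_um: float = 2.5

    def __post_init__(self) -> None:
        if self.n_nodes < 5 or self.n_nodes % 2 == 0:
            raise ValueError("n_nodes must be odd and >= 5")
        if not DERMIS_SPAN_MM[0] <= self.depth_mm <= DERMIS_SPAN_MM[1]:
            raise ValueError(f"fiber depth must lie within the dermis span {DERMIS_SPAN_MM} mm")
        if self.orientation not in ("x", "y"):
            raise ValueError("orientation must be 'x' or 'y'")

    @property
    def span_mm(self) -> float:
        return (self.n_nodes - 1) * self.internode_mm


@dataclass(frozen=True)
class CableParams:
    """Lumped nodal electrical constants (SI units)."""

    c_m: float  # F, nodal membrane capacitance
    g_a: float  # S, internodal axial conductance
    g_m: float  # S, nodal membrane conductance
    v_rest_mv: float = -70.0
    v_th_mv: float = -55.0
    k_per_mv: float = 0.05

    def __post_init__(self) -> None:
        if min(self.c_m, self.g_a, self.g_m) <= 0:
            raise ValueError("capacitance and conductances must be positive")
        if self.v_th_mv <= self.v_rest_mv:
            raise ValueError("threshold must exceed resting potential")

    @classmethod
    def from_geometry(
        cls,
        fiber: FiberGeometry,
        rho_axial_ohm_cm: float = 110.0,
        c_nodal_uf_per_cm2: float = 2.0,
        g_nodal_ms_per_cm2: float = 30.4,
        **kwargs,
    ) -> "CableParams":
        d_cm = fiber.diameter_um * 1e-4
        gap_cm = fiber.nodal_gap_um * 1e-4
        length_cm = fiber.internode_mm * 1e-1
        nodal_area_cm2 = np.pi * d_cm * gap_cm
        c_m = c_nodal_uf_per_cm2 * 1e-6 * nodal_area_cm2
        g_m = g_nodal_ms_per_cm2 * 1e-3 * nodal_area_cm2
        g_a = np.pi * d_cm**2 / (4.0 * rho_axial_ohm_cm * length_cm)
        return cls(c_m=c_m, g_a=g_a, g_m=g_m, **kwargs)

    @property
    def stability_dt_s(self) -> float:
        """Explicit-Euler step bound: 0.1 * Cm / (Gm + 2 Ga)."""
        return 0.1 * self.c_m / (self.g_m + 2.0 * self.g_a)


@dataclass(frozen=True)
class BiphasicWaveform:
    """Charge-balanced rectangular biphasic pulse, cathodic phase first."""

    amplitude_ma: float = 2.0
    phase_width_us: float = 100.0
    cathodic_first: bool = True

    def __post_init__(self) -> None:
        if not 10.0 <= self.phase_width_us <= 500.0:
            raise ValueError("phase width must lie within the 10-500 us device range")
        if self.amplitude_ma < 0:
            raise ValueError("amplitude must be non-negative")

    def current_ma(self, t_s: np.ndarray) -> np.ndarray:
        """Instantaneous current (mA) at times ``t_s`` (s), pulse onset at 0."""
        t = np.asarray(t_s, dtype=float)
        pw = self.phase_width_us * 1e-6
        first = -self.amplitude_ma if self.cathodic_first else self.amplitude_ma
        out = np.zeros_like(t)
        out[(t >= 0) & (t < pw)] = first
        out[(t >= pw) & (t < 2 * pw)] = -first
        return out


@dataclass
class DriveSeries:
    """Per-node extracellular potential time series Ve,n(t) in volts."""

    ve: np.ndarray  # (n_nodes, n_t)
    dt_s: float
    waveform: BiphasicWaveform


@dataclass
class CableTrajectory:
    """Membrane-potential deviations from rest, (n_nodes, n_t), volts."""

    v: np.ndarray
    dt_s: float
    params: CableParams


@dataclass(frozen=True)
class NeuralFeatures:
    v_peak_mv: float  # absolute membrane potential maximum
    t_peak_s: float
    activated: bool


def node_positions(fiber: FiberGeometry, layout: ArrayLayout) -> np.ndarray:
    """Collinear node coordinates (n, 3) as (x, y, z) in mm.

    Nodes are centred under the array centroid at ``fiber.depth_mm``,
    along the chosen lateral axis.
    """
    offs = (np.arange(fiber.n_nodes) - (fiber.n_nodes - 1) / 2.0) * fiber.internode_mm
    pts = np.zeros((fiber.n_nodes, 3))
    pts[:, 0 if fiber.orientation == "x" else 1] = offs
    pts[:, 2] = fiber.depth_mm
    return pts


def extracellular_drive(
    p: PotentialField,
    nodes_mm: np.ndarray,
    waveform: BiphasicWaveform,
    dt_s: float = 1e-6,
    duration_s: float = 1e-3,
) -> DriveSeries:
    """Ve,n(t) = phi(x_n) * i(t) / I_solved (quasi-static separability).

    The spatial solve is done once at the solved amplitude; time enters
    only through the source waveform.
    """
    if p.injected_current_ma == 0:
        raise ValueError("drive requires a potential solved at nonzero current")
    phi_per_ma = sample_potential_along_path(p, nodes_mm) / p.injected_current_ma
    t = np.arange(0.0, duration_s, dt_s)
    i_t = waveform.current_ma(t)
    return DriveSeries(ve=np.outer(phi_per_ma, i_t), dt_s=dt_s, waveform=waveform)


def _sealed_laplacian(n: int) -> np.ndarray:
    """Second-difference matrix with zero-axial-flux (Neumann) ends."""
    L = np.zeros((n, n))
    for i in range(n):
        if i > 0:
            L[i, i - 1] += 1.0
            L[i, i] -= 1.0
        if i < n - 1:
            L[i, i + 1] += 1.0
            L[i, i] -= 1.0
    return L


def integrate_cable(
    params: CableParams,
    drive: DriveSeries,
    method: str = "exact",
    divergence_limit_v: float = 50.0,
    v0: np.ndarray | None = None,
) -> CableTrajectory:
    """Integrate the passive nodal cable under a given extracellular drive.

    ``method="exact"`` steps the linear system with a precomputed matrix
    exponential: the drive is piecewise constant on the sampling grid,
    so each step is exact to machine precision.  ``method="euler"`` is
    the classical fixed-step explicit scheme and requires
    ``dt <= 0.1 * Cm / (Gm + 2 Ga)``.
    """
    ve = drive.ve
    n, nt = ve.shape
    dt = drive.dt_s
    L = _sealed_laplacian(n)
    A = (params.g_a * L - params.g_m * np.eye(n)) / params.c_m
    src = (params.g_a / params.c_m) * (L @ ve)  # (n, nt)

    out = np.zeros((n, nt))
    v = np.zeros(n) if v0 is None else np.asarray(v0, dtype=float).copy()
    out[:, 0] = v
    if method == "exact":
        E = expm(A * dt)
        M = dense_solve(A, E - np.eye(n))  # A^{-1} (e^{A dt} - I)
        for k in range(nt - 1):
            v = E @ v + M @ src[:, k]
            out[:, k + 1] = v
    elif method == "euler":
        if dt > params.stability_dt_s:
            raise ValueError(
                f"dt={dt:g}s violates the explicit stability bound {params.stability_dt_s:g}s"
            )
        for k in range(nt - 1):
            v = v + dt * (A @ v + src[:, k])
            out[:, k + 1] = v
    else:
        raise ValueError(f"unknown integration method {method!r}")
    if not np.isfinite(out).all() or np.abs(out).max() > divergence_limit_v:
        raise RuntimeError(f"cable integration diverged (dt={dt:g}s, method={method!r})")
    return CableTrajectory(v=out, dt_s=dt, params=params)


def neural_features(traj: CableTrajectory, params: CableParams | None = None) -> NeuralFeatures:
    """Peak absolute membrane potential, its time, and threshold crossing."""
    if traj.v.size == 0:
        raise ValueError("empty trajectory")
    p = params if params is not None else traj.params
    dev_mv = traj.v * 1e3
    flat = int(np.argmax(dev_mv))
    _, t_idx = np.unravel_index(flat, dev_mv.shape)
    v_peak = p.v_rest_mv + float(dev_mv.max())
    return NeuralFeatures(
        v_peak_mv=v_peak,
        t_peak_s=float(t_idx * traj.dt_s),
        activated=bool(v_peak >= p.v_th_mv),
    )
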