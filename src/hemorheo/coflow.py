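"""Two-fluid stratified laminar flow in a rectangular microchannel.

The optical-viscometry principle: two immiscible-in-practice streams (a
reference fluid of known viscosity ``μ1`` and a test fluid of unknown
apparent viscosity ``μ2``) flow side by side down a rectangular channel of
width ``w`` and depth ``h``.  For fully developed Stokes flow the
flow-rate ratio ``Q1/Q2`` is an analytic function of the viscosity ratio
``μ2/μ1``, the dimensionless interface position ``Y`` and the aspect
ratio ``β = h/w``.  Measuring ``Q1/Q2`` (set by the pumps) and ``Y``
(observed optically) therefore determines ``μ2``.

Coordinates and conventions (used everywhere in the package):

* ``y`` spans the width with the origin on the channel centerline,
  ``y ∈ [−w/2, +w/2]``; ``z`` spans the depth, ``z ∈ [0, h]``.
* fluid 1 (reference) occupies ``y > Y·w``; fluid 2 (test/blood)
  occupies ``y < Y·w``.
* ``Y = 1/2 − w1/w`` where ``w1`` is the reference-stream width, so
  ``Y = 0`` means equal stream widths and ``Y → +1/2`` means the
  reference stream vanishes.

The series solution is obtained by expanding the axial velocity in
``sin(nπz/h)`` modes.  Each odd mode satisfies a 1-D Helmholtz equation
across the width whose piecewise solution is matched at the interface by
continuity of velocity and of shear stress ``μ ∂u/∂y``.  The part of the
modal sum that decays like ``1/n⁴`` telescopes exactly to the
plane-Poiseuille base flow ``G h³ L_i /(12 μ_i)`` per stream, so it is
summed in closed form and only an ``O(1/n⁵)`` correction series remains;
all hyperbolic ratios are evaluated in overflow-safe form (``tanh`` /
``coth`` of positive arguments only).

An independent second-order finite-difference solver for the same
piecewise-viscosity duct problem (:func:`fd_velocity_field`) serves as a
cross-check and as the field generator for the synthetic experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import scipy.sparse
import scipy.sparse.linalg
from scipy.optimize import brentq

from .errors import ConvergenceError, DomainError, InversionError
from .units import M3_S_TO_UL_PER_HR, M_TO_UM, M_S_TO_MM_S, UM_TO_M

__all__ = [
    "ChannelGeometry",
    "CoflowProblem",
    "SeriesSettings",
    "DuctField",
    "series_flow_ratio",
    "solve_viscosity_ratio",
    "solve_interface_position",
    "fd_velocity_field",
    "apparent_viscosity",
    "single_fluid_flow_rate",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelGeometry:
    """Rectangular channel with a stratified two-fluid interface.

    Parameters
    ----------
    width_um, depth_um:
        Channel cross-section in μm (width ``w`` across the streams,
        depth ``h`` along the optical axis).
    interface_Y:
        Dimensionless interface position in ``(−1/2, +1/2)``; see module
        docstring for the sign convention.
    """

    width_um: float
    depth_um: float
    interface_Y: float = 0.0

    def __post_init__(self):
        if not (self.width_um > 0 and self.depth_um > 0):
            raise DomainError("channel width and depth must be positive")
        if not -0.5 < self.interface_Y < 0.5:
            raise DomainError(
                f"interface_Y must lie in (-0.5, 0.5), got {self.interface_Y}"
            )

    @property
    def aspect_beta(self) -> float:
        """Aspect ratio β = h/w."""
        return self.depth_um / self.width_um

    @property
    def width_reference_um(self) -> float:
        """Width w1 of the reference stream (fluid 1, y > Y·w)."""
        return (0.5 - self.interface_Y) * self.width_um

    @property
    def width_test_um(self) -> float:
        """Width w2 of the test stream (fluid 2, y < Y·w)."""
        return (0.5 + self.interface_Y) * self.width_um

    @classmethod
    def from_stream_widths(cls, width_reference_um: float, width_test_um: float,
                           depth_um: float) -> "ChannelGeometry":
        w = width_reference_um + width_test_um
        return cls(width_um=w, depth_um=depth_um,
                   interface_Y=0.5 - width_reference_um / w)


@dataclass(frozen=True)
class SeriesSettings:
    """Truncation control for the stratified-flow series."""

    max_terms: int = 2000         # number of odd modes retained
    relative_tolerance: float = 1e-10

    def __post_init__(self):
        if self.max_terms < 1:
            raise DomainError("max_terms must be >= 1")
        if not self.relative_tolerance > 0:
            raise DomainError("relative_tolerance must be > 0")


DEFAULT_SETTINGS = SeriesSettings()


@dataclass(frozen=True)
class CoflowProblem:
    """One co-flow viscometry measurement.

    Viscosities in Pa·s; flow rates in μL/hr.  ``mu_test`` may be None
    when it is the unknown to be solved for.
    """

    mu_reference: float
    q_reference_ul_hr: float
    q_test_ul_hr: float
    mu_test: Optional[float] = None
    pressure_gradient_pa_m: Optional[float] = None

    def __post_init__(self):
        if not self.mu_reference > 0:
            raise DomainError("reference viscosity must be positive")
        if not (self.q_reference_ul_hr > 0 and self.q_test_ul_hr > 0):
            raise DomainError("flow rates must be positive")
        if self.mu_test is not None and not self.mu_test > 0:
            raise DomainError("test viscosity must be positive")

    @property
    def flow_ratio(self) -> float:
        """Q1/Q2, reference over test."""
        return self.q_reference_ul_hr / self.q_test_ul_hr


@dataclass
class DuctField:
    """Finite-difference axial velocity field for the two-fluid duct.

    ``axial_velocity_mm_s`` is indexed ``[i_y, j_z]`` on the (possibly
    piecewise-uniform) grid ``grid_y_um`` × ``grid_z_um``; the interface
    lies exactly on grid line ``interface_index``.
    """

    grid_y_um: np.ndarray
    grid_z_um: np.ndarray
    axial_velocity_mm_s: np.ndarray
    viscosity_map_pa_s: np.ndarray
    flow_rate_1_ul_hr: float
    flow_rate_2_ul_hr: float
    geometry: ChannelGeometry
    pressure_gradient_pa_m: float
    interface_index: int

    @property
    def flow_ratio(self) -> float:
        return self.flow_rate_1_ul_hr / self.flow_rate_2_ul_hr

    def mid_plane_profile(self) -> Tuple[np.ndarray, np.ndarray]:
        """Velocity profile u(y) at mid-depth z = h/2 (mm/s vs μm)."""
        z = self.grid_z_um
        j = int(np.argmin(np.abs(z - 0.5 * (z[0] + z[-1]))))
        return self.grid_y_um.copy(), self.axial_velocity_mm_s[:, j].copy()

    def to_csv(self, path) -> None:
        """Write the field as tidy CSV with columns y_um, z_um, u_mm_s."""
        import pandas as pd

        yy, zz = np.meshgrid(self.grid_y_um, self.grid_z_um, indexing="ij")
        pd.DataFrame({
            "y_um": yy.ravel(),
            "z_um": zz.ravel(),
            "u_mm_s": self.axial_velocity_mm_s.ravel(),
        }).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# series solution
# ---------------------------------------------------------------------------


def _two_fluid_flow_rates(mu1: float, mu2: float, interface_Y: float,
                          aspect_beta: float,
                          settings: SeriesSettings) -> Tuple[float, float, int]:
    """Dimensionless per-stream flow rates (w = 1, G = 1).

    Returns (Q1, Q2, n_terms_used).  Only the ratio is physically
    meaningful to callers that work in dimensionless form.
    """
    h = aspect_beta                      # w = 1
    L1 = 0.5 - interface_Y               # reference-stream width
    L2 = 0.5 + interface_Y               # test-stream width

    base1 = h ** 3 * L1 / (12.0 * mu1)
    base2 = h ** 3 * L2 / (12.0 * mu2)

    n = np.arange(1, 2 * settings.max_terms, 2, dtype=float)  # odd modes
    k = n * np.pi / h
    p = 4.0 * h ** 2 / (np.pi ** 3 * n ** 3)   # modal pressure forcing /2μ removed

    th1 = np.tanh(0.5 * k * L1)
    th2 = np.tanh(0.5 * k * L2)
    coth1 = 1.0 / np.tanh(k * L1)
    coth2 = 1.0 / np.tanh(k * L2)

    # modal interface velocity
    U = p * (th1 + th2) / (mu1 * coth1 + mu2 * coth2)

    pref = 2.0 * h / (n * np.pi * k)
    terms1 = pref * th1 * (U - 2.0 * p / mu1)
    terms2 = pref * th2 * (U - 2.0 * p / mu2)

    Q1 = base1 + float(np.sum(terms1))
    Q2 = base2 + float(np.sum(terms2))

    tol = settings.relative_tolerance
    if (abs(terms1[-1]) > tol * abs(Q1)) or (abs(terms2[-1]) > tol * abs(Q2)):
        raise ConvergenceError(
            f"stratified-flow series not converged after {settings.max_terms} "
            f"odd modes (last relative terms "
            f"{abs(terms1[-1]) / abs(Q1):.2e}, {abs(terms2[-1]) / abs(Q2):.2e})",
            last_values=((Q1 - terms1[-1], Q2 - terms2[-1]), (Q1, Q2)),
        )
    return Q1, Q2, len(n)


def _validate_series_inputs(mu_ratio, interface_Y, aspect_beta):
    for name, val in (("mu_ratio", mu_ratio), ("interface_Y", interface_Y),
                      ("aspect_beta", aspect_beta)):
        if not np.isfinite(val):
            raise DomainError(f"{name} must be finite, got {val}")
    if not mu_ratio > 0:
        raise DomainError(f"viscosity ratio must be positive, got {mu_ratio}")
    if not -0.5 < interface_Y < 0.5:
        raise DomainError(f"interface_Y must lie in (-0.5, 0.5), got {interface_Y}")
    if not aspect_beta > 0:
        raise DomainError(f"aspect ratio must be positive, got {aspect_beta}")


def series_flow_ratio(mu_ratio_test_over_ref: float, interface_Y: float,
                      aspect_beta: float,
                      settings: SeriesSettings = DEFAULT_SETTINGS) -> float:
    """Flow-rate ratio Q1/Q2 of the two co-flowing streams.

    Parameters
    ----------
    mu_ratio_test_over_ref:
        μ2/μ1, the test-fluid (blood) viscosity over the reference-fluid
        viscosity.
    interface_Y, aspect_beta:
        Interface position and aspect ratio β = h/w (see module docstring).

    Returns
    -------
    float
        Q1/Q2 (> 0); strictly increasing in the viscosity ratio at fixed
        Y and β — a more viscous test stream carries less flow.
    """
    _validate_series_inputs(mu_ratio_test_over_ref, interface_Y, aspect_beta)
    Q1, Q2, _ = _two_fluid_flow_rates(1.0, mu_ratio_test_over_ref,
                                      interface_Y, aspect_beta, settings)
    return Q1 / Q2


def solve_viscosity_ratio(flow_ratio_q1_over_q2: float, interface_Y: float,
                          aspect_beta: float,
                          settings: SeriesSettings = DEFAULT_SETTINGS,
                          bracket: Tuple[float, float] = (1e-3, 1e3)) -> float:
    """Invert the forward model for the viscosity ratio μ2/μ1.

    Finds ``r`` such that ``series_flow_ratio(r, Y, β) == Q1/Q2`` by a
    bracketing root search in ``log r`` over ``bracket``; monotonicity of
    the forward map across the bracket is checked numerically first.
    """
    if not (np.isfinite(flow_ratio_q1_over_q2) and flow_ratio_q1_over_q2 > 0):
        raise DomainError(f"flow ratio must be positive and finite, got "
                          f"{flow_ratio_q1_over_q2}")
    lo, hi = bracket

    def resid(log_r):
        return (series_flow_ratio(np.exp(log_r), interface_Y, aspect_beta,
                                  settings) - flow_ratio_q1_over_q2)

    f_lo, f_hi = resid(np.log(lo)), resid(np.log(hi))
    f_mid = resid(0.5 * (np.log(lo) + np.log(hi)))
    if not (f_lo < f_mid < f_hi):
        raise InversionError(
            "forward flow-ratio map is not monotone increasing over the "
            "bracket; refusing to invert", bracket_values=(f_lo, f_hi))
    if f_lo > 0 or f_hi < 0:
        raise InversionError(
            f"no viscosity ratio in [{lo:g}, {hi:g}] reproduces flow ratio "
            f"{flow_ratio_q1_over_q2:g}",
            bracket_values=(f_lo + flow_ratio_q1_over_q2,
                            f_hi + flow_ratio_q1_over_q2))
    log_r = brentq(resid, np.log(lo), np.log(hi), xtol=1e-14, rtol=8.9e-16)
    return float(np.exp(log_r))


def solve_interface_position(flow_ratio_q1_over_q2: float, mu_ratio: float,
                             aspect_beta: float,
                             settings: SeriesSettings = DEFAULT_SETTINGS,
                             bracket: Tuple[float, float] = (-0.4995, 0.4995),
                             ) -> float:
    """Interface position Y at which the given flow ratio is realized.

    Needed by the synthetic generator: the pumps fix Q1/Q2 and the
    physics then fixes where the interface sits.
    """
    if not (np.isfinite(flow_ratio_q1_over_q2) and flow_ratio_q1_over_q2 > 0):
        raise DomainError("flow ratio must be positive and finite")
    if not mu_ratio > 0:
        raise DomainError("viscosity ratio must be positive")

    def resid(Y):
        return (series_flow_ratio(mu_ratio, Y, aspect_beta, settings)
                - flow_ratio_q1_over_q2)

    lo, hi = bracket
    f_lo, f_hi = resid(lo), resid(hi)
    # Q1/Q2 decreases as Y grows (reference stream narrows)
    if f_lo < 0 or f_hi > 0:
        raise InversionError(
            f"no interface position in ({lo}, {hi}) yields flow ratio "
            f"{flow_ratio_q1_over_q2:g} at viscosity ratio {mu_ratio:g}",
            bracket_values=(f_lo + flow_ratio_q1_over_q2,
                            f_hi + flow_ratio_q1_over_q2))
    Y = brentq(resid, lo, hi, xtol=1e-14)
    return float(Y)


def apparent_viscosity(problem: CoflowProblem, geometry: ChannelGeometry,
                       settings: SeriesSettings = DEFAULT_SETTINGS) -> float:
    """Apparent viscosity of the test stream (same unit as ``mu_reference``).

    Applies the flow-ratio inversion to the measured (Q1, Q2, Y).
    """
    r = solve_viscosity_ratio(problem.flow_ratio, geometry.interface_Y,
                              geometry.aspect_beta, settings)
    return problem.mu_reference * r


# ---------------------------------------------------------------------------
# single-fluid closed form (oracle for the FD solver)
# ---------------------------------------------------------------------------


def single_fluid_flow_rate(width_m: float, depth_m: float, mu_pa_s: float,
                           pressure_gradient_pa_m: float,
                           n_terms: int = 200) -> float:
    """Classical series solution for one fluid in a rectangular duct (m³/s)."""
    w, h = width_m, depth_m
    n = np.arange(1, 2 * n_terms, 2, dtype=float)
    series = np.sum(np.tanh(n * np.pi * w / (2 * h)) / n ** 5)
    Q = (pressure_gradient_pa_m * h ** 3 * w / (12.0 * mu_pa_s)
         * (1.0 - 192.0 * h / (np.pi ** 5 * w) * series))
    return float(Q)


# ---------------------------------------------------------------------------
# finite-difference oracle / field generator
# ---------------------------------------------------------------------------


def _interface_grid(width_m: float, interface_y_m: float, n_y: int
                    ) -> Tuple[np.ndarray, int]:
    """y-grid through the interface: two uniform blocks sharing a node."""
    total = n_y - 1
    frac2 = (interface_y_m + 0.5 * width_m) / width_m
    m2 = int(round(total * frac2))
    m2 = min(max(m2, 1), total - 1)
    y2 = np.linspace(-0.5 * width_m, interface_y_m, m2 + 1)
    y1 = np.linspace(interface_y_m, 0.5 * width_m, total - m2 + 1)
    return np.concatenate([y2, y1[1:]]), m2


def fd_velocity_field(geometry: ChannelGeometry, mu_reference: float,
                      mu_test: float, pressure_gradient_pa_m: float,
                      grid_shape: Tuple[int, int] = (201, 201)) -> DuctField:
    """Solve ∇·(μ∇u) = −G on the duct cross-section by finite differences.

    Piecewise-constant viscosity split at the interface grid line, no-slip
    on all four walls, and shear-stress continuity enforced naturally by
    the conservative (flux) form with face viscosities taken from the
    fluid each face lies in.  Second-order accurate on each uniform block.

    Parameters are SI (Pa·s, Pa/m); geometry is in μm as everywhere else.
    """
    n_y, n_z = grid_shape
    if n_y < 51 or n_z < 51:
        raise DomainError("grid must be at least 51x51")
    if not (mu_reference > 0 and mu_test > 0):
        raise DomainError("viscosities must be positive")

    w = geometry.width_um * UM_TO_M
    h = geometry.depth_um * UM_TO_M
    y_if = geometry.interface_Y * w

    y, i_if = _interface_grid(w, y_if, n_y)
    z = np.linspace(0.0, h, n_z)
    dz = z[1] - z[0]
    dy = np.diff(y)

    # face viscosity in y (between nodes i and i+1): side of the interface
    y_face_mid = 0.5 * (y[:-1] + y[1:])
    mu_face = np.where(y_face_mid < y_if, mu_test, mu_reference)
    # nodal viscosity for the z-fluxes; interface node gets the mean
    mu_node = np.where(y < y_if, mu_test, mu_reference)
    mu_node[i_if] = 0.5 * (mu_test + mu_reference)

    ni, nj = n_y - 2, n_z - 2  # interior counts

    def idx(i, j):  # i, j are interior indices starting at 0
        return i * nj + j

    ii, jj = np.meshgrid(np.arange(ni), np.arange(nj), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    gi = ii + 1  # global y index

    hy = 0.5 * (dy[gi] + dy[gi - 1])
    a_e = mu_face[gi] / dy[gi] / hy          # coupling to i+1
    a_w = mu_face[gi - 1] / dy[gi - 1] / hy  # coupling to i-1
    a_z = mu_node[gi] / dz ** 2
    a_c = -(a_e + a_w + 2.0 * a_z)

    rows = [idx(ii, jj)]
    cols = [idx(ii, jj)]
    vals = [a_c]
    for di, dj, a in ((1, 0, a_e), (-1, 0, a_w), (0, 1, a_z), (0, -1, a_z)):
        ni2, nj2 = ii + di, jj + dj
        keep = (ni2 >= 0) & (ni2 < ni) & (nj2 >= 0) & (nj2 < nj)
        rows.append(idx(ii, jj)[keep])
        cols.append(idx(ni2, nj2)[keep])
        vals.append(a[keep])

    A = scipy.sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ni * nj, ni * nj))
    b = np.full(ni * nj, -pressure_gradient_pa_m)

    try:
        u_int = scipy.sparse.linalg.spsolve(A, b)
    except Exception as exc:  # pragma: no cover - degenerate geometry
        raise InversionError(f"FD linear system could not be solved: {exc}")

    u = np.zeros((n_y, n_z))
    u[1:-1, 1:-1] = u_int.reshape(ni, nj)

    q_z = np.trapezoid(u, z, axis=1)          # per-y line flux, m²/s
    Q2 = np.trapezoid(q_z[: i_if + 1], y[: i_if + 1])
    Q1 = np.trapezoid(q_z[i_if:], y[i_if:])

    visc_map = np.repeat(mu_node[:, None], n_z, axis=1)

    return DuctField(
        grid_y_um=y * M_TO_UM,
        grid_z_um=z * M_TO_UM,
        axial_velocity_mm_s=u * M_S_TO_MM_S,
        viscosity_map_pa_s=visc_map,
        flow_rate_1_ul_hr=Q1 * M3_S_TO_UL_PER_HR,
        flow_rate_2_ul_hr=Q2 * M3_S_TO_UL_PER_HR,
        geometry=geometry,
        pressure_gradient_pa_m=pressure_gradient_pa_m,
        interface_index=i_if,
    )
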