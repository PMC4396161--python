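"""Verification and validation studies.

* Method-of-manufactured-solutions (MMS) convergence in space for the
  transport discretization (pure diffusion, or diffusion + electromigration
  drift against a prescribed potential), with dt refined as h^2 so the
  spatial error dominates.
* Time-step stability study of the full published scenario.
* Electrophysiological validation: excitability, all-or-none thresholding by
  bisection, and action-potential morphology metrics.

The error norm used throughout is the mesh-weighted L2 norm at final time,
sqrt(e^T M e); the maximum over saved time levels is reported alongside.
Absolute error values depend on this norm choice and are not comparable
across different norm definitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.sparse.linalg as spla

from .config import PhysicalConstants, SpeciesTable
from .dynamics import RunResult, SolverSettings, Simulator
from .fem import (apply_dirichlet, assemble_drift, assemble_mass,
                  assemble_stiffness)
from .kinetics import SuicideSubstrateParams
from .mesh import TriangleMesh, generate_ellipse_mesh, mesh_size
from .stimulus import StimulusProtocol

__all__ = [
    "l2_error", "two_point_order", "ConvergenceReport",
    "mms_convergence_study", "StabilityReport", "stability_study",
    "APMetrics", "ap_metrics", "ValidationReport",
    "validate_electrophysiology",
]


def l2_error(mesh: TriangleMesh, field_values: np.ndarray, exact,
             M=None) -> float:
    """Mesh-weighted L2 norm sqrt(e^T M e) of the nodal difference between a
    field and an exact solution (callable ``exact(x, y)`` or nodal array)."""
    v = np.asarray(field_values, dtype=float).ravel()
    if callable(exact):
        ex = exact(mesh.nodes[:, 0], mesh.nodes[:, 1])
    else:
        ex = np.asarray(exact, dtype=float).ravel()
    e = v - ex
    if M is None:
        M = assemble_mass(mesh)
    return float(np.sqrt(e @ (M @ e)))


def two_point_order(e1: float, h1: float, e2: float, h2: float) -> float:
    """Observed order from two (error, h) pairs: ln(e1/e2)/ln(h1/h2)."""
    return math.log(e1 / e2) / math.log(h1 / h2)


@dataclass
class ConvergenceReport:
    h: list                      # achieved mesh sizes, strictly decreasing
    dt: list
    errors: list                 # L2 at final time, per level
    errors_max: list             # max over saved time levels
    fitted_order: float          # least-squares slope of log e vs log h
    norm: str = "L2(Omega) at T"
    asymptotic: bool = True      # False when errors are not monotone

    def pairwise_orders(self) -> list:
        return [two_point_order(self.errors[i], self.h[i],
                                self.errors[i + 1], self.h[i + 1])
                for i in range(len(self.h) - 1)]


def mms_convergence_study(levels: Sequence[float] = (0.2, 0.15, 0.1),
                          mode: str = "diffusion",
                          d: float = 1.0,
                          drift_m: float = 0.5,
                          a: float = 2.0, b: float = 1.0,
                          T: float = 0.1, dt0: float = 2e-3) -> ConvergenceReport:
    """Spatial convergence of the backward-Euler P1 transport step against a
    manufactured solution u = exp(-t) sin(x) cos(y) on the ellipse.

    ``mode='diffusion'`` solves u_t = d*Lap(u) + g; ``mode='drift'`` adds the
    electromigration term with a prescribed potential phi = x*y and mobility
    ``drift_m``.  The compensating source g makes u exact; Dirichlet values on
    the boundary are the exact trace.  The time step is refined as
    dt = dt0*(h/h0)^2 so the O(dt) temporal error of backward Euler scales
    like the O(h^2) spatial error.
    """
    if len(levels) < 3:
        raise ValueError("need at least 3 refinement levels")
    if mode not in ("diffusion", "drift"):
        raise ValueError(f"unknown MMS mode {mode!r}")
    h0 = levels[0]
    m = drift_m if mode == "drift" else 0.0

    def u_exact(x, y, t):
        return np.exp(-t) * np.sin(x) * np.cos(y)

    def source(x, y, t):
        # u_t - d*Lap u - m*div(u grad phi), phi = x*y (harmonic)
        u = u_exact(x, y, t)
        ux = np.exp(-t) * np.cos(x) * np.cos(y)
        uy = -np.exp(-t) * np.sin(x) * np.sin(y)
        return -u + 2.0 * d * u - m * (ux * y + uy * x)

    hs, dts, errs, errs_max = [], [], [], []
    for h_t in levels:
        mesh = generate_ellipse_mesh(a, b, h_t)
        x, y = mesh.nodes[:, 0], mesh.nodes[:, 1]
        M = assemble_mass(mesh)
        K = assemble_stiffness(mesh, d)
        A = (assemble_drift(mesh, x * y, m) if m != 0.0 else None)
        dt = dt0 * (h_t / h0) ** 2
        n_steps = max(1, round(T / dt))
        dt = T / n_steps
        sys_op = M + dt * K
        if A is not None:
            sys_op = sys_op + dt * A
        bnd = mesh.boundary_nodes
        u = u_exact(x, y, 0.0)
        emax = 0.0
        # LU of the Dirichlet-constrained operator (bc values enter the rhs)
        for n in range(1, n_steps + 1):
            t = n * dt
            rhs = M @ u + dt * (M @ source(x, y, t))
            op_d, rhs_d = apply_dirichlet(sys_op, rhs, bnd,
                                          u_exact(x[bnd], y[bnd], t))
            if n == 1:
                lu = spla.splu(op_d.tocsc())
            u = lu.solve(rhs_d)
            emax = max(emax, l2_error(mesh, u, u_exact(x, y, t), M=M))
        hs.append(mesh_size(mesh))
        dts.append(dt)
        errs.append(l2_error(mesh, u, u_exact(x, y, T), M=M))
        errs_max.append(emax)
    slope = np.polyfit(np.log(hs), np.log(errs), 1)[0]
    monotone = all(errs[i] > errs[i + 1] for i in range(len(errs) - 1))
    return ConvergenceReport(hs, dts, errs, errs_max, float(slope),
                             asymptotic=monotone)


# ---------------------------------------------------------------------------


@dataclass
class StabilityReport:
    dts: list                    # descending time steps
    h: float
    phi_diffs: list              # max |Delta phi| at T between consecutive dts
    c_diffs: list                # max |Delta C| at T between consecutive dts
    phi_range: float             # max |phi| scale at T, for relative reading

    def decreasing(self) -> bool:
        return all(self.phi_diffs[i + 1] <= self.phi_diffs[i]
                   for i in range(len(self.phi_diffs) - 1))


def _default_model(h: float, **overrides):
    mesh = generate_ellipse_mesh(2.0, 1.0, h)
    kw = dict(constants=PhysicalConstants(), species=SpeciesTable(),
              kinetics=SuicideSubstrateParams(), stimulus=StimulusProtocol())
    kw.update(overrides)
    return mesh, kw


def stability_study(dts: Sequence[float] = (1e-5, 5e-6, 2.5e-6),
                    h: float = 0.15, T: float = 0.006,
                    **overrides) -> StabilityReport:
    """Run the full published scenario at several time steps on one mesh and
    compare the final-time fields pairwise (consecutive dts)."""
    mesh, kw = _default_model(h, **overrides)
    dts = sorted(dts, reverse=True)
    finals = []
    for dt in dts:
        sim = Simulator(mesh, settings=SolverSettings(dt=dt, T=T), **kw)
        res = sim.run()
        finals.append((res.final_state.phi, res.final_state.C))
    phi_diffs = [float(np.max(np.abs(finals[i][0] - finals[i + 1][0])))
                 for i in range(len(dts) - 1)]
    c_diffs = [float(np.max(np.abs(finals[i][1] - finals[i + 1][1])))
               for i in range(len(dts) - 1)]
    scale = float(np.max(np.abs(finals[-1][0])))
    return StabilityReport(list(dts), h, phi_diffs, c_diffs, scale)


# ---------------------------------------------------------------------------


@dataclass
class APMetrics:
    """Shape descriptors of the membrane-potential response at a probe."""

    peak_potential: float        # mV at the extremum of the deflection
    peak_deflection: float       # signed deflection from the pre-onset baseline
    time_to_peak: float          # s, from stimulus onset
    repolarized: bool            # deflection back below 50% of peak by T
    plateau_fraction: float      # fraction of AP duration within 5% of peak

    def __post_init__(self) -> None:
        if not (0.0 <= self.plateau_fraction <= 1.0):
            raise ValueError("plateau fraction must lie in [0, 1]")


def ap_metrics(t: np.ndarray, phi: np.ndarray, onset: float) -> APMetrics:
    """Morphology metrics of a potential trace.

    The baseline is the value immediately before onset; the AP duration is the
    span where |deflection| exceeds half its peak; the plateau fraction is the
    portion of that span spent within 5% of the peak (a triangular AP has a
    small plateau fraction, a square one a fraction near 1).
    """
    t = np.asarray(t, dtype=float)
    phi = np.asarray(phi, dtype=float)
    pre = np.searchsorted(t, onset, side="left")
    baseline = phi[max(pre - 1, 0)]
    defl = phi - baseline
    mask = t >= onset
    idx = np.flatnonzero(mask)
    k = idx[np.argmax(np.abs(defl[idx]))]
    peak = defl[k]
    if peak == 0.0:
        return APMetrics(float(phi[k]), 0.0, float(t[k] - onset), True, 0.0)
    rel = defl / peak                     # 1 at the peak, sign-free
    above_half = mask & (rel >= 0.5)
    dur = float(np.trapezoid(above_half.astype(float), t))
    within5 = mask & (rel >= 0.95)
    plateau = float(np.trapezoid(within5.astype(float), t))
    frac = plateau / dur if dur > 0 else 0.0
    return APMetrics(float(phi[k]), float(peak), float(t[k] - onset),
                     bool(rel[-1] < 0.5), min(frac, 1.0))


@dataclass
class ValidationReport:
    excitable: bool              # no-stimulus run stays at rest
    rest_deviation: float        # max |phi - phi(0)| at the probe, no stimulus
    ap_detected: bool            # supra-threshold stimulus elicits an AP
    threshold: Optional[float]   # stimulus magnitude at the AP threshold
    all_or_none: bool            # half-threshold stimulus elicits no AP
    metrics: APMetrics           # morphology of the supra-threshold AP
    tested_amplitudes: list      # (magnitude, ap?) pairs from the bisection


def validate_electrophysiology(h: float = 0.15,
                               amplitude: float = -200.0,
                               bisect_iters: int = 8,
                               settings: SolverSettings = SolverSettings(),
                               **overrides) -> ValidationReport:
    """The three-part electrophysiological validation.

    (a) excitability: before the stimulus onset the probe trace at the cell
    center stays at its initial value; (b) all-or-none: bisection on the
    stimulus magnitude between 0 and |amplitude| locates the AP threshold,
    and a half-threshold pulse elicits no AP; (c) morphology: the
    supra-threshold AP is triangular (plateau fraction < 0.2).

    The stimulus response of a run is its probe trace minus that of the
    no-stimulus run (the two are identical before onset, so this isolates
    the AP from the slow relaxation of the -80 mV initial condition toward
    the grounded membrane).  An AP is detected when the peak response reaches
    half that of the reference supra-threshold run.
    """
    mesh, kw = _default_model(h, **overrides)
    proto = kw.pop("stimulus")

    def trace(amp: float):
        stim = replace(proto, amplitude=amp) if amp != 0.0 else None
        sim = Simulator(mesh, stimulus=stim, settings=settings, **kw)
        res = sim.run()
        return res.t, res.probe_phi[0]

    t, phi_rest_trace = trace(0.0)
    pre = t <= proto.onset
    rest_dev = float(np.max(np.abs(phi_rest_trace[pre] - phi_rest_trace[0])))

    _, phi_supra = trace(amplitude)
    response_supra = phi_supra - phi_rest_trace
    metrics = ap_metrics(t, response_supra + phi_supra[0], proto.onset)
    supra_defl = abs(metrics.peak_deflection)
    excitable = supra_defl > 0 and rest_dev < 0.05 * supra_defl

    def has_ap(amp_mag: float) -> bool:
        if amp_mag == 0.0:
            return False
        _, phi = trace(math.copysign(amp_mag, amplitude))
        m = ap_metrics(t, phi - phi_rest_trace + phi[0], proto.onset)
        return abs(m.peak_deflection) >= 0.5 * supra_defl

    lo, hi = 0.0, abs(amplitude)       # lo: no AP, hi: AP
    tested = [(0.0, False), (hi, True)]
    threshold: Optional[float] = None
    for _ in range(bisect_iters):
        mid = 0.5 * (lo + hi)
        ap = has_ap(mid)
        tested.append((mid, ap))
        if ap:
            hi = mid
        else:
            lo = mid
    threshold = 0.5 * (lo + hi)
    all_or_none = not has_ap(0.5 * threshold)
    # monotonicity sanity: every tested amplitude below the threshold must
    # lack an AP and every one above must have one
    for mag, ap in tested:
        if (mag < lo and ap) or (mag > hi and not ap):
            threshold = None
            break
    return ValidationReport(excitable, rest_dev, supra_defl > 0, threshold,
                            all_or_none, metrics, tested)
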