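"""Suicide-substrate (mechanism-based inhibition) mass-action kinetics.

The reaction scheme is

    E + S <-> X -> Y,   Y -> E + P  (rate k3),   Y -> Ei  (rate k4)

with reversible binding (k1 forward, k-1 back) and irreversible turnover k2.
The intermediate Y partitions between productive turnover (k3) and enzyme
inactivation (k4); their ratio r = k3/k4 is the partition ratio.  With
mu = e0/s0, the factor (1+r)*mu decides the outcome: > 1 the substrate is
exhausted first, < 1 the enzyme is fully inactivated, = 1 both occur
(Tatsunami's criterion; Waley's earlier factor was r*mu).

Species order is fixed as (E, S, X, Y, P, Ei) = (C1..C6) throughout the
package.  Two stoichiometric moieties are conserved by the rates identically:
enzyme e + x + y + ei, and substrate s + x + y + p + ei (the inactivated
complex Ei contains the substrate-derived inhibitor, so it counts in both).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SuicideSubstrateParams",
    "SPECIES_NAMES",
    "ENZYME_MOIETY",
    "SUBSTRATE_MOIETY",
    "reaction_rates",
    "reaction_jacobian",
    "partition_ratio",
    "classify_outcome",
    "OutcomeReport",
    "simulate_well_mixed",
    "WellMixedResult",
    "outcome_from_trajectory",
]

SPECIES_NAMES = ("E", "S", "X", "Y", "P", "Ei")
#: indices of the conserved enzyme moiety e + x + y + ei
ENZYME_MOIETY = (0, 2, 3, 5)
#: indices of the conserved substrate moiety s + x + y + p + ei
SUBSTRATE_MOIETY = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class SuicideSubstrateParams:
    """Positive mass-action rate constants (s^-1 scale).  Defaults are the
    published set k1=2, k-1=4, k2=12, k3=10, k4=2."""

    k1: float = 2.0
    k_1: float = 4.0
    k2: float = 12.0
    k3: float = 10.0
    k4: float = 2.0

    def __post_init__(self) -> None:
        for name in ("k1", "k_1", "k2", "k3", "k4"):
            if not getattr(self, name) > 0:
                raise ValueError(f"rate constant {name} must be strictly "
                                 f"positive, got {getattr(self, name)!r}")


def reaction_rates(state, params: SuicideSubstrateParams, *,
                   check: bool = True) -> np.ndarray:
    """Mass-action production rates F_i for the state (e, s, x, y, p, ei).

    ``state`` has shape (6,) or (6, n) (nodal fields); the result has the same
    shape.  Negative concentrations raise a ValueError when ``check`` is true;
    clipping is the caller's policy, not this function's.
    """
    c = np.asarray(state, dtype=float)
    if c.shape[0] != 6:
        raise ValueError("state must have 6 species on the leading axis")
    if check and (c < 0).any():
        raise ValueError("negative concentration in kinetic state")
    e, s, x, y = c[0], c[1], c[2], c[3]
    k = params
    binding = k.k1 * e * s
    F = np.empty_like(c)
    F[0] = -binding + k.k_1 * x + k.k3 * y          # E
    F[1] = -binding + k.k_1 * x                     # S
    F[2] = binding - (k.k_1 + k.k2) * x             # X
    F[3] = k.k2 * x - (k.k3 + k.k4) * y             # Y
    F[4] = k.k3 * y                                 # P
    F[5] = k.k4 * y                                 # Ei
    return F


def reaction_jacobian(state, params: SuicideSubstrateParams) -> np.ndarray:
    """Analytic Jacobian dF_i/dC_j; shape (6, 6) for a (6,) state or
    (6, 6, n) for nodal fields (6, n)."""
    c = np.asarray(state, dtype=float)
    e, s = c[0], c[1]
    k = params
    J = np.zeros((6, 6) + c.shape[1:])
    J[0, 0] = -k.k1 * s
    J[0, 1] = -k.k1 * e
    J[0, 2] = k.k_1
    J[0, 3] = k.k3
    J[1, 0] = -k.k1 * s
    J[1, 1] = -k.k1 * e
    J[1, 2] = k.k_1
    J[2, 0] = k.k1 * s
    J[2, 1] = k.k1 * e
    J[2, 2] = -(k.k_1 + k.k2)
    J[3, 2] = k.k2
    J[3, 3] = -(k.k3 + k.k4)
    J[4, 3] = k.k3
    J[5, 3] = k.k4
    return J


def partition_ratio(params: SuicideSubstrateParams) -> float:
    """r = k3/k4, productive turnover relative to inactivation."""
    return params.k3 / params.k4


@dataclass(frozen=True)
class OutcomeReport:
    classification: str          # substrate_exhausted | enzyme_inactivated | boundary
    mu: float                    # e0/s0
    tatsunami_factor: float      # (1 + r) * mu
    waley_factor: float          # r * mu


def classify_outcome(r: float, e0: float, s0: float) -> OutcomeReport:
    """Tatsunami classification of the reaction endpoint from (1+r)*mu."""
    if s0 <= 0:
        raise ValueError("s0 must be strictly positive")
    if e0 <= 0:
        raise ValueError("e0 must be strictly positive")
    mu = e0 / s0
    factor = (1.0 + r) * mu
    if abs(factor - 1.0) < 1e-12:
        cls = "boundary"
    elif factor > 1.0:
        cls = "substrate_exhausted"
    else:
        cls = "enzyme_inactivated"
    return OutcomeReport(cls, mu, factor, r * mu)


@dataclass
class WellMixedResult:
    t: np.ndarray                # (nt,)
    c: np.ndarray                # (nt, 6)
    endpoint_error: float        # step-halving (Richardson) estimate at T

    def final(self) -> np.ndarray:
        return self.c[-1]


def _rk4(f, c0: np.ndarray, t0: float, T: float, dt: float):
    n_steps = int(round((T - t0) / dt))
    t = t0 + dt * np.arange(n_steps + 1)
    out = np.empty((n_steps + 1, c0.size))
    out[0] = c0
    c = c0.copy()
    for n in range(n_steps):
        k1 = f(c)
        k2 = f(c + 0.5 * dt * k1)
        k3 = f(c + 0.5 * dt * k2)
        k4 = f(c + dt * k3)
        c = c + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.isfinite(c).all():
            raise RuntimeError(f"well-mixed RK4 diverged at t={t[n + 1]:.6g}")
        out[n + 1] = c
    return t, out


def simulate_well_mixed(params: SuicideSubstrateParams, init, T: float,
                        dt: float) -> WellMixedResult:
    """Classical fixed-step RK4 trajectory of the well-mixed ODE dC/dt = F(C).

    This is the zero-dimensional oracle for the spatially uniform PDE limit.
    A second run at dt/2 provides the step-halving endpoint error estimate.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if T < dt:
        raise ValueError("T must be at least dt")
    c0 = np.asarray(init, dtype=float)
    if c0.shape != (6,):
        raise ValueError("init must be a 6-vector (e, s, x, y, p, ei)")

    def f(c):
        return reaction_rates(c, params, check=False)

    t, c = _rk4(f, c0, 0.0, T, dt)
    _, c_half = _rk4(f, c0, 0.0, T, dt / 2.0)
    err = float(np.max(np.abs(c[-1] - c_half[-1])))
    return WellMixedResult(t, c, err)


def outcome_from_trajectory(result: WellMixedResult, e0: float, s0: float,
                            rel_tol: float = 1e-3) -> str:
    """Operational endpoint classification of a long trajectory: the substrate
    is exhausted when s(T) < rel_tol*s0, the enzyme inactivated when the
    available enzyme e + x + y < rel_tol*e0; 'boundary' when both, 'neither'
    when the run was too short."""
    cT = result.final()
    s_gone = cT[1] < rel_tol * s0
    e_gone = (cT[0] + cT[2] + cT[3]) < rel_tol * e0
    if s_gone and e_gone:
        return "boundary"
    if s_gone:
        return "substrate_exhausted"
    if e_gone:
        return "enzyme_inactivated"
    return "neither"
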