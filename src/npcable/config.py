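"""Physical constants, the ionic species table, and derived transport parameters.

This module is the single source of truth for every symbol of the model:
membrane constants (capacitance ``Cm``, resistivity ``rho``, surface-to-volume
ratio ``S``), the resting/initial potentials, and the per-species diffusion
coefficients, valences and initial concentrations.

Unit regime
-----------
The model is solved in a single consistent "model unit" system: time in
seconds, potential in mV, concentrations in uM, lengths in the units of the
elliptical cell (semi-axes a=2, b=1).  Two physical scale factors are not
pinned down by the published parameter set and are therefore explicit,
configurable model-unit numbers (default 1):

* ``beta_drift`` -- the factor Fa/(R*Te) of the Einstein relation, setting the
  strength of electromigration drift relative to diffusion;
* ``faraday_model`` -- the factor Fa multiplying the net ionic charge
  production in the potential equation.

Only :func:`cable_diffusion` performs genuine unit conversion: it takes the
membrane constants in their conventional laboratory units (Ohm*cm, um^-1,
uF/cm^2) and returns the cable "diffusion" coefficient D = 1/(rho*S*Cm) in
cm^2/ms.  The PDE solver uses seconds as its time unit, so the coefficient is
re-expressed per second there (see :meth:`PhysicalConstants.cable_diffusion_model`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PhysicalConstants",
    "SpeciesTable",
    "cable_diffusion",
    "einstein_mobility",
    "FARADAY_SI",
    "GAS_CONSTANT_SI",
]

#: Faraday constant, C/mol (SI; used for real-unit mobility calculations only).
FARADAY_SI = 96485.33212
#: Universal gas constant, J/(mol*K).
GAS_CONSTANT_SI = 8.314462618


def cable_diffusion(rho: float, S: float, Cm: float) -> float:
    """Cable-equation diffusion coefficient D = 1/(rho*S*Cm), in cm^2/ms.

    Parameters
    ----------
    rho : cellular resistivity, Ohm*cm.
    S   : surface-to-volume ratio, um^-1.
    Cm  : membrane capacitance per unit area, uF/cm^2.

    The product rho*S*Cm has units (Ohm*cm)(cm^-1)(F/cm^2) = s/cm^2 once S is
    converted to cm^-1 (1 um^-1 = 1e4 cm^-1) and Cm to F/cm^2, so the inverse
    is in cm^2/s; division by 1000 expresses it per millisecond.  With the
    standard human-myocyte values (162, 0.2, 2.0) this evaluates to
    0.00154 cm^2/ms.
    """
    for name, v in (("rho", rho), ("S", S), ("Cm", Cm)):
        if not v > 0:
            raise ValueError(f"{name} must be strictly positive, got {v!r}")
    S_cm = S * 1e4          # um^-1 -> cm^-1
    Cm_F = Cm * 1e-6        # uF/cm^2 -> F/cm^2
    return 1.0 / (rho * S_cm * Cm_F) / 1000.0


def einstein_mobility(d: float, z: float, Fa: float = FARADAY_SI,
                      R: float = GAS_CONSTANT_SI, Te: float = 310.0) -> float:
    """Einstein relation m = d*z*Fa/(R*Te) linking mobility to diffusivity.

    The mobility carries the sign of the valence ``z``; a neutral species has
    zero mobility.  ``Fa``, ``R`` and ``Te`` default to SI values at body
    temperature; pass model-unit factors to work in the solver's unit system.
    """
    if not d > 0:
        raise ValueError(f"diffusion coefficient must be positive, got {d!r}")
    for name, v in (("Fa", Fa), ("R", R), ("Te", Te)):
        if not v > 0:
            raise ValueError(f"{name} must be strictly positive, got {v!r}")
    return d * z * Fa / (R * Te)


@dataclass(frozen=True)
class PhysicalConstants:
    """Membrane and environment constants of the single-cell model.

    Defaults are the published human-myocyte values: Cm = 2.0 uF/cm^2,
    S = 0.2 um^-1, rho = 162 Ohm*cm, resting potential 0 mV, initial
    potential -80 mV.
    """

    Fa: float = FARADAY_SI        # C/mol
    R: float = GAS_CONSTANT_SI    # J/(mol K)
    Te: float = 310.0             # K
    Cm: float = 2.0               # uF/cm^2
    rho: float = 162.0            # Ohm cm
    S: float = 0.2                # um^-1
    phi_rest: float = 0.0         # mV (Dirichlet value on the membrane)
    phi0: float = -80.0           # mV (initial interior potential)
    beta_drift: float = 1.0       # Fa/(R*Te) in model units (drift scale)
    faraday_model: float = 1.0    # Fa in model units (ionic coupling scale)

    def __post_init__(self) -> None:
        for name in ("Fa", "R", "Te", "Cm", "rho", "S"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"PhysicalConstants.{name} must be strictly "
                                 f"positive, got {v!r}")

    def cable_diffusion(self) -> float:
        """D = 1/(rho*S*Cm) in cm^2/ms (the conventional printed unit)."""
        return cable_diffusion(self.rho, self.S, self.Cm)

    def cable_diffusion_model(self) -> float:
        """D in the solver's model units (per second): cm^2/ms * 1000."""
        return self.cable_diffusion() * 1000.0


# species order is fixed positionally: (E, S, X, Y, P, Ei) <-> (C1..C6),
# matching the printed diffusion/valence lists.
_DEFAULT_NAMES = ("E", "S", "X", "Y", "P", "Ei")
_DEFAULT_D = (1e-3, 2e-3, 5e-3, 1e-3, 2e-3, 4e-6)
_DEFAULT_Z = (1, -1, 1, 1, 1, -1)
_DEFAULT_C0 = (0.5, 0.5, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SpeciesTable:
    """Per-species transport data: names, diffusivities d_i, valences z_i and
    initial (spatially uniform) concentrations C_i0 in uM.

    The default is the six-species suicide-substrate system in the fixed order
    (enzyme E, substrate S, intermediates X and Y, product P, inactivated
    enzyme Ei), with the published d_i, z_i and e0 = s0 = 0.5 uM.
    """

    names: tuple[str, ...] = _DEFAULT_NAMES
    d: tuple[float, ...] = _DEFAULT_D
    z: tuple[int, ...] = _DEFAULT_Z
    c0: tuple[float, ...] = _DEFAULT_C0

    def __post_init__(self) -> None:
        n = len(self.names)
        if not (len(self.d) == len(self.z) == len(self.c0) == n):
            raise ValueError("names, d, z, c0 must have equal length")
        if any(not di > 0 for di in self.d):
            raise ValueError("all diffusion coefficients d_i must be positive")
        if any(ci < 0 for ci in self.c0):
            raise ValueError("initial concentrations must be non-negative")
        object.__setattr__(self, "d", tuple(float(x) for x in self.d))
        object.__setattr__(self, "z", tuple(int(x) for x in self.z))
        object.__setattr__(self, "c0", tuple(float(x) for x in self.c0))

    @property
    def n_species(self) -> int:
        return len(self.names)

    def d_array(self) -> np.ndarray:
        return np.asarray(self.d, dtype=float)

    def z_array(self) -> np.ndarray:
        return np.asarray(self.z, dtype=float)

    def c0_array(self) -> np.ndarray:
        return np.asarray(self.c0, dtype=float)

    def mobilities(self, beta_drift: float = 1.0) -> np.ndarray:
        """Model-unit mobilities m_i = d_i * z_i * beta_drift (Einstein
        relation with Fa/(R*Te) = ``beta_drift``)."""
        return self.d_array() * self.z_array() * float(beta_drift)

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "SpeciesTable":
        """Build from a list of ``{name, d, z, c0}`` mappings (config files)."""
        return cls(
            names=tuple(str(r["name"]) for r in records),
            d=tuple(float(r["d"]) for r in records),
            z=tuple(int(r["z"]) for r in records),
            c0=tuple(float(r["c0"]) for r in records),
        )
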