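"""Stimulation protocols: square pulse, sign-alternating, sinusoidal.

The external current I_stim is localized in space by the Gaussian Dirac
surrogate f = exp(-sharpness*|x - center|^2) and modulated in time by one of
three protocols.  The published default is a single square pulse of
-200 uA/cm^2 lasting 1 ms, beginning at t = 120e-5 s, applied at the cell
center (0, 0) with sharpness 1000.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import pi, sin
from typing import Optional

import numpy as np

from .fem import assemble_point_source
from .mesh import TriangleMesh

__all__ = ["StimulusProtocol", "stim_amplitude", "stim_field"]

_KINDS = ("pulse", "alternating", "sinusoidal")


@dataclass(frozen=True)
class StimulusProtocol:
    """Time/space description of the applied current.

    amplitude in uA/cm^2; onset and duration in s; ``frequency`` (rad/s) only
    matters for the sinusoidal kind and defaults to one full period over the
    stimulus duration.  ``kind='alternating'`` flips the sign of the amplitude
    at every time step of the solver.
    """

    kind: str = "pulse"
    amplitude: float = -200.0
    onset: float = 120e-5
    duration: float = 1e-3
    center: tuple[float, float] = (0.0, 0.0)
    sharpness: float = 1000.0
    frequency: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown stimulus kind {self.kind!r}; "
                             f"expected one of {_KINDS}")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if self.onset < 0:
            raise ValueError("onset must be non-negative")
        if not self.sharpness > 0:
            raise ValueError("sharpness must be positive")

    @property
    def omega(self) -> float:
        return self.frequency if self.frequency is not None \
            else 2.0 * pi / self.duration


def stim_amplitude(protocol: StimulusProtocol, t: float,
                   step_index: int = 0) -> float:
    """Instantaneous stimulus amplitude at time ``t`` (solver step ``n``).

    Zero outside [onset, onset + duration]; inside, the pulse is constant, the
    alternating protocol is amplitude*(-1)^n, and the sinusoidal protocol is
    amplitude*sin(omega*(t - onset)).
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    p = protocol
    if t < p.onset or t > p.onset + p.duration:
        return 0.0
    if p.kind == "pulse":
        return p.amplitude
    if p.kind == "alternating":
        return p.amplitude * (-1.0) ** (step_index % 2)
    return p.amplitude * sin(p.omega * (t - p.onset))


def stim_field(protocol: StimulusProtocol, mesh: TriangleMesh, t: float,
               step_index: int = 0,
               base_load: Optional[np.ndarray] = None) -> np.ndarray:
    """Assembled load vector stim_amplitude(t) * int f psi_i.

    ``base_load`` allows reuse of the (time-independent) spatial Gaussian load
    across steps; when omitted it is assembled here.
    """
    if base_load is None:
        base_load = assemble_point_source(mesh, protocol.center,
                                          protocol.sharpness)
    return stim_amplitude(protocol, t, step_index) * base_load
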