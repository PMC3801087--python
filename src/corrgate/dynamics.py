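"""Single-neuron quadratic integrate-and-fire (QIF) dynamics.

The QIF equation

    tau dv/dt = v**2 - b**2 + I(t)

is the normal form of type-1 spike initiation.  The membrane potential ``v``
is dimensionless; ``-b`` is the stable resting potential and ``+b`` the
unstable spike-initiation threshold of the noiseless neuron.  A spike is
emitted when ``v`` reaches ``v_t`` and the voltage is reset to ``v_r``.
Synapses are instantaneous: every presynaptic event increments ``v`` by its
synaptic strength ``J`` within the Euler step in which it arrives, so the
per-step input is simply the summed weight of the events delivered in that
step.

This module is the pure computational kernel: a single Euler step, plus the
closed-form firing period under constant drive which serves as an accuracy
oracle for the integrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class NeuronParams:
    """QIF constants shared by all neurons of a population.

    Parameters
    ----------
    tau : float
        Membrane time constant in ms.
    b : float
        Magnitude of the resting potential (dimensionless voltage); the
        noiseless neuron rests at ``-b`` and has its firing threshold at
        ``+b``.
    v_t : float
        Spike threshold (dimensionless).
    v_r : float
        Reset potential (dimensionless).
    """

    tau: float = 20.0
    b: float = 1.0
    v_t: float = 20.0
    v_r: float = -20.0

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if not (self.v_r < -self.b < self.b < self.v_t):
            raise ValueError(
                "parameters must satisfy v_r < -b < b < v_t, got "
                f"v_r={self.v_r}, b={self.b}, v_t={self.v_t}"
            )


@dataclass
class VoltageState:
    """Membrane potential of one neuron plus a flag for a spike in the last step."""

    v: float
    spiked: bool = field(default=False)


def qif_step(
    state: VoltageState,
    params: NeuronParams,
    input_increment: float = 0.0,
    dt: float = 0.1,
) -> VoltageState:
    """Advance one Euler step of the QIF equation with delta-pulse input.

    ``input_increment`` is the summed synaptic weight of all events delivered
    during this step (each delta-pulse event integrates to a voltage jump of
    exactly its weight, so delivering k events in one step is identical to
    delivering their summed weight once).  If the updated voltage reaches the
    threshold ``params.v_t`` the spike flag is set and the voltage is reset to
    ``params.v_r`` exactly, with no carry-over of the overshoot.

    Raises
    ------
    ValueError
        If ``dt`` is not positive.
    FloatingPointError
        If the updated voltage is non-finite (parameter blow-up; the state is
        never silently clamped).
    """
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    v = state.v
    v_new = v + (dt / params.tau) * (v * v - params.b * params.b) + input_increment
    if not math.isfinite(v_new):
        raise FloatingPointError(
            f"non-finite membrane potential after step (v={v}, "
            f"increment={input_increment})"
        )
    if v_new >= params.v_t:
        return VoltageState(v=params.v_r, spiked=True)
    return VoltageState(v=v_new, spiked=False)


def analytic_period(params: NeuronParams, i_const: float) -> float:
    """Closed-form firing period of the QIF neuron under constant drive.

    For constant suprathreshold input ``i_const > b**2`` the time from reset
    to threshold follows from integrating ``tau dv/(v**2 + a**2) = dt`` with
    ``a = sqrt(i_const - b**2)``:

        T = tau/a * (atan(v_t/a) - atan(v_r/a))

    Used as an independent oracle for the accuracy of the Euler integrator.

    Raises
    ------
    ValueError
        If ``i_const <= b**2`` (subthreshold drive: no periodic solution).
    """
    drive = i_const - params.b * params.b
    if drive <= 0:
        raise ValueError(
            f"constant drive {i_const} is subthreshold (needs > b^2 = "
            f"{params.b**2}); no periodic firing"
        )
    a = math.sqrt(drive)
    return params.tau / a * (math.atan(params.v_t / a) - math.atan(params.v_r / a))
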