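"""Kinetic model of non-photochemical quenching (NPQ) induction and relaxation.

NPQ relaxation after a high-light period is decomposed into three phases:
a fast, energy-dependent component qE (time constant < 2 min), an
intermediate component qM (2-30 min), and a slow, photoinhibitory
component qI (> 30 min, treated as non-relaxing on the time scale of a
single measurement).  The relaxation curve is

    NPQ(t) = A_qI + A_qE * exp(-t / tau_qE) + A_qM * exp(-t / tau_qM)

with t measured in minutes from the moment the high actinic light is
switched off.  Induction under high light is modelled as a mono-exponential
rise toward the amplitude sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["KineticsTruth", "relaxation_curve", "induction_curve"]


def relaxation_curve(t, a_qi, a_qe, tau_qe, a_qm, tau_qm):
    """Double-exponential (plus offset) NPQ relaxation.

    Parameters
    ----------
    t : array-like
        Minutes since the high->low light transition.
    a_qi, a_qe, a_qm : float
        Amplitudes of the slow, fast and intermediate components (NPQ units).
    tau_qe, tau_qm : float
        Relaxation time constants of qE and qM in minutes.
    """
    t = np.asarray(t, dtype=float)
    return a_qi + a_qe * np.exp(-t / tau_qe) + a_qm * np.exp(-t / tau_qm)


def induction_curve(t, amplitude_sum, induction_tau):
    """Mono-exponential NPQ rise toward ``amplitude_sum`` under high light."""
    t = np.asarray(t, dtype=float)
    return amplitude_sum * (1.0 - np.exp(-t / induction_tau))


@dataclass(frozen=True)
class KineticsTruth:
    """Ground-truth kinetic parameters of one leaf disk.

    Amplitudes are in NPQ units, time constants in minutes.
    ``induction_tau`` shapes the NPQ rise during the high-light phase; only
    the relaxation parameters are recovered by curve fitting.
    """

    a_qe: float
    a_qm: float
    a_qi: float
    tau_qe: float
    tau_qm: float
    induction_tau: float = 1.5

    def __post_init__(self):
        for name in ("a_qe", "a_qm", "a_qi"):
            if getattr(self, name) < 0:
                raise ValueError(f"amplitude {name} must be >= 0")
        if not (0 < self.tau_qe < self.tau_qm):
            raise ValueError("require 0 < tau_qe < tau_qm")
        if self.induction_tau <= 0:
            raise ValueError("induction_tau must be > 0")

    @property
    def amplitude_sum(self) -> float:
        return self.a_qe + self.a_qm + self.a_qi

    def npq_at(self, phase: str, t_min) -> np.ndarray:
        """True NPQ at time ``t_min`` (minutes within ``phase``).

        The initial low-light phase carries no quenching; the high-light
        phase follows the induction curve; the final low-light phase follows
        the relaxation curve with t = 0 at light-off.
        """
        t = np.asarray(t_min, dtype=float)
        if phase == "lowlight1":
            return np.zeros_like(t)
        if phase == "highlight":
            return induction_curve(t, self.amplitude_sum, self.induction_tau)
        if phase == "lowlight2":
            return relaxation_curve(t, self.a_qi, self.a_qe, self.tau_qe, self.a_qm, self.tau_qm)
        raise ValueError(f"unknown phase {phase!r}")
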