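"""Saturating-pulse measurement protocol for the leaf-disk NPQ assay.

The default schedule reproduces the low-high-low actinic sequence used for
field leaf disks: 10 min at 50 umol m-2 s-1, 15 min at 2000, 50 min back at
50, with 4000 umol m-2 s-1 saturating pulses at fixed offsets within each
phase (4 pulses during the first low-light phase, 6 during high light, 11
during relaxation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

PHASES = ("lowlight1", "highlight", "lowlight2")

_DEFAULT_DURATIONS = {"lowlight1": 10.0, "highlight": 15.0, "lowlight2": 50.0}
_DEFAULT_ACTINIC = {"lowlight1": 50.0, "highlight": 2000.0, "lowlight2": 50.0}
_DEFAULT_OFFSETS = {
    "lowlight1": (2.5, 5.0, 7.5, 10.0),
    "highlight": (2.5, 5.0, 7.5, 10.0, 12.5, 15.0),
    "lowlight2": (2.5, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 50.0),
}


@dataclass(frozen=True)
class ProtocolSchedule:
    """Phase durations, actinic levels and pulse offsets (minutes).

    Pulse offsets are relative to the start of their phase and must be
    strictly increasing and within the phase duration.
    """

    durations_min: dict = field(default_factory=lambda: dict(_DEFAULT_DURATIONS))
    actinic_umol: dict = field(default_factory=lambda: dict(_DEFAULT_ACTINIC))
    pulse_umol: float = 4000.0
    pulse_offsets_min: dict = field(default_factory=lambda: {k: tuple(v) for k, v in _DEFAULT_OFFSETS.items()})

    def __post_init__(self):
        for phase in PHASES:
            if phase not in self.durations_min or phase not in self.pulse_offsets_min:
                raise ValueError(f"protocol missing phase {phase!r}")
            offsets = tuple(self.pulse_offsets_min[phase])
            if any(b <= a for a, b in zip(offsets, offsets[1:])):
                raise ValueError(f"pulse offsets in {phase!r} must be strictly increasing")
            if offsets and offsets[-1] > self.durations_min[phase] + 1e-9:
                raise ValueError(f"pulse offsets in {phase!r} exceed phase duration")

    def pulses(self):
        """Yield (phase, t_min) for every saturating pulse in order."""
        for phase in PHASES:
            for t in self.pulse_offsets_min[phase]:
                yield phase, float(t)

    @property
    def n_relaxation_pulses(self) -> int:
        return len(self.pulse_offsets_min["lowlight2"])
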