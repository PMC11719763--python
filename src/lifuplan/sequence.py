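"""Plans (requested dose + sequence parameters) and pulse timelines.

A *Plan* holds the user-requested pulse, sequence, and beamforming
parameters; compiling it yields a *Timeline* of (start time, focus index,
duration) pulse events. Multi-focus plans raster the pulses across the foci
in a fixed cyclic order (interleaved pulses), which spreads the time-average
intensity across the focal pattern without lowering the per-pulse pressure.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np
import yaml

from .exceptions import PlanRangeError

#: Allowed [min, max] per plan parameter. ``None`` means unbounded.
PARAMETER_RANGES = {
    "voltage_v": (5.0, 35.0),
    "duration_ms": (0.0, 100.0),
    "pri_ms": (10.0, 1000.0),
    "pulse_count": (1, 1000),
    "ptri_s": (0.0, 120.0),
    "train_count": (1, None),
    "pnp_kpa": (100.0, 1000.0),
}

NOMINAL_FOCUS_MM = (0.0, 0.0, 50.0)


@dataclass(frozen=True)
class Plan:
    """Requested ultrasound dose and sequence parameters.

    Units follow the configuration table conventions: frequency in kHz,
    voltage in V, pulse duration and PRI in ms, PTRI in s, target peak
    negative pressure in kPa, simulation voxel spacing in mm. ``foci`` are
    target points in the transducer frame (mm); single-focus plans list one.
    """

    frequency_khz: float = 400.0
    voltage_v: float = 20.0
    duration_ms: float = 5.0
    pri_ms: float = 100.0
    pulse_count: int = 300
    ptri_s: float = 30.0
    train_count: int = 20
    pnp_kpa: float = 820.0
    spacing_mm: float = 1.0
    foci: tuple = ((0.0, 0.0, 50.0),)
    max_tic: float = 3.0
    max_grating_ratio: float = 0.5

    @property
    def n_foci(self) -> int:
        return len(self.foci)

    @property
    def foci_array(self) -> np.ndarray:
        return np.asarray(self.foci, dtype=float).reshape(-1, 3)

    @property
    def train_on_time_s(self) -> float:
        return self.pulse_count * self.pri_ms / 1000.0

    def to_dict(self) -> dict:
        return {
            "frequency_khz": self.frequency_khz,
            "voltage_v": self.voltage_v,
            "duration_ms": self.duration_ms,
            "pri_ms": self.pri_ms,
            "pulse_count": self.pulse_count,
            "ptri_s": self.ptri_s,
            "train_count": self.train_count,
            "pnp_kpa": self.pnp_kpa,
            "spacing_mm": self.spacing_mm,
            "foci": [list(f) for f in self.foci],
            "max_tic": self.max_tic,
            "max_grating_ratio": self.max_grating_ratio,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Plan":
        d = dict(d)
        if "foci" in d:
            d["foci"] = tuple(tuple(float(x) for x in f) for f in d["foci"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "Plan":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Plan":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class Timeline:
    """Compiled pulse schedule: parallel arrays of event start/focus/duration."""

    start_times_s: np.ndarray
    focus_indices: np.ndarray
    duration_ms: float
    total_duration_s: float
    n_foci: int = 1

    @property
    def n_events(self) -> int:
        return self.start_times_s.size

    def events(self):
        """Iterate (start_time_s, focus_index, duration_ms)."""
        for t, f in zip(self.start_times_s, self.focus_indices):
            yield float(t), int(f), self.duration_ms

    def focus_time_fractions(self) -> np.ndarray:
        """Fraction of wall time each focus is actively insonified."""
        frac = np.zeros(self.n_foci)
        on = self.duration_ms / 1000.0
        for f in range(self.n_foci):
            frac[f] = np.count_nonzero(self.focus_indices == f) * on
        return frac / self.total_duration_s

    def total_on_time_s(self) -> float:
        return self.n_events * self.duration_ms / 1000.0


def validate_plan(plan: Plan) -> Plan:
    """Check every parameter against its allowed range.

    Returns the plan unchanged if valid; raises :class:`PlanRangeError`
    naming the first violating parameter. Edge values (zero-energy plans,
    continuous wave) produce warnings, not errors.
    """
    for name, (lo, hi) in PARAMETER_RANGES.items():
        value = getattr(plan, name)
        if lo is not None and value < lo:
            raise PlanRangeError(name, value, "min", lo)
        if hi is not None and value > hi:
            raise PlanRangeError(name, value, "max", hi)
    if plan.duration_ms > plan.pri_ms:
        raise PlanRangeError("duration_ms", plan.duration_ms, "max (PRI)", plan.pri_ms)
    if plan.ptri_s > 0 and plan.train_on_time_s > plan.ptri_s:
        raise PlanRangeError(
            "pulse_count", plan.pulse_count, "max (train must fit in PTRI)",
            plan.ptri_s * 1000.0 / plan.pri_ms,
        )
    if plan.duration_ms == 0:
        warnings.warn("plan has zero pulse duration (zero-energy plan)", stacklevel=2)
    if plan.duration_ms == plan.pri_ms:
        warnings.warn("pulse duration equals PRI: continuous wave", stacklevel=2)
    return plan


def build_timeline(plan: Plan, raster: str = "single") -> Timeline:
    """Compile a plan into a pulse timeline.

    ``raster='single'`` fires every pulse at focus 0. ``raster='interleaved'``
    cycles the focus index 0..n_foci-1 across consecutive pulses at the plan
    PRI, so the per-focus repetition interval is n_foci * PRI.
    """
    if raster not in ("single", "interleaved"):
        raise ValueError(f"unknown raster mode {raster!r}")
    if raster == "interleaved" and plan.n_foci < 2:
        warnings.warn("interleaved raster with one focus degenerates to single",
                      stacklevel=2)
        raster = "single"

    pri_s = plan.pri_ms / 1000.0
    pulse_idx = np.arange(plan.pulse_count)
    train_idx = np.arange(plan.train_count)
    train_period = plan.ptri_s if plan.ptri_s > 0 else plan.train_on_time_s
    starts = (train_idx[:, None] * train_period + pulse_idx[None, :] * pri_s).ravel()
    if raster == "interleaved":
        # continuous cyclic raster across train boundaries
        foci = np.arange(starts.size) % plan.n_foci
        n_foci = plan.n_foci
    else:
        foci = np.zeros(starts.size, dtype=int)
        n_foci = 1
    total = plan.train_count * train_period
    return Timeline(
        start_times_s=starts,
        focus_indices=foci,
        duration_ms=plan.duration_ms,
        total_duration_s=float(total),
        n_foci=n_foci,
    )


def duty_cycles(plan: Plan, timeline: Timeline) -> tuple[float, float, float]:
    """Return (pulse_duty, per_focus_duty, train_duty).

    pulse_duty is the within-train fraction duration/PRI; per_focus_duty
    divides that across interleaved foci; train_duty is the fraction of wall
    time with a train active (1.0 for back-to-back trains).
    """
    pulse_duty = plan.duration_ms / plan.pri_ms
    per_focus_duty = pulse_duty / timeline.n_foci
    if plan.ptri_s > 0:
        train_duty = min(plan.train_on_time_s / plan.ptri_s, 1.0)
    else:
        train_duty = 1.0
    return pulse_duty, per_focus_duty, train_duty


def time_average_duty(plan: Plan, timeline: Timeline) -> float:
    """Overall on-fraction of the sequence (pulse duty x train duty)."""
    pulse_duty, _, train_duty = duty_cycles(plan, timeline)
    return pulse_duty * train_duty


def cross_foci(center=NOMINAL_FOCUS_MM, offset_mm: float = 5.0) -> tuple:
    """Five-focus cross pattern: center plus four foci offset laterally and
    in elevation by ``offset_mm`` (center listed first)."""
    cx, cy, cz = center
    return (
        (cx, cy, cz),
        (cx + offset_mm, cy, cz),
        (cx - offset_mm, cy, cz),
        (cx, cy + offset_mm, cz),
        (cx, cy - offset_mm, cz),
    )


def phase_1_1_plan() -> Plan:
    """Single-focus 510 kPa sequence: 30 s pulse trains alternating with 30 s
    off periods (50% train duty) for a 10-minute total."""
    return Plan(pnp_kpa=510.0, ptri_s=60.0, train_count=10)


def phase_1_2_plan() -> Plan:
    """Interleaved five-focus 650 kPa sequence, back-to-back trains."""
    return Plan(pnp_kpa=650.0, ptri_s=30.0, train_count=20, foci=cross_foci())


def phase_1_3_plan() -> Plan:
    """Interleaved five-focus 820 kPa sequence, back-to-back trains."""
    return Plan(pnp_kpa=820.0, ptri_s=30.0, train_count=20, foci=cross_foci())


def with_target(plan: Plan, target) -> Plan:
    """Recenter the plan's focal pattern on ``target`` (transducer frame mm)."""
    shift = np.asarray(target, float) - plan.foci_array[0]
    foci = tuple(tuple(f) for f in (plan.foci_array + shift))
    return replace(plan, foci=foci)
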