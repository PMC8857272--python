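"""Patient-level domain types: baselines, injection schedules, trajectories."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PRETREATMENT_LEVELS",
    "PatientBaseline",
    "InjectionSchedule",
    "VATrajectory",
    "VAObservation",
]

PRETREATMENT_LEVELS = ("naive", "pretreated", "possibly_pretreated")


@dataclass(frozen=True)
class PatientBaseline:
    """One subject's covariates at study baseline (time of diagnosis).

    ``delay`` is the gap in days between baseline/diagnosis and the first
    injection; ``obs_end`` the days from baseline to the last observation.
    """

    patient_id: str
    age: float
    g0: float
    pretreatment: str = "naive"
    delay: float = 0.0
    obs_end: float = 730.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.g0 <= 100.0):
            raise ValueError(f"{self.patient_id}: g0 must be in [0, 100], got {self.g0}")
        if self.age <= 0:
            raise ValueError(f"{self.patient_id}: age must be > 0, got {self.age}")
        if self.obs_end <= 0:
            raise ValueError(f"{self.patient_id}: obs_end must be > 0")
        if self.delay < 0:
            raise ValueError(f"{self.patient_id}: delay must be >= 0")
        if self.pretreatment not in PRETREATMENT_LEVELS:
            raise ValueError(
                f"{self.patient_id}: pretreatment must be one of {PRETREATMENT_LEVELS}, "
                f"got {self.pretreatment!r}"
            )


@dataclass(frozen=True)
class InjectionSchedule:
    """Ordered dosing events ``(time_days, dose_mg)`` for one subject.

    Times are days from baseline, strictly increasing and non-negative;
    doses are positive.  An empty schedule encodes the no-treatment case.
    """

    events: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        events = tuple((float(t), float(d)) for t, d in self.events)
        object.__setattr__(self, "events", events)
        times = self.times
        if len(times) and times[0] < 0:
            raise ValueError("injection times must be >= 0")
        if np.any(np.diff(times) <= 0):
            raise ValueError("injection times must be strictly increasing")
        if any(d <= 0 for _, d in events):
            raise ValueError("doses must be > 0")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.events], dtype=float)

    @property
    def doses(self) -> np.ndarray:
        return np.array([d for _, d in self.events], dtype=float)

    def __len__(self) -> int:
        return len(self.events)

    @classmethod
    def from_arrays(cls, times: Sequence[float], doses) -> "InjectionSchedule":
        times = np.asarray(times, dtype=float)
        doses = np.broadcast_to(np.asarray(doses, dtype=float), times.shape)
        return cls(tuple(zip(times.tolist(), doses.tolist())))

    def shifted(self, shift: float) -> "InjectionSchedule":
        """Schedule with every event time moved by ``shift`` days."""
        return InjectionSchedule.from_arrays(self.times + shift, self.doses)


@dataclass(frozen=True)
class VATrajectory:
    """A simulated continuous VA path sampled at ``times``."""

    patient_id: str
    times: np.ndarray
    va: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        va = np.asarray(self.va, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "va", va)
        if times.shape != va.shape:
            raise ValueError("times and va must have the same length")
        if not np.all(np.isfinite(va)):
            raise ValueError(f"{self.patient_id}: non-finite VA values in trajectory")


@dataclass(frozen=True)
class VAObservation:
    """One noisy VA measurement at a clinic visit."""

    patient_id: str
    time: float
    va: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("observation time must be >= 0")
        if not (0.0 <= self.va <= 100.0):
            raise ValueError(f"VA must be in [0, 100] letters, got {self.va}")
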