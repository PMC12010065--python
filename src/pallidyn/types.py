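"""Core domain containers for pallidal single-unit analysis.

A recorded neuron is represented as a :class:`SpikeTrain` (sorted spike times in
seconds plus identity labels), a patient as a :class:`ClinicalRecord` (BFMDRS-M
motor scores before and after pallidal DBS), and each dystonia gene's published
neural signature as a :class:`GeneProfile` (per-metric mean/SD plus target
fractions of discharge regimes, used to calibrate synthetic cohorts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpikeTrain",
    "ClinicalRecord",
    "GeneProfile",
    "SimConfig",
    "GENES",
]

#: The nine dystonia genes of the cohort, in alphabetical order.
GENES = (
    "AOPEP",
    "GNAL",
    "KMT2B",
    "PANK2",
    "PLA2G6",
    "SGCE",
    "THAP1",
    "TOR1A",
    "VPS16",
)


@dataclass
class SpikeTrain:
    """One neuron's spike times on the half-open recording window [0, duration).

    Invariants are enforced at construction: strictly increasing times within
    the recording window and a positive duration. ISI-based features require at
    least 2 spikes; callers gate on :attr:`n_spikes`.
    """

    unit_id: str
    patient_id: str
    gene: str
    times: np.ndarray
    duration: float
    #: optional ground-truth annotations from the simulator (planted burst or
    #: pause windows as (onset, offset) pairs); empty for real recordings
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if not (self.duration > 0) or not math.isfinite(self.duration):
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.times.ndim != 1:
            raise ValueError("times must be a 1-D array")
        if self.times.size:
            if np.any(np.diff(self.times) <= 0):
                raise ValueError(f"spike times of unit {self.unit_id!r} must be strictly increasing")
            if self.times[0] < 0 or self.times[-1] >= self.duration + 1e-12:
                raise ValueError(
                    f"spike times of unit {self.unit_id!r} must lie in [0, duration)"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def rate(self) -> float:
        """Mean firing rate in spikes/s."""
        return self.n_spikes / self.duration

    def isi(self) -> np.ndarray:
        """Interspike intervals in seconds (length n_spikes - 1)."""
        return np.diff(self.times)

    def shifted(self, offset: float) -> "SpikeTrain":
        """Same train with a constant time offset (detection must be invariant)."""
        return SpikeTrain(
            self.unit_id,
            self.patient_id,
            self.gene,
            self.times + offset,
            self.duration + offset,
            dict(self.annotations),
        )


@dataclass
class ClinicalRecord:
    """One patient's demographics and BFMDRS-M motor scores (0-128 scale).

    Missing follow-ups are ``None``. ``bfmdrs_pre`` is the preoperative score;
    ``bfmdrs_fu1``/``fu3``/``fu5`` the 1-, 3- and 5-year post-DBS scores.
    """

    patient_id: str
    gene: str
    sex: str
    onset_age: float
    surgery_age: float
    bfmdrs_pre: float
    bfmdrs_fu1: float | None = None
    bfmdrs_fu3: float | None = None
    bfmdrs_fu5: float | None = None

    def __post_init__(self) -> None:
        if self.onset_age > self.surgery_age:
            raise ValueError(f"{self.patient_id}: onset_age exceeds surgery_age")
        for name in ("bfmdrs_pre", "bfmdrs_fu1", "bfmdrs_fu3", "bfmdrs_fu5"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 128):
                raise ValueError(f"{self.patient_id}: {name}={v} outside [0, 128]")

    @property
    def disease_duration(self) -> float:
        return self.surgery_age - self.onset_age

    def followup(self, horizon_years: int) -> float | None:
        """Score at the 1-, 3- or 5-year follow-up horizon, or None if missing."""
        return {1: self.bfmdrs_fu1, 3: self.bfmdrs_fu3, 5: self.bfmdrs_fu5}[horizon_years]


@dataclass
class GeneProfile:
    """Published per-gene neural signature: metric mean/SD plus regime fractions.

    ``metrics`` maps metric name -> (mean, sd) in the units of the cohort
    summary table (rates in spikes/s, ISI moments in ms, durations in s,
    proportions in percent, band peaks in Hz). The four fractions give the
    target share of tonic / irregular / bursting discharge (mutually exclusive,
    summing to 1) and of any-band oscillatory neurons (independent flag).
    """

    gene: str
    metrics: dict[str, tuple[float, float]]
    frac_tonic: float = 0.0
    frac_irregular: float = 0.0
    frac_bursting: float = 0.0
    frac_oscillatory: float = 0.0

    def __post_init__(self) -> None:
        for name, (mu, sd) in self.metrics.items():
            if sd < 0:
                raise ValueError(f"{self.gene}: SD of {name} is negative")
        for name in ("frac_tonic", "frac_irregular", "frac_bursting", "frac_oscillatory"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{self.gene}: {name}={v} outside [0, 1]")
        s = self.frac_tonic + self.frac_irregular + self.frac_bursting
        if s > 1 + 1e-9:
            raise ValueError(f"{self.gene}: mutually exclusive discharge fractions sum to {s} > 1")

    def mean(self, metric: str) -> float:
        return self.metrics[metric][0]

    def sd(self, metric: str) -> float:
        return self.metrics[metric][1]


@dataclass
class SimConfig:
    """Parameters of the synthetic spike-train generator.

    Rates are in events/s, durations in seconds; ``shape`` is the gamma-renewal
    shape (1 = Poisson, larger = more regular); ``osc_depth`` is the relative
    depth of sinusoidal rate modulation in [0, 1].
    """

    base_rate: float = 20.0
    shape: float = 1.0
    duration: float = 20.0
    burst_rate: float = 0.0
    intra_burst_rate: float = 200.0
    burst_len: float = 10.0
    pause_rate: float = 0.0
    pause_dur_mean: float = 0.5
    osc_freq: float = 0.0
    osc_depth: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_rate", "burst_rate", "intra_burst_rate", "pause_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.shape <= 0:
            raise ValueError("shape must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if not (0 <= self.osc_depth <= 1):
            raise ValueError("osc_depth must be in [0, 1]")
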