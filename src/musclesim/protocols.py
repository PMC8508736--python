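"""Exercise protocols, fiber-type recruitment and fatigue.

A protocol is a piecewise total work-rate function W(t) in watts over time
in minutes.  Recruitment splits the total power between slow-twitch (type I)
and fast-twitch (type II) fibers: type I fibers are recruited from exercise
onset, type II only above a threshold fraction of the power at VO2max, and
both reach their caps simultaneously at W_max — at which point the subject
is exhausted and the test terminates.  Fatigue is represented prescriptively
as a decline of the power generated by type II fibers while under load.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ExerciseProtocol",
    "RecruitmentModel",
    "FatigueModel",
    "FiberLoad",
    "ExhaustionError",
    "ramp_protocol",
    "interval_protocol",
    "continuous_protocol",
    "protocol_from_table",
    "recruit",
    "apply_fatigue",
    "exhaustion_time",
    "type2_onset_time",
]


class ExhaustionError(RuntimeError):
    """Demanded power exceeds full recruitment capacity."""


@dataclass
class ExerciseProtocol:
    """Total work rate over time; zero outside [t_start, t_end]."""

    work_rate: Callable[[float], float]
    t_start: float
    t_end: float
    events: tuple[float, ...] = ()
    label: str = ""

    def __call__(self, t: float) -> float:
        if t < self.t_start or t > self.t_end:
            return 0.0
        return max(0.0, float(self.work_rate(t)))

    def event_times(self) -> tuple[float, ...]:
        pts = {self.t_start, self.t_end, *self.events}
        return tuple(sorted(pts))


@dataclass(frozen=True)
class RecruitmentModel:
    """Power split between fiber types.

    ``W_max``: power at full recruitment (the VO2max-equivalent workload).
    ``theta``: fraction of W_max below which only type I fibers work.
    ``cap_I``/``cap_II``: per-type peak powers; they must sum to W_max so
    that both types saturate together at exhaustion.
    """

    W_max: float = 250.0
    theta: float = 0.24
    cap_I: float = 125.0
    cap_II: float = 125.0

    def __post_init__(self) -> None:
        if not math.isclose(self.cap_I + self.cap_II, self.W_max):
            raise ValueError("fiber caps must sum to W_max")
        if not 0.0 < self.theta < self.cap_I / self.W_max:
            raise ValueError("type II onset must lie below the type I cap")

    @property
    def W_onset(self) -> float:
        """Power at which type II recruitment begins."""
        return self.theta * self.W_max

    def split(self, W: float, supramaximal: bool = False) -> tuple[float, float]:
        if W < 0:
            raise ValueError("work rate must be nonnegative")
        if W > self.W_max * (1 + 1e-9):
            if not supramaximal:
                raise ExhaustionError(
                    f"W = {W:g} W exceeds full recruitment capacity "
                    f"{self.W_max:g} W"
                )
            # brief supra-maximal bouts: type I saturates at its cap and
            # type II generates the remainder
            return self.cap_I, W - self.cap_I
        W = min(W, self.W_max)
        if W <= self.W_onset:
            return W, 0.0
        frac = (W - self.W_onset) / (self.W_max - self.W_onset)
        W_I = self.W_onset + (self.cap_I - self.W_onset) * frac
        W_II = self.cap_II * frac
        return W_I, W_II


def recruit(W: float, model: RecruitmentModel) -> tuple[float, float]:
    """Split total power into (type I, type II) contributions."""
    return model.split(W)


@dataclass(frozen=True)
class FatigueModel:
    """Prescribed decline of type-II power while under load.

    ``decline`` is the fractional loss of type-II power per minute of
    accumulated work (time spent in work bouts); it accrues across bouts, so
    successive bouts start from progressively lower type-II power.
    """

    enabled: bool = False
    decline: float = 0.0

    def __post_init__(self) -> None:
        if self.decline < 0:
            raise ValueError("decline rate must be >= 0")


# --------------------------------------------------------------------------
# protocol constructors


def ramp_protocol(slope: float = 10.0, t_start: float = 0.0,
                  recruitment: RecruitmentModel | None = None) -> ExerciseProtocol:
    """Incremental ramp to exhaustion: W rises linearly at ``slope`` W/min
    until full recruitment terminates the test."""
    if slope <= 0:
        raise ValueError("ramp slope must be positive")
    rec = recruitment or RecruitmentModel()
    t_end = t_start + rec.W_max / slope
    return ExerciseProtocol(
        work_rate=lambda t: slope * (t - t_start),
        t_start=t_start,
        t_end=t_end,
        events=(),
        label=f"ramp {slope:g} W/min",
    )


def interval_protocol(work_s: float, rest_s: float, n_bouts: int,
                      W_peak: float, t_start: float = 0.0) -> ExerciseProtocol:
    """Square-wave intervals: ``n_bouts`` bouts of ``work_s`` seconds at
    ``W_peak`` watts separated by ``rest_s`` seconds of rest."""
    if work_s <= 0 or rest_s <= 0:
        raise ValueError("bout durations must be positive")
    if n_bouts < 1:
        raise ValueError("need at least one bout")
    work = work_s / 60.0
    rest = rest_s / 60.0
    period = work + rest
    t_end = t_start + n_bouts * work + (n_bouts - 1) * rest

    def w(t: float) -> float:
        u = t - t_start
        phase = u % period
        return W_peak if phase < work else 0.0

    edges: list[float] = []
    for k in range(n_bouts):
        edges.append(t_start + k * period)
        edges.append(t_start + k * period + work)
    return ExerciseProtocol(
        work_rate=w, t_start=t_start, t_end=t_end,
        events=tuple(e for e in edges if t_start < e < t_end),
        label=f"interval {work_s:g}:{rest_s:g} s x{n_bouts} @ {W_peak:g} W",
    )


def continuous_protocol(fraction_vo2max: float, duration_min: float,
                        t_start: float = 0.0,
                        recruitment: RecruitmentModel | None = None) -> ExerciseProtocol:
    """Constant-power exercise at a fraction of the VO2max workload."""
    if not 0.0 < fraction_vo2max <= 1.0:
        raise ValueError("fraction of VO2max must be in (0, 1]")
    rec = recruitment or RecruitmentModel()
    W = fraction_vo2max * rec.W_max
    return ExerciseProtocol(
        work_rate=lambda t: W,
        t_start=t_start,
        t_end=t_start + duration_min,
        label=f"continuous {100 * fraction_vo2max:g}% VO2max, {duration_min:g} min",
    )


def protocol_from_table(table, label: str = "tabular") -> ExerciseProtocol:
    """Wrap a :class:`~musclesim.tables.ProtocolTable` interpolant."""
    return ExerciseProtocol(
        work_rate=table,
        t_start=table.domain[0],
        t_end=table.domain[1],
        events=tuple(t for t in getattr(table, "times", ())
                     if table.domain[0] < t < table.domain[1]),
        label=label,
    )


def exhaustion_time(protocol: ExerciseProtocol,
                    recruitment: RecruitmentModel,
                    dt: float = 1e-3) -> float | None:
    """First time at which demanded power reaches full recruitment capacity.

    Scans the protocol on a fine grid and refines by bisection; returns
    ``None`` if the protocol never reaches W_max.
    """
    ts = np.arange(protocol.t_start, protocol.t_end + dt, dt)
    W = np.array([protocol(t) for t in ts])
    hit = np.nonzero(W >= recruitment.W_max * (1 - 1e-12))[0]
    if len(hit) == 0:
        return None
    return float(ts[hit[0]])


# --------------------------------------------------------------------------
# per-fiber load


@dataclass
class FiberLoad:
    """Per-fiber work rates derived from a protocol, the recruitment model
    and (optionally) fatigue.

    Provides callables ``W_I(t)``, ``W_II(t)``, ``W_total(t)`` and per-fiber
    relative intensities (fraction of the fiber cap) used by the calcium
    drive.  With fatigue enabled, type-II power is scaled by
    ``max(0, 1 - decline * accumulated_work_minutes(t))``; type I power is
    unaffected, so total power declines accordingly.
    """

    protocol: ExerciseProtocol
    recruitment: RecruitmentModel = field(default_factory=RecruitmentModel)
    fatigue: FatigueModel = field(default_factory=FatigueModel)
    supramaximal: bool = False

    def _accumulated_work_time(self, t: float) -> float:
        # time spent with W > 0 up to t, piecewise-exact between protocol events
        if t <= self.protocol.t_start:
            return 0.0
        acc = 0.0
        pts = [p for p in self.protocol.event_times() if p < t] + [min(t, self.protocol.t_end)]
        prev = pts[0]
        for p in pts[1:]:
            mid = 0.5 * (prev + p)
            if self.protocol(mid) > 0:
                acc += p - prev
            prev = p
        return acc

    def _fatigue_factor(self, t: float) -> float:
        if not self.fatigue.enabled or self.fatigue.decline == 0.0:
            return 1.0
        return max(0.0, 1.0 - self.fatigue.decline * self._accumulated_work_time(t))

    def W_I(self, t: float) -> float:
        return self.recruitment.split(self.protocol(t), self.supramaximal)[0]

    def W_II(self, t: float) -> float:
        return (self.recruitment.split(self.protocol(t), self.supramaximal)[1]
                * self._fatigue_factor(t))

    def W_total(self, t: float) -> float:
        return self.W_I(t) + self.W_II(t)

    def intensity_I(self, t: float) -> float:
        return self.W_I(t) / self.recruitment.cap_I

    def intensity_II(self, t: float) -> float:
        return self.W_II(t) / self.recruitment.cap_II


def apply_fatigue(protocol: ExerciseProtocol, fatigue: FatigueModel,
                  recruitment: RecruitmentModel | None = None,
                  supramaximal: bool = False) -> FiberLoad:
    """Per-fiber power series with the type-II fatigue decline applied."""
    return FiberLoad(protocol, recruitment or RecruitmentModel(), fatigue,
                     supramaximal)


def type2_onset_time(protocol: ExerciseProtocol,
                     recruitment: RecruitmentModel,
                     tol: float = 1e-9) -> float | None:
    """First time at which type II fibers are recruited (W crosses the
    onset threshold), found by bisection; None if never recruited."""
    W_on = recruitment.W_onset
    ts = np.linspace(protocol.t_start, protocol.t_end, 4001)
    above = [protocol(t) > W_on for t in ts]
    try:
        k = above.index(True)
    except ValueError:
        return None
    if k == 0:
        return float(ts[0])
    lo, hi = ts[k - 1], ts[k]
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if protocol(mid) > W_on:
            hi = mid
        else:
            lo = mid
    return float(hi)
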