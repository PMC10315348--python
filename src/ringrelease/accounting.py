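"""Mass-balance bookkeeping: from measured concentrations to released drug.

Two sampling regimes are covered, matching common ring IVRT practice:

* **monophasic, full replacement** — the vessel medium is sampled and the
  whole volume discarded and replaced daily (weekends bridged by a larger
  Friday refill), so the drug released over interval *i* is simply
  ``C_i * V_i``;
* **biphasic, partial replacement** — a small aliquot ``v_s`` is withdrawn
  from each phase daily and replaced with drug-free medium, so the
  cumulative amount attributable to a phase at event *n* must add back the
  drug removed in earlier aliquots:  ``A_n = V * C_n + sum_{i<n} v_s * C_i``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    ScheduleMismatchError,
    ValidationError,
)

__all__ = [
    "SamplingEvent",
    "SamplingProtocol",
    "ConcentrationSeries",
    "ReleaseProfile",
    "CalibrationCurve",
    "monophasic_protocol",
    "biphasic_protocol",
    "reconstruct_monophasic",
    "reconstruct_biphasic",
    "apply_calibration",
    "pool_replicates",
]

Replacement = Literal["full", "partial"]


@dataclass(frozen=True)
class SamplingEvent:
    """One sampling/replacement event in a release experiment."""

    time: float  # days since immersion
    phase: str  # "single", "buffer" or "octanol"
    sample_volume: float  # mL withdrawn for assay
    replacement: Replacement
    vessel_volume: float  # mL in the vessel over the interval ending here
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.sample_volume < 0 or self.sample_volume > self.vessel_volume:
            raise InvalidParameterError(
                f"sample volume {self.sample_volume} mL must be within "
                f"[0, vessel volume {self.vessel_volume} mL]"
            )
        if self.dilution_factor < 1.0:
            raise InvalidParameterError("dilution factor must be >= 1")


@dataclass(frozen=True)
class SamplingProtocol:
    """Ordered sampling schedule defining each vessel's volume history."""

    events: tuple[SamplingEvent, ...]

    def __post_init__(self) -> None:
        for phase in self.phases():
            t = [e.time for e in self.for_phase(phase)]
            if any(b <= a for a, b in zip(t, t[1:])):
                raise ValidationError(
                    f"event times for phase {phase!r} must be strictly increasing"
                )

    def phases(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for e in self.events:
            seen.setdefault(e.phase, None)
        return tuple(seen)

    def for_phase(self, phase: str) -> tuple[SamplingEvent, ...]:
        return tuple(e for e in self.events if e.phase == phase)

    def times(self, phase: str) -> np.ndarray:
        return np.array([e.time for e in self.for_phase(phase)], dtype=float)


def monophasic_protocol(
    days: int = 28,
    *,
    volume: float = 100.0,
    weekend_volume: float = 200.0,
    initial_volume: float = 200.0,
    weekend_days: Sequence[int] = (6, 0),
    skip_weekends: bool = True,
    phase: str = "single",
) -> SamplingProtocol:
    """Daily full-replacement schedule with weekend bridging.

    Day 1 is the first sampling, 24 h after immersion in ``initial_volume``
    mL; thereafter the medium is discarded and replaced with ``volume`` mL
    except on the day before a weekend, when ``weekend_volume`` mL carries
    the vessel over the unsampled days.  ``weekend_days`` are day numbers
    mod 7 that are skipped (default: day 1 = Monday, days 6 and 7 are the
    weekend).
    """
    weekend = {d % 7 for d in weekend_days}
    sampling_days = [d for d in range(1, days + 1) if (d % 7) not in weekend]
    if not sampling_days:
        raise InvalidParameterError("schedule contains no sampling days")
    events = []
    prev = 0
    for d in sampling_days:
        gap = d - prev
        if d == sampling_days[0]:
            v = initial_volume
        elif gap > 1:
            v = weekend_volume
        else:
            v = volume
        # the whole vessel is assayed via the aliquot, then discarded
        events.append(
            SamplingEvent(float(d), phase, 0.0, "full", v)
        )
        prev = d
    if not skip_weekends:
        events = [
            SamplingEvent(float(d), phase, 0.0, "full",
                          initial_volume if d == 1 else volume)
            for d in range(1, days + 1)
        ]
    return SamplingProtocol(tuple(events))


def daily_protocol(days: int = 28, *, volume: float = 100.0,
                   phase: str = "single") -> SamplingProtocol:
    """Simple daily full-replacement schedule with constant volume."""
    return monophasic_protocol(
        days, volume=volume, initial_volume=volume, skip_weekends=False,
        phase=phase,
    )


def biphasic_protocol(
    days: int = 28,
    *,
    buffer_volume: float = 100.0,
    octanol_volume: float = 20.0,
    sample_volume: float = 1.0,
    octanol_dilution: float = 20.0,
) -> SamplingProtocol:
    """Daily partial-sampling schedule for a buffer + octanol vessel.

    Both phases are sampled (``sample_volume`` mL) and topped up with
    drug-free medium every day; octanol aliquots are diluted for assay.
    """
    events = []
    for d in range(1, days + 1):
        events.append(
            SamplingEvent(float(d), "buffer", sample_volume, "partial", buffer_volume)
        )
        events.append(
            SamplingEvent(float(d), "octanol", sample_volume, "partial",
                          octanol_volume, dilution_factor=octanol_dilution)
        )
    return SamplingProtocol(tuple(events))


@dataclass
class ConcentrationSeries:
    """Measured concentrations for one replicate ring in one phase.

    Concentrations are µg/mL *in the vessel* (i.e. already corrected for
    any assay dilution).  Rows are sorted by time on construction.
    """

    replicate_id: str
    phase: str
    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape or self.times.ndim != 1:
            raise ValidationError("times and concentrations must be equal-length 1-D")
        order = np.argsort(self.times, kind="stable")
        self.times = self.times[order]
        self.concentrations = self.concentrations[order]
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("duplicate time points in concentration series")
        if np.any(self.concentrations < 0):
            raise ValidationError("negative concentration in series")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class ReleaseProfile:
    """Reconstructed per-interval and cumulative release for one replicate."""

    replicate_id: str
    times: np.ndarray
    interval_amounts: np.ndarray  # µg released per sampling interval
    cumulative: np.ndarray  # µg
    interval_lengths: np.ndarray  # days
    fractional: Optional[np.ndarray] = None  # cumulative / ring loading
    cumulative_sd: Optional[np.ndarray] = None  # set by pool_replicates
    interval_sd: Optional[np.ndarray] = None
    n_pooled: int = 1
    qc_nonmonotonic_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.interval_amounts = np.asarray(self.interval_amounts, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        self.interval_lengths = np.asarray(self.interval_lengths, dtype=float)
        if self.fractional is not None:
            self.fractional = np.asarray(self.fractional, dtype=float)

    @property
    def daily_rates(self) -> np.ndarray:
        """Per-day release rate over each interval, µg/day."""
        return self.interval_amounts / self.interval_lengths

    def with_loading(self, ring_loading: float) -> "ReleaseProfile":
        """Return a copy with fractional release computed from a loading."""
        if ring_loading <= 0:
            raise InvalidParameterError("ring loading must be positive")
        return replace(self, fractional=self.cumulative / ring_loading)


def _interval_lengths(times: np.ndarray) -> np.ndarray:
    return np.diff(np.concatenate([[0.0], times]))


def reconstruct_monophasic(
    series: ConcentrationSeries,
    protocol: SamplingProtocol,
    ring_loading: Optional[float] = None,
) -> ReleaseProfile:
    """Release profile under full medium replacement.

    Each event's interval amount is ``C_i * V_i`` (everything in the vessel
    was released since the previous replacement); cumulative release is the
    running sum and is non-decreasing by construction.
    """
    events = protocol.for_phase(series.phase)
    if not events:
        raise ScheduleMismatchError(f"protocol has no events for phase {series.phase!r}")
    by_time = {e.time: e for e in events}
    missing = [t for t in series.times if t not in by_time]
    if missing:
        raise ScheduleMismatchError(
            f"series times {missing} have no matching protocol event"
        )
    for e in by_time.values():
        if e.replacement != "full":
            raise ScheduleMismatchError(
                "monophasic reconstruction requires full-replacement events"
            )
    volumes = np.array([by_time[t].vessel_volume for t in series.times])
    interval = series.concentrations * volumes
    cumulative = np.cumsum(interval)
    profile = ReleaseProfile(
        replicate_id=series.replicate_id,
        times=series.times.copy(),
        interval_amounts=interval,
        cumulative=cumulative,
        interval_lengths=_interval_lengths(series.times),
    )
    return profile.with_loading(ring_loading) if ring_loading else profile


def reconstruct_biphasic(
    series: ConcentrationSeries,
    protocol: SamplingProtocol,
    ring_loading: Optional[float] = None,
) -> ReleaseProfile:
    """Cumulative amount in one phase under partial daily sampling.

    A_n = V * C_n + sum_{i<n} v_s * C_i: the drug currently in the phase
    plus everything previously carried away in assay aliquots.  Measured
    noise can make A decrease between days; decreases are flagged rather
    than forced monotone.
    """
    events = protocol.for_phase(series.phase)
    if not events:
        raise ScheduleMismatchError(f"protocol has no events for phase {series.phase!r}")
    by_time = {e.time: e for e in events}
    missing = [t for t in series.times if t not in by_time]
    if missing:
        raise ScheduleMismatchError(
            f"series times {missing} have no matching protocol event"
        )
    evs = [by_time[t] for t in series.times]
    for e in evs:
        if e.replacement != "partial":
            raise ScheduleMismatchError(
                "biphasic reconstruction requires partial-replacement events"
            )
    volumes = {e.vessel_volume for e in evs}
    if len(volumes) > 1:
        raise ValidationError("vessel volume must be constant per phase")

    c = series.concentrations
    v_s = np.array([e.sample_volume for e in evs])
    V = evs[0].vessel_volume
    removed_before = np.concatenate([[0.0], np.cumsum(v_s * c)[:-1]])
    cumulative = V * c + removed_before
    interval = np.diff(np.concatenate([[0.0], cumulative]))
    dips = tuple(series.times[1:][np.diff(cumulative) < 0])
    profile = ReleaseProfile(
        replicate_id=series.replicate_id,
        times=series.times.copy(),
        interval_amounts=interval,
        cumulative=cumulative,
        interval_lengths=_interval_lengths(series.times),
        qc_nonmonotonic_times=dips,
    )
    return profile.with_loading(ring_loading) if ring_loading else profile


@dataclass(frozen=True)
class CalibrationCurve:
    """Weighted linear instrument calibration: response = slope*conc + intercept.

    Fitted by weighted least squares with 1/x^2 weights by default
    (concentration-proportional assay variance, the usual HPLC convention).
    """

    nominal: tuple[float, ...]
    response: tuple[float, ...]
    slope: float
    intercept: float
    weighting: str = "1/x2"

    def __post_init__(self) -> None:
        if len(self.nominal) < 3:
            raise InsufficientDataError("calibration needs >= 3 points")
        if self.slope <= 0:
            raise InvalidParameterError("calibration slope must be positive")

    @classmethod
    def fit(
        cls,
        nominal: Iterable[float],
        response: Iterable[float],
        weighting: str = "1/x2",
    ) -> "CalibrationCurve":
        x = np.asarray(list(nominal), dtype=float)
        y = np.asarray(list(response), dtype=float)
        if x.size < 3:
            raise InsufficientDataError("calibration needs >= 3 points")
        if np.any(x <= 0):
            raise InvalidParameterError("nominal calibration levels must be positive")
        if weighting == "1/x2":
            w = 1.0 / x**2
        elif weighting == "1/x":
            w = 1.0 / x
        elif weighting in ("none", "1"):
            w = np.ones_like(x)
        else:
            raise InvalidParameterError(f"unknown weighting {weighting!r}")
        res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
        return cls(
            nominal=tuple(x),
            response=tuple(y),
            slope=float(res.params[1]),
            intercept=float(res.params[0]),
            weighting=weighting,
        )

    @property
    def response_range(self) -> tuple[float, float]:
        return (min(self.response), max(self.response))


def apply_calibration(
    raw_responses,
    curve: CalibrationCurve,
    dilution_factor: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Back-calculate vessel concentrations from instrument responses.

    concentration = dilution_factor * (response - intercept) / slope,
    floored at zero.  Returns ``(concentrations, below_range)`` where the
    boolean mask flags responses under the calibrated range (reported, not
    raised).
    """
    if dilution_factor < 1.0:
        raise InvalidParameterError("dilution factor must be >= 1")
    r = np.asarray(raw_responses, dtype=float)
    if np.any(r < 0):
        raise ValidationError("instrument responses must be non-negative")
    conc = dilution_factor * (r - curve.intercept) / curve.slope
    below = (r < curve.response_range[0]) | (conc < 0)
    return np.maximum(conc, 0.0), below


def pool_replicates(profiles: Sequence[ReleaseProfile]) -> ReleaseProfile:
    """Mean profile across replicate rings with per-time sample SD (n-1).

    All profiles must share the same time grid.  With a single replicate the
    SD is reported as missing (NaN).
    """
    if not profiles:
        raise InsufficientDataError("no profiles to pool")
    t0 = profiles[0].times
    for p in profiles[1:]:
        if p.times.shape != t0.shape or not np.allclose(p.times, t0):
            raise ValidationError("replicate profiles are on different time grids")
    cum = np.vstack([p.cumulative for p in profiles])
    inter = np.vstack([p.interval_amounts for p in profiles])
    n = len(profiles)
    sd = (np.full(t0.shape, np.nan), np.full(t0.shape, np.nan)) if n == 1 else (
        cum.std(axis=0, ddof=1), inter.std(axis=0, ddof=1))
    frac = None
    if all(p.fractional is not None for p in profiles):
        frac = np.vstack([p.fractional for p in profiles]).mean(axis=0)
    return ReleaseProfile(
        replicate_id=f"pooled(n={n})",
        times=t0.copy(),
        interval_amounts=inter.mean(axis=0),
        cumulative=cum.mean(axis=0),
        interval_lengths=profiles[0].interval_lengths.copy(),
        fractional=frac,
        cumulative_sd=sd[0],
        interval_sd=sd[1],
        n_pooled=n,
    )
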