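"""Release-kinetics models and ordinary-least-squares fitting.

Three classical dissolution models, each linearised and fitted by OLS with
parametric 95% confidence intervals (Student t, n-2 df):

* zero-order:     Q(t) = a*t + b          (partition/solubility-controlled)
* Higuchi:        Q(t) = a*sqrt(t) + b    (matrix diffusion-controlled)
* Korsmeyer-Peppas: Mt/Minf = k*t**n, fitted as
                  log10(fraction) = n*log10(t) + log10(k)

The Peppas exponent n diagnoses mechanism: n ~ 0.5 Fickian diffusion,
0.5 < n < 1 anomalous transport.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

from .accounting import ReleaseProfile, pool_replicates
from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    SingularFitError,
)

__all__ = [
    "ModelFit",
    "eval_zero_order",
    "eval_higuchi",
    "eval_peppas",
    "fit_linear",
    "fit_zero_order",
    "fit_higuchi",
    "fit_peppas",
    "select_time_basis",
    "BasisSelection",
    "correct_interval_with_model",
    "exclude_replicates",
    "ExclusionResult",
]

ModelName = Literal["zero_order", "higuchi", "peppas"]


@dataclass(frozen=True)
class ModelFit:
    """Fitted kinetic-model parameters with 95% confidence intervals.

    For zero-order and Higuchi fits ``slope``/``intercept`` are in µg/day
    (or µg/day^1/2) and µg.  For Peppas fits ``slope`` is the release
    exponent n and ``intercept`` is log10 k.
    """

    model: ModelName
    slope: float
    intercept: float
    ci95_slope: tuple[float, float]
    ci95_intercept: tuple[float, float]
    r_squared: float
    n_points: int
    fit_window: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.ci95_slope
        if not lo <= self.slope <= hi:
            raise InvalidParameterError("slope CI does not bracket the estimate")
        lo, hi = self.ci95_intercept
        if not lo <= self.intercept <= hi:
            raise InvalidParameterError("intercept CI does not bracket the estimate")

    # Peppas aliases
    @property
    def n_exponent(self) -> float:
        return self.slope

    @property
    def log10_k(self) -> float:
        return self.intercept

    @property
    def k(self) -> float:
        return 10.0**self.intercept

    def predict(self, t) -> np.ndarray:
        """Evaluate the fitted model at times t (days)."""
        if self.model == "zero_order":
            return eval_zero_order(t, self.slope, self.intercept)
        if self.model == "higuchi":
            return eval_higuchi(t, self.slope, self.intercept)
        return eval_peppas(t, self.k, self.slope)


def eval_zero_order(t, a: float, b: float):
    """Cumulative release a*t + b (µg) under zero-order kinetics."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("time must be non-negative")
    return a * t + b


def eval_higuchi(t, a: float, b: float):
    """Cumulative release a*sqrt(t) + b (µg) under Higuchi kinetics."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("time must be non-negative")
    return a * np.sqrt(t) + b


def eval_peppas(t, k: float, n: float, clip: bool = False):
    """Fractional release k * t**n under the Korsmeyer-Peppas power law.

    Defined for t > 0 only (the log-log form is singular at 0).  With
    ``clip=True`` the fraction is capped at 1 for reporting.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise InvalidParameterError("Peppas model requires t > 0")
    if k <= 0 or n <= 0:
        raise InvalidParameterError("Peppas k and n must be positive")
    f = k * np.power(t, n)
    return np.minimum(f, 1.0) if clip else f


def fit_linear(
    x,
    y,
    model: ModelName = "zero_order",
    fit_window: Optional[tuple[float, float]] = None,
) -> ModelFit:
    """Ordinary least squares y = slope*x + intercept with t-based 95% CIs.

    R^2 = 1 - SS_res/SS_tot.  Exactly collinear input yields zero-width
    intervals and R^2 = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InsufficientDataError("x and y must have equal length")
    if x.size < 3:
        raise InsufficientDataError(f"linear fit needs >= 3 points, got {x.size}")
    if np.ptp(x) == 0.0:
        raise SingularFitError("all abscissa values equal; fit is singular")
    if np.ptp(y) == 0.0:
        # constant ordinate: zero slope fits perfectly on any basis
        return ModelFit(
            model=model,
            slope=0.0,
            intercept=float(y[0]),
            ci95_slope=(0.0, 0.0),
            ci95_intercept=(float(y[0]), float(y[0])),
            r_squared=1.0,
            n_points=int(x.size),
            fit_window=fit_window or (float(x.min()), float(x.max())),
        )
    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.975, x.size - 2)
    # rvalue can exceed 1 by rounding error on exact data
    r2 = min(float(res.rvalue) ** 2, 1.0)
    return ModelFit(
        model=model,
        slope=float(res.slope),
        intercept=float(res.intercept),
        ci95_slope=(
            float(res.slope - tcrit * res.stderr),
            float(res.slope + tcrit * res.stderr),
        ),
        ci95_intercept=(
            float(res.intercept - tcrit * res.intercept_stderr),
            float(res.intercept + tcrit * res.intercept_stderr),
        ),
        r_squared=r2,
        n_points=int(x.size),
        fit_window=fit_window or (float(x.min()), float(x.max())),
    )


def _window_mask(times: np.ndarray, window: Optional[tuple[float, float]]):
    if window is None:
        return np.ones(times.shape, dtype=bool), (float(times.min()), float(times.max()))
    lo, hi = window
    mask = (times >= lo) & (times <= hi)
    if mask.sum() < 3:
        raise InsufficientDataError("fit window contains fewer than 3 points")
    return mask, (float(lo), float(hi))


def fit_zero_order(
    profile: ReleaseProfile, window: Optional[tuple[float, float]] = None
) -> ModelFit:
    """OLS of cumulative release against time (partition-controlled basis)."""
    mask, win = _window_mask(profile.times, window)
    return fit_linear(profile.times[mask], profile.cumulative[mask],
                      model="zero_order", fit_window=win)


def fit_higuchi(
    profile: ReleaseProfile, window: Optional[tuple[float, float]] = None
) -> ModelFit:
    """OLS of cumulative release against root time (matrix-diffusion basis)."""
    mask, win = _window_mask(profile.times, window)
    return fit_linear(np.sqrt(profile.times[mask]), profile.cumulative[mask],
                      model="higuchi", fit_window=win)


def fit_peppas(
    profile: ReleaseProfile,
    ring_loading: Optional[float] = None,
    window: Optional[tuple[float, float]] = None,
    max_fraction: Optional[float] = None,
) -> ModelFit:
    """Power-law fit on log10 fraction vs log10 time.

    The slope is the release exponent n and the intercept log10 k.  Points
    with non-positive fractional release (or t <= 0) are excluded with a
    warning; ``max_fraction`` optionally restricts to the textbook early
    portion of the curve (e.g. 0.6).
    """
    if profile.fractional is not None:
        frac = profile.fractional
    elif ring_loading is not None:
        frac = profile.cumulative / float(ring_loading)
    else:
        raise InvalidParameterError(
            "fit_peppas needs fractional release: supply ring_loading or a "
            "profile with fractional set"
        )
    mask, win = _window_mask(profile.times, window)
    usable = mask & (frac > 0) & (profile.times > 0)
    if max_fraction is not None:
        usable &= frac <= max_fraction
    dropped = int(mask.sum() - usable.sum())
    if dropped:
        warnings.warn(
            f"fit_peppas: excluded {dropped} point(s) outside (0, "
            f"{max_fraction if max_fraction is not None else 1}] fractional range",
            stacklevel=2,
        )
    if usable.sum() < 3:
        raise InsufficientDataError("fewer than 3 usable points for Peppas fit")
    return fit_linear(
        np.log10(profile.times[usable]), np.log10(frac[usable]),
        model="peppas", fit_window=win,
    )


@dataclass(frozen=True)
class BasisSelection:
    """Outcome of time-basis model discrimination."""

    basis: Literal["zero_order", "higuchi"]
    fit_zero_order: ModelFit
    fit_higuchi: ModelFit

    @property
    def best(self) -> ModelFit:
        return self.fit_higuchi if self.basis == "higuchi" else self.fit_zero_order


def select_time_basis(
    profile: ReleaseProfile,
    window: Optional[tuple[float, float]] = None,
    tie_tolerance: float = 1e-12,
) -> BasisSelection:
    """Choose between t and sqrt(t) regression bases by R^2.

    Ties (R^2 equal within ``tie_tolerance``) resolve to Higuchi, the
    expected mechanism for a matrix-type ring.
    """
    fz = fit_zero_order(profile, window)
    fh = fit_higuchi(profile, window)
    if fz.r_squared > fh.r_squared + tie_tolerance:
        basis = "zero_order"
    else:
        basis = "higuchi"
    return BasisSelection(basis=basis, fit_zero_order=fz, fit_higuchi=fh)


def correct_interval_with_model(
    profile: ReleaseProfile,
    fit: ModelFit,
    interval: tuple[float, float],
) -> tuple[ReleaseProfile, float]:
    """Replace an anomalous stretch of a profile with model-predicted release.

    Within ``interval`` (inclusive, days) each sampling increment is replaced
    by the fitted model's predicted increment; the cumulative curve is
    rebuilt and the change in final cumulative release (µg) returned.  Used
    to back-calculate expected release across a transient artefact (e.g. a
    mis-prepared batch of medium causing a dip).
    """
    lo, hi = interval
    if lo > hi:
        raise InvalidParameterError("interval must satisfy lo <= hi")
    if lo > profile.times.max() or hi < profile.times.min():
        raise InvalidParameterError("correction interval outside profile time range")
    if fit.model == "peppas":
        raise InvalidParameterError(
            "interval correction expects an amount-scale model (zero_order/higuchi)"
        )
    t = profile.times
    prev_t = np.concatenate([[0.0], t[:-1]])
    increments = profile.interval_amounts.copy()
    in_window = (t >= lo) & (t <= hi)
    pred_inc = np.asarray(fit.predict(t)) - np.asarray(fit.predict(prev_t))
    increments[in_window] = pred_inc[in_window]
    corrected = replace(
        profile,
        interval_amounts=increments,
        cumulative=np.cumsum(increments),
        fractional=None,
        cumulative_sd=None,
        interval_sd=None,
    )
    delta = float(corrected.cumulative[-1] - profile.cumulative[-1])
    return corrected, delta


@dataclass(frozen=True)
class ExclusionResult:
    """Pooled refit after dropping anomalous replicate rings."""

    fit: ModelFit
    used_ids: tuple[str, ...]
    excluded_ids: tuple[str, ...]
    flagged_ids: tuple[str, ...]  # replicates diverging from the pooled fit
    pooled_profile: ReleaseProfile


def exclude_replicates(
    profiles: Sequence[ReleaseProfile],
    exclude_ids: Sequence[str] = (),
    basis: Literal["zero_order", "higuchi"] = "zero_order",
    window: Optional[tuple[float, float]] = None,
    flag_multiplier: float = 3.0,
) -> ExclusionResult:
    """Refit the pooled profile after excluding named replicates.

    Remaining replicates are additionally screened: residuals from the
    pooled fit are centred by their per-time median across rings (removing
    the shared lack-of-fit component), and any ring whose median absolute
    centred residual exceeds ``flag_multiplier`` times a robust (MAD-based)
    SD of all centred residuals is flagged as divergent (flagged, not
    dropped — exclusion stays an explicit analyst decision).
    """
    excl = set(exclude_ids)
    kept = [p for p in profiles if p.replicate_id not in excl]
    if not kept:
        raise InsufficientDataError("all replicates excluded")
    unknown = excl - {p.replicate_id for p in profiles}
    if unknown:
        raise InvalidParameterError(f"unknown replicate ids: {sorted(unknown)}")
    pooled = pool_replicates(kept)
    fitter = fit_higuchi if basis == "higuchi" else fit_zero_order
    fit = fitter(pooled, window)
    pred = np.asarray(fit.predict(pooled.times))
    residuals = np.vstack([p.cumulative - pred for p in kept])
    centred = residuals - np.median(residuals, axis=0, keepdims=True)
    robust_sd = 1.4826 * np.median(np.abs(centred - np.median(centred)))
    threshold = max(
        flag_multiplier * robust_sd,
        1e-9 * max(np.max(np.abs(pooled.cumulative)), 1.0),
    )
    flagged = tuple(
        p.replicate_id
        for p, e in zip(kept, centred)
        if np.median(np.abs(e)) > threshold
    )
    return ExclusionResult(
        fit=fit,
        used_ids=tuple(p.replicate_id for p in kept),
        excluded_ids=tuple(sorted(excl)),
        flagged_ids=flagged,
        pooled_profile=pooled,
    )
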