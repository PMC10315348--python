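"""Sink-condition assessment, mechanism classification and scaling summaries.

Sink conditions are judged against saturation solubility in the release
medium: daily sample concentrations below 10% of saturation define the
strict criterion, below 30% a relaxed one.  When release is not
solubility-limited, the time basis of the best linear fit and the
Korsmeyer-Peppas exponent classify the transport mechanism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .accounting import ConcentrationSeries
from .errors import InvalidParameterError
from .release_models import ModelFit

__all__ = [
    "MediumSpec",
    "SinkReport",
    "MechanismCall",
    "assess_sink",
    "classify_mechanism",
    "composition_summary",
    "scale_volume_for_target",
]


@dataclass(frozen=True)
class MediumSpec:
    """A release medium: identity, composition, pH and saturation solubility."""

    label: str
    solubility: float  # µg/mL saturation solubility of the drug
    volume: float  # mL in the vessel
    cosolvent_percent: float = 0.0  # % v/v water-miscible co-solvent
    pH: Optional[float] = None  # aqueous media only

    def __post_init__(self) -> None:
        if self.solubility <= 0:
            raise InvalidParameterError("medium solubility must be positive")
        if not 0.0 <= self.cosolvent_percent <= 100.0:
            raise InvalidParameterError("co-solvent percent must be in [0, 100]")
        if self.volume <= 0:
            raise InvalidParameterError("medium volume must be positive")


@dataclass(frozen=True)
class SinkReport:
    """Saturation ratios C/S over time and the sink verdicts they imply."""

    times: tuple[float, ...]
    ratios: tuple[float, ...]
    strict_sink: bool
    relaxed_sink: bool
    thresholds: tuple[float, float]
    max_ratio: float
    first_strict_violation: Optional[float]  # day, or None
    first_relaxed_violation: Optional[float]


def assess_sink(
    series: ConcentrationSeries,
    medium: MediumSpec,
    thresholds: tuple[float, float] = (0.10, 0.30),
) -> SinkReport:
    """Evaluate sink conditions from daily sample concentrations.

    ratio_i = C_i / S; strict sink requires every ratio below the first
    threshold, relaxed sink below the second.  The first violating day per
    threshold is reported for diagnostics.
    """
    strict_thr, relaxed_thr = thresholds
    if not 0 < strict_thr < relaxed_thr:
        raise InvalidParameterError("thresholds must satisfy 0 < strict < relaxed")
    ratios = series.concentrations / medium.solubility
    strict_bad = series.times[ratios >= strict_thr]
    relaxed_bad = series.times[ratios >= relaxed_thr]
    return SinkReport(
        times=tuple(series.times),
        ratios=tuple(ratios),
        strict_sink=strict_bad.size == 0,
        relaxed_sink=relaxed_bad.size == 0,
        thresholds=(strict_thr, relaxed_thr),
        max_ratio=float(ratios.max()) if ratios.size else 0.0,
        first_strict_violation=float(strict_bad[0]) if strict_bad.size else None,
        first_relaxed_violation=float(relaxed_bad[0]) if relaxed_bad.size else None,
    )


@dataclass(frozen=True)
class MechanismCall:
    """Release-mechanism label with the evidence behind it."""

    label: str
    rationale: str
    basis: str  # "zero_order" or "higuchi"
    n_exponent: Optional[float]
    peppas_used: bool


def classify_mechanism(
    fit_zero: ModelFit,
    fit_higuchi: ModelFit,
    fit_peppas: Optional[ModelFit],
    sink: SinkReport,
    fickian_n: float = 0.5,
    delta: float = 0.05,
) -> MechanismCall:
    """Deterministic mechanism call from time basis, exponent and sink state.

    Rules (sink = the relaxed criterion):

    * non-sink, linear-in-t fit at least as good  -> partition-controlled
      (release limited by medium solubility);
    * non-sink, root-time fit better              -> transitional; the
      Peppas exponent is suppressed with a warning, since power-law
      parameters are not interpretable without sink conditions;
    * sink, linear-in-t fit strictly better       -> zero-order release;
    * sink, root-time basis: n within fickian_n +/- delta -> Fickian matrix
      diffusion; fickian_n + delta < n < 1 -> anomalous transport; n >= 1
      -> super-case-II transport; n < fickian_n - delta -> pseudo-Fickian
      diffusion.
    """
    sink_ok = sink.relaxed_sink
    hig_better = fit_higuchi.r_squared >= fit_zero.r_squared  # tie -> higuchi
    basis = "higuchi" if hig_better else "zero_order"
    n = fit_peppas.n_exponent if fit_peppas is not None else None

    if not sink_ok:
        if not hig_better:
            return MechanismCall(
                label="partition-controlled",
                rationale=(
                    "sink conditions absent (max C/S "
                    f"{sink.max_ratio:.2f}) and cumulative release is linear in t: "
                    "release is limited by drug solubility in the medium"
                ),
                basis=basis, n_exponent=n, peppas_used=False,
            )
        warnings.warn(
            "root-time fit preferred but sink conditions absent; Peppas "
            "exponent suppressed — interpret mechanism with caution",
            stacklevel=2,
        )
        return MechanismCall(
            label="transitional (non-sink)",
            rationale=(
                "root-time basis fits better but saturation ratios reach "
                f"{sink.max_ratio:.2f}; the medium is between partition- and "
                "matrix-controlled regimes"
            ),
            basis=basis, n_exponent=n, peppas_used=False,
        )

    if not hig_better:
        return MechanismCall(
            label="zero-order release",
            rationale="sink conditions hold and cumulative release is linear in t",
            basis=basis, n_exponent=n, peppas_used=False,
        )
    if n is None:
        return MechanismCall(
            label="matrix diffusion (exponent unavailable)",
            rationale="root-time basis preferred under sink; no Peppas fit supplied",
            basis=basis, n_exponent=None, peppas_used=False,
        )
    if abs(n - fickian_n) <= delta:
        label, why = "Fickian matrix diffusion", (
            f"n = {n:.3f} within {fickian_n} +/- {delta}: diffusion out of the "
            "polymer matrix controls release"
        )
    elif n >= 1.0:
        label, why = "super-case-II transport", f"n = {n:.3f} >= 1"
    elif n > fickian_n + delta:
        label, why = "anomalous transport", (
            f"n = {n:.3f} in ({fickian_n + delta}, 1): coupled diffusion and "
            "solubility/relaxation effects"
        )
    else:
        label, why = "pseudo-Fickian diffusion", f"n = {n:.3f} < {fickian_n - delta}"
    return MechanismCall(label=label, rationale=why, basis=basis,
                         n_exponent=n, peppas_used=True)


def composition_summary(
    entries: Sequence[tuple[MediumSpec, ModelFit, float]],
) -> pd.DataFrame:
    """Tabulate release rate and day-1 burst against co-solvent content.

    ``entries`` are (medium, rate fit, day-1 interval amount µg) triples;
    rates are conventionally taken on the root-time basis for comparability
    across media.  Rows are ordered by co-solvent percent (stable).
    """
    rows = [
        {
            "medium": m.label,
            "cosolvent_percent": m.cosolvent_percent,
            "release_rate": fit.slope,
            "rate_ci_lo": fit.ci95_slope[0],
            "rate_ci_hi": fit.ci95_slope[1],
            "rate_basis": fit.model,
            "r_squared": fit.r_squared,
            "day1_burst_ug": burst,
        }
        for m, fit, burst in entries
    ]
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("cosolvent_percent", kind="stable").reset_index(drop=True)
    return df


def scale_volume_for_target(
    release_28d: float, volume: float, target: float
) -> float:
    """Medium volume required to reach a target 28-day release, assuming
    release scales linearly with aqueous volume.

    A deliberately transparent first-order extrapolation (volume * target /
    release); it carries all the caveats of the linearity assumption.
    """
    if release_28d <= 0 or volume <= 0 or target <= 0:
        raise InvalidParameterError("release, volume and target must be positive")
    return volume * target / release_28d
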