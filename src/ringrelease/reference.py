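"""Published reference values for the 25 mg dapivirine matrix vaginal ring.

Physicochemical constants, the measured solubility ladder across
isopropanol/water (IPA/water) mixtures and buffers, and the reported
release-kinetics parameters (with 95% confidence intervals) for the
monophasic IPA/water and biphasic buffer/octanol IVRT protocols.  These are
inputs for worked examples, consistency checks and simulator calibration —
not values the package computes.

Units: solubilities µg/mL; slopes µg/day or µg/day^1/2; intercepts µg;
day-28 cumulative release mg; Peppas intercepts log10(fraction).
"""

from __future__ import annotations

import math

from .errors import InvalidParameterError
from .physchem import DrugProperties

__all__ = [
    "DAPIVIRINE",
    "IPA_WATER_SOLUBILITY",
    "MONOPHASIC_KINETICS",
    "BIPHASIC_KINETICS",
    "IN_VIVO_RELEASE_28D_UG",
    "solubility_at_cosolvent",
]

#: Measured saturation solubility of dapivirine (µg/mL) per medium.
IPA_WATER_SOLUBILITY: dict[str, float] = {
    "0/100": 0.084,  # unbuffered water
    "10/90": 0.556,
    "20/80": 2.76,
    "30/70": 24.14,
    "40/60": 178.6,
    "50/50": 645.0,
}

DAPIVIRINE = DrugProperties(
    name="dapivirine",
    molecular_weight=329.4,
    pKa=5.30,
    logP=5.35,
    # unionized aqueous solubility, from the pH 7 phosphate-buffer
    # measurement (0.018 µg/mL) corrected for its ~2% ionized fraction
    intrinsic_solubility=0.01765,
    ring_loading=24400.0,  # µg; mean measured content of the 25 mg ring
    medium_solubilities={
        **IPA_WATER_SOLUBILITY,
        "phosphate_pH7": 0.018,
        "acetate_pH4.2": 0.499,
        "octanol": 6058.0,
    },
)

#: Reported release kinetics per monophasic IPA/water medium.  ``basis`` is
#: the time basis on which cumulative release was linear; media without sink
#: conditions have no meaningful Peppas parameters (None).
MONOPHASIC_KINETICS: dict[str, dict] = {
    "0/100": dict(
        basis="zero_order",
        slope=7.55, slope_ci=(7.41, 7.69),
        intercept=14.24, intercept_ci=(11.9, 16.58),
        r_squared=0.9931,
        day28_mg=0.218, day28_sd=0.004,
        peppas_n=None, peppas_n_ci=None,
        peppas_log10k=None, peppas_log10k_ci=None, peppas_r_squared=None,
    ),
    "10/90": dict(
        basis="zero_order",
        slope=25.0, slope_ci=(24.51, 25.51),
        intercept=58.48, intercept_ci=(50.25, 66.70),
        r_squared=0.9922,
        day28_mg=0.75, day28_sd=0.03,
        peppas_n=None, peppas_n_ci=None,
        peppas_log10k=None, peppas_log10k_ci=None, peppas_r_squared=None,
    ),
    "20/80": dict(
        basis="higuchi",
        slope=766.1, slope_ci=(723.8, 808.4),
        intercept=-723.4, intercept_ci=(-883.4, -563.5),
        r_squared=0.9427,
        day28_mg=3.49, day28_sd=0.31,
        peppas_n=0.817, peppas_n_ci=(0.7751, 0.8589),
        peppas_log10k=-2.044, peppas_log10k_ci=(-2.090, -1.998),
        peppas_r_squared=0.9507,
    ),
    "30/70": dict(
        basis="higuchi",
        slope=1693.0, slope_ci=(1685.0, 1702.0),
        intercept=-903.0, intercept_ci=(-935.9, -870.0),
        r_squared=0.9995,
        day28_mg=8.01, day28_sd=0.07,
        peppas_n=0.6638, peppas_n_ci=(0.6505, 0.6771),
        peppas_log10k=-1.447, peppas_log10k_ci=(-1.462, -1.433),
        peppas_r_squared=0.9922,
    ),
    "40/60": dict(
        basis="higuchi",
        slope=1904.0, slope_ci=(1879.0, 1929.0),
        intercept=-430.5, intercept_ci=(-524.9, -336.2),
        r_squared=0.9966,
        day28_mg=9.54, day28_sd=0.20,
        peppas_n=0.5622, peppas_n_ci=(0.5547, 0.5698),
        peppas_log10k=-1.235, peppas_log10k_ci=(-1.244, -1.227),
        peppas_r_squared=0.9965,
    ),
    "50/50": dict(
        basis="higuchi",
        slope=2022.0, slope_ci=(2004.0, 2040.0),
        intercept=-238.5, intercept_ci=(-306.7, -170.2),
        r_squared=0.9984,
        day28_mg=10.35, day28_sd=0.11,
        peppas_n=0.535, peppas_n_ci=(0.5294, 0.5406),
        peppas_log10k=-1.163, peppas_log10k_ci=(-1.169, -1.157),
        peppas_r_squared=0.9978,
    ),
}

#: Reported octanol-phase accumulation kinetics (zero-order basis) for the
#: biphasic buffer/octanol protocol, with and without the anomalous rings
#: (octanol-contact artefacts) excluded.
BIPHASIC_KINETICS: dict[str, dict] = {
    "pH7": dict(
        slope=31.88, slope_ci=(22.89, 40.88),
        intercept=-57.15, intercept_ci=(-205.2, 90.91),
        r_squared=0.3898, day28_mg=0.85, day28_sd=0.82,
        excluded=(),
    ),
    "pH4.2": dict(
        slope=68.81, slope_ci=(56.67, 80.95),
        intercept=-89.70, intercept_ci=(-289.6, 110.2),
        r_squared=0.6202, day28_mg=1.58, day28_sd=0.72,
        excluded=(),
    ),
    "pH7_minus_ring4": dict(
        slope=17.77, slope_ci=(14.81, 20.73),
        intercept=9.91, intercept_ci=(-38.84, 58.66),
        r_squared=0.7134, day28_mg=0.44, day28_sd=0.11,
        excluded=("ring4",),
    ),
    "pH4.2_minus_rings_5_8": dict(
        slope=40.94, slope_ci=(38.19, 43.69),
        intercept=-26.24, intercept_ci=(-71.52, 19.03),
        r_squared=0.9598, day28_mg=0.98, day28_sd=0.14,
        excluded=("ring5", "ring8"),
    ),
}

#: Average cumulative dapivirine release over 28 days of clinical ring use,
#: from residual-content assays (µg).
IN_VIVO_RELEASE_28D_UG = 4000.0


def solubility_at_cosolvent(percent: float) -> float:
    """Dapivirine solubility (µg/mL) at an arbitrary co-solvent percentage.

    Tabulated levels are returned exactly; between levels the measured
    ladder spans ~4 orders of magnitude, so interpolation is log-linear in
    co-solvent %.  No extrapolation beyond the measured 0-50% range.
    """
    pts = sorted((float(label.split("/")[0]), s)
                 for label, s in IPA_WATER_SOLUBILITY.items())
    lo_p, hi_p = pts[0][0], pts[-1][0]
    if not lo_p <= percent <= hi_p:
        raise InvalidParameterError(
            f"co-solvent percent {percent} outside measured range [{lo_p}, {hi_p}]"
        )
    for (p0, s0), (p1, s1) in zip(pts, pts[1:]):
        if p0 <= percent <= p1:
            if percent == p0:
                return s0
            if percent == p1:
                return s1
            frac = (percent - p0) / (p1 - p0)
            return 10.0 ** (math.log10(s0) + frac * (math.log10(s1) - math.log10(s0)))
    return pts[-1][1]
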