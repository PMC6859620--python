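"""RNA decay kinetics, LC-MS/MS calibration and qPCR enrichment.

Decay follows the first-order shutoff model N_t/N_0 = e^(-k t): after
transcription inhibition a transcript's relative abundance decays
exponentially with rate k (per hour), giving a half-life t1/2 = ln2/k.
The fit is ordinary least squares of ln(N_t) on t with the intercept fixed
at zero, which is exact for series normalised to N_0 = 1.

Nucleoside quantification mirrors triple-quadrupole LC-MS/MS practice:
per-channel linear standard curves (m6A monitored at the 282->150 mass
transition, adenosine at 268->136), sample responses converted to
concentrations through the fitted curve, and the m6A/A ratio taken on the
calibrated concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

#: channel labels carrying the nucleoside-to-base ion mass transitions
CHANNEL_M6A = "m6A:282>150"
CHANNEL_A = "A:268>136"
VALID_CHANNELS = (CHANNEL_M6A, CHANNEL_A)

LN2 = math.log(2.0)


@dataclass(frozen=True)
class DecaySeries:
    """A shutoff time course: hours and abundances relative to t = 0."""

    timepoints: np.ndarray
    abundances: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.timepoints, dtype=float)
        a = np.asarray(self.abundances, dtype=float)
        if t.shape != a.shape or t.ndim != 1:
            raise ValueError("timepoints and abundances must be 1-D and aligned")
        object.__setattr__(self, "timepoints", t)
        object.__setattr__(self, "abundances", a)

    def normalized(self) -> "DecaySeries":
        """Rescale so the abundance at t = 0 is exactly 1."""
        at0 = self.abundances[self.timepoints == 0]
        if at0.size == 0:
            raise ValueError("series has no t = 0 reference point")
        return DecaySeries(self.timepoints, self.abundances / at0[0])


@dataclass(frozen=True)
class DecayFit:
    k: float                 # per-hour degradation rate
    t_half: float            # hours; inf when the series does not decay
    r_squared: float         # on the log scale
    n_points: int
    decaying: bool = True    # False flags a fitted k <= 0


@dataclass(frozen=True)
class CalibrationCurve:
    channel: str
    slope: float
    intercept: float
    r_squared: float
    n_standards: int


@dataclass(frozen=True)
class QpcrMeasurement:
    """Paired IP/input Ct values for one amplicon."""

    target: str
    ct_ip: float
    ct_input: float
    input_dilution_factor: float = 1.0

    def __post_init__(self):
        if not (math.isfinite(self.ct_ip) and math.isfinite(self.ct_input)):
            raise ValueError("Ct values must be finite")
        if self.ct_ip <= 0 or self.ct_input <= 0:
            raise ValueError("Ct values must be positive")
        if self.input_dilution_factor < 1:
            raise ValueError("input_dilution_factor must be >= 1")


def fit_decay(series: DecaySeries) -> DecayFit:
    """Fit N_t = e^(-k t) by least squares on the log scale, origin fixed.

    The series is renormalised to N_0 = 1 first, so the model has a single
    parameter and k has the closed form -sum(t*lnN)/sum(t^2).  R^2 is
    computed on ln(N); a non-decaying series (fitted k <= 0) is returned
    flagged with an infinite half-life rather than raising.
    """
    s = series.normalized()
    t, a = s.timepoints, s.abundances
    if t.size < 3:
        raise ValueError("need >= 3 timepoints to fit a decay rate")
    bad = np.flatnonzero(a <= 0)
    if bad.size:
        raise ValueError(f"non-positive abundance at t = {t[bad[0]]} h")
    ln_a = np.log(a)
    k = -float(np.dot(t, ln_a) / np.dot(t, t))
    resid = ln_a + k * t
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.sum((ln_a - ln_a.mean()) ** 2))
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        r2 = 1.0 if ss_res < 1e-12 else 0.0
    if k <= 0:
        return DecayFit(k=k, t_half=math.inf, r_squared=r2,
                        n_points=int(t.size), decaying=False)
    return DecayFit(k=k, t_half=LN2 / k, r_squared=r2, n_points=int(t.size))


def half_life(k: float) -> float:
    """Half-life t1/2 = ln2/k (hours) of a first-order decay rate k (> 0)."""
    if k <= 0:
        raise ValueError("half-life is defined for k > 0 only")
    return LN2 / k


def fit_calibration(
    standards: Sequence[tuple[float, float]],
    channel: str,
) -> CalibrationCurve:
    """OLS standard curve (response = slope * concentration + intercept)."""
    if channel not in VALID_CHANNELS:
        raise ValueError(f"unknown channel {channel!r}; expected one of {VALID_CHANNELS}")
    pts = np.asarray(list(standards), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need >= 2 (concentration, response) standards")
    conc, resp = pts[:, 0], pts[:, 1]
    if np.unique(conc).size < 2:
        raise ValueError("calibration requires >= 2 distinct concentrations")
    res = stats.linregress(conc, resp)
    return CalibrationCurve(
        channel=channel,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_standards=int(conc.size),
    )


def quantify_m6a_to_a_ratio(
    responses: Mapping[str, float],
    curves: Mapping[str, CalibrationCurve],
) -> float:
    """m6A/A ratio from calibrated concentrations of the two channels."""
    conc = {}
    for channel in (CHANNEL_M6A, CHANNEL_A):
        if channel not in responses or channel not in curves:
            raise ValueError(f"missing response or curve for channel {channel!r}")
        curve = curves[channel]
        if curve.slope <= 0:
            raise ValueError(f"invalid calibration slope for channel {channel!r}")
        c = (responses[channel] - curve.intercept) / curve.slope
        if c <= 0:
            raise ValueError(f"calibrated concentration <= 0 on channel {channel!r}")
        conc[channel] = c
    return conc[CHANNEL_M6A] / conc[CHANNEL_A]


def qpcr_percent_input(measure: QpcrMeasurement) -> float:
    """Percent input: 100 * 2^(adjusted input Ct - IP Ct).

    The input Ct is first corrected for its dilution factor by subtracting
    log2(dilution), the standard 2^dCt adjustment.
    """
    adj_input = measure.ct_input - math.log2(measure.input_dilution_factor)
    return 100.0 * 2.0 ** (adj_input - measure.ct_ip)


def fold_enrichment(target: QpcrMeasurement, reference: QpcrMeasurement) -> float:
    """Ratio of percent-input enrichment of a target region over a reference."""
    return qpcr_percent_input(target) / qpcr_percent_input(reference)
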