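"""Ecoenzymatic stoichiometry vector analysis and root N:P classification.

Microbial nutrient limitation is read off ratios of ln-transformed
potential activities of four extracellular enzymes: BG (C-acquiring),
NAG + LAP (N-acquiring) and ACP (P-acquiring).  With

    x = ln(BG) / ln(ACP)          (C:P acquisition ratio)
    y = ln(BG) / ln(NAG + LAP)    (C:N acquisition ratio)

the vector length sqrt(x^2 + y^2) indexes relative microbial C
limitation (longer = more C-limited) and the vector angle

    angle = atan(ln(ACP) / ln(NAG + LAP))   [degrees]

indexes relative N vs P limitation: > 45 deg means relative P
limitation, < 45 deg relative N limitation.  Its complement,

    microbial N limitation = atan(ln(NAG + LAP) / ln(ACP)) = 90 deg - angle,

grows with the severity of microbial N limitation.  The enzymatic N:P
acquisition ratio N:P_SEE = ln(NAG+LAP)/ln(ACP) crosses 1 exactly where
the angle crosses 45 deg.

For fine roots, the point (TN, TP) in content space makes an angle
atan(TP/TN) with the TN axis.  The conventional foliar/root thresholds
N:P = 14 (N limitation below) and N:P = 16 (P limitation above)
correspond to angles 4.09 deg and 3.58 deg: angles above 4.09 deg call
relative N limitation, below 3.58 deg relative P limitation, and the
band between them neither.

All logarithms are natural; every activity entering a log must exceed
1 nmol g-1 h-1 so its log is strictly positive -- smaller activities
raise :class:`~rhizostoich.errors.DomainError` rather than being
clamped, because clamping could silently flip a limitation call.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data_model import EnzymeProfile, PlotObservation, RootChemistry
from .errors import ConfigError, DomainError

#: microbial vector-angle boundary between relative N and P limitation (degrees)
MICROBIAL_ANGLE_THRESHOLD = 45.0
#: root vector-angle thresholds (degrees); numerically the N:P = 16 and 14 lines
ROOT_ANGLE_LOW = 3.58
ROOT_ANGLE_HIGH = 4.09
#: root N:P mass-ratio reference below which roots are conventionally N-limited
ROOT_NP_REFERENCE = 14.0

_TIE_TOL = 1e-9


def angle_threshold_from_np(np_ref: float) -> float:
    """Root vector angle (degrees) lying exactly on a given N:P line.

    atan(1/np_ref); 14 -> 4.0856, 16 -> 3.5763.  The conventional 2-dp
    thresholds (4.09, 3.58) are roundings of these; use the exact values
    when the angle rule must agree with the ratio rule everywhere.
    """
    if np_ref <= 0:
        raise ConfigError(f"N:P reference must be > 0, got {np_ref}")
    return math.degrees(math.atan(1.0 / np_ref))


def _ln_checked(value: float, name: str) -> float:
    if not np.isfinite(value) or value <= 1.0:
        raise DomainError(
            f"{name} must exceed 1 nmol g-1 h-1 for a strictly positive "
            f"natural log, got {value}"
        )
    return math.log(value)


def _lns(e: EnzymeProfile) -> tuple[float, float, float]:
    """(ln BG, ln(NAG+LAP), ln ACP) with the log-domain guard applied."""
    return (
        _ln_checked(e.bg, "BG"),
        _ln_checked(e.n_acq, "NAG+LAP"),
        _ln_checked(e.acp, "ACP"),
    )


def enzyme_np_ratio(e: EnzymeProfile) -> float:
    """Enzymatic N:P acquisition ratio, ln(NAG+LAP) / ln(ACP)."""
    _, ln_n, ln_p = _lns(e)
    return ln_n / ln_p


def enzyme_cnp_ratio(e: EnzymeProfile) -> tuple[float, float, float]:
    """Enzyme C:N:P stoichiometry normalized to C: (1, lnN/lnC, lnP/lnC)."""
    ln_c, ln_n, ln_p = _lns(e)
    return (1.0, ln_n / ln_c, ln_p / ln_c)


def vector_length(e: EnzymeProfile) -> float:
    """Relative microbial C limitation: sqrt(x^2 + y^2) of the ln-ratio point."""
    ln_c, ln_n, ln_p = _lns(e)
    x = ln_c / ln_p
    y = ln_c / ln_n
    return math.hypot(x, y)


def vector_angle(e: EnzymeProfile) -> float:
    """Microbial vector angle in degrees; > 45 relative P limitation,
    < 45 relative N limitation.

    Equal N- and P-acquiring log-activities give exactly 45 degrees.  The
    positive-log guard confines the point to the open first quadrant, so a
    single-argument arctangent of ln(ACP)/ln(NAG+LAP) is quadrant-safe.
    """
    _, ln_n, ln_p = _lns(e)
    return math.degrees(math.atan(ln_p / ln_n))


def microbial_n_limitation(e: EnzymeProfile) -> float:
    """Microbial N-limitation angle, degrees; the complement of
    :func:`vector_angle` (their sum is exactly 90).  Larger values mean
    stronger relative microbial N limitation."""
    _, ln_n, ln_p = _lns(e)
    return math.degrees(math.atan(ln_n / ln_p))


def classify_microbial_limitation(angle: float) -> str:
    """Call microbial limitation from the vector angle: 'P-limited' above
    45 deg, 'N-limited' below, 'balanced' within 1e-9 deg of the boundary."""
    if abs(angle - MICROBIAL_ANGLE_THRESHOLD) <= _TIE_TOL:
        return "balanced"
    return "P-limited" if angle > MICROBIAL_ANGLE_THRESHOLD else "N-limited"


def root_np(r: RootChemistry) -> float:
    """Fine-root N:P mass ratio TN/TP (g N per g P)."""
    if r.tp <= 0:
        raise DomainError(f"root TP must be > 0, got {r.tp}")
    return r.tn / r.tp


def root_vector_angle(r: RootChemistry) -> float:
    """Angle (degrees) of the point (TN, TP) from the TN axis: atan(TP/TN).

    Rises as roots become N-poor relative to P; 4.09 deg and 3.58 deg sit
    exactly on the N:P = 14 and 16 reference lines.
    """
    if r.tn <= 0 or r.tp <= 0:
        raise DomainError(f"root TN and TP must be > 0, got TN={r.tn}, TP={r.tp}")
    return math.degrees(math.atan(r.tp / r.tn))


def classify_root_limitation(
    angle: float, thresholds: tuple[float, float] = (ROOT_ANGLE_LOW, ROOT_ANGLE_HIGH)
) -> str:
    """Call root limitation from the root vector angle.

    'N-limited' above the high threshold, 'P-limited' below the low one,
    'unlimited' in between (boundary values inclusive, matching the strict
    inequalities of the calling rule)."""
    low, high = thresholds
    if not (0 < low < high):
        raise ConfigError(f"thresholds must satisfy 0 < low < high, got {thresholds}")
    if angle > high:
        return "N-limited"
    if angle < low:
        return "P-limited"
    return "unlimited"


@dataclass(frozen=True)
class EnzymeVectorResult:
    """All microbial-limitation metrics for one enzyme profile."""

    ln_bg: float
    ln_n_acq: float
    ln_acp: float
    np_see: float
    vector_length: float
    vector_angle: float
    microbial_n_limitation: float
    limitation_call: str


def enzyme_vector_result(e: EnzymeProfile) -> EnzymeVectorResult:
    ln_c, ln_n, ln_p = _lns(e)
    angle = math.degrees(math.atan(ln_p / ln_n))
    return EnzymeVectorResult(
        ln_bg=ln_c,
        ln_n_acq=ln_n,
        ln_acp=ln_p,
        np_see=ln_n / ln_p,
        vector_length=math.hypot(ln_c / ln_p, ln_c / ln_n),
        vector_angle=angle,
        microbial_n_limitation=math.degrees(math.atan(ln_n / ln_p)),
        limitation_call=classify_microbial_limitation(angle),
    )


@dataclass(frozen=True)
class RootVectorResult:
    """Root N:P ratio, vector angle and limitation call for one plot."""

    np_con: float
    root_vector_angle: float
    limitation_call: str


def root_vector_result(
    r: RootChemistry,
    thresholds: tuple[float, float] = (ROOT_ANGLE_LOW, ROOT_ANGLE_HIGH),
) -> RootVectorResult:
    angle = root_vector_angle(r)
    return RootVectorResult(
        np_con=root_np(r),
        root_vector_angle=angle,
        limitation_call=classify_root_limitation(angle, thresholds),
    )


def plot_vector_metrics(obs: PlotObservation, thresholds=(ROOT_ANGLE_LOW, ROOT_ANGLE_HIGH)) -> dict:
    """One flat record of all vector metrics for a plot (for CSV output)."""
    ev = enzyme_vector_result(obs.rhizo_enzymes)
    rv = root_vector_result(obs.root, thresholds)
    return {
        "age_class": obs.key.age_class,
        "n_level": obs.key.n_level,
        "block": obs.key.block,
        "np_see": ev.np_see,
        "vector_length": ev.vector_length,
        "vector_angle": ev.vector_angle,
        "microbial_n_limitation": ev.microbial_n_limitation,
        "microbial_call": ev.limitation_call,
        "np_con": rv.np_con,
        "root_vector_angle": rv.root_vector_angle,
        "root_call": rv.limitation_call,
    }


@dataclass(frozen=True)
class SMAFit:
    """Standardized major axis line in (x, y): slope = sign(r) sd(y)/sd(x)."""

    slope: float
    intercept: float
    r: float
    n: int


def sma_fit(x, y) -> SMAFit:
    """Standardized (reduced) major axis regression.

    The symmetric line-fitting method of allometry and stoichiometric
    scaling: slope magnitude sd(y)/sd(x), sign taken from the Pearson
    correlation; intercept through the means.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 3:
        raise DomainError(f"SMA needs n >= 3, got {n}")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise DomainError("SMA is degenerate when either variable has zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    sign = -1.0 if r < 0 else 1.0
    slope = sign * sy / sx
    intercept = float(y.mean() - slope * x.mean())
    return SMAFit(slope=float(slope), intercept=intercept, r=r, n=int(n))
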