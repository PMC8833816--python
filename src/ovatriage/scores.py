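"""Serum-marker risk scores: ROMA and RMI.

ROMA (Risk of Malignancy Algorithm) is a logistic score on ln(HE4) and
ln(CA125) with menopause-specific coefficients:

    premenopausal  PI = -12.0 + 2.38 ln(HE4) + 0.0626 ln(CA125)
    postmenopausal PI = -8.09 + 1.04 ln(HE4) + 0.732 ln(CA125)
    ROMA = 100 * exp(PI) / (1 + exp(PI))

High risk at ROMA >= 7.4 (pre) or >= 25.3 (post); both cut-offs inclusive.

RMI (Risk of Malignancy Index, variant I) multiplies an ultrasound score
U in {0, 1, 3} (zero, one, or two-plus of five features: multilocular
cyst, solid areas, metastases, ascites, bilaterality), a menopausal score
M (1 pre, 3 post) and serum CA125 in U/mL; high risk at RMI >= 200
(inclusive).  The U/M value mapping is the classical Jacobs convention;
both it and the cut-offs are configurable via :class:`Thresholds`.

Thresholds compare the unrounded score; display rounding never feeds back
into classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .cohort import RMI_FLAGS, UltrasoundExam

#: (intercept, HE4 coefficient, CA125 coefficient) on the natural-log scale.
ROMA_COEFFICIENTS: dict[str, tuple[float, float, float]] = {
    "pre": (-12.0, 2.38, 0.0626),
    "post": (-8.09, 1.04, 0.732),
}

#: RMI-I menopausal score.
RMI_MENOPAUSAL_SCORE: dict[str, float] = {"pre": 1.0, "post": 3.0}


@dataclass(frozen=True)
class Thresholds:
    """Decision cut-offs, defaults as published (all inclusive at the boundary)."""

    roma_pre: float = 7.4
    roma_post: float = 25.3
    rmi_cut: float = 200.0

    def __post_init__(self) -> None:
        for name in ("roma_pre", "roma_post", "rmi_cut"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name}: threshold must be strictly positive")

    def roma_cut(self, menopausal: str) -> float:
        return self.roma_pre if menopausal == "pre" else self.roma_post


@dataclass(frozen=True)
class RomaResult:
    pi: float
    score: float  # percentage in (0, 100)
    call: str  # high | low


@dataclass(frozen=True)
class RmiResult:
    u: float
    m: float
    rmi: float  # units of CA125 (U/mL)
    call: str  # high | low


def roma_pi(he4: float, ca125: float, menopausal: str) -> float:
    """Predictive index; raises on non-positive markers (log undefined)."""
    if not he4 > 0:
        raise ValueError(f"he4: must be strictly positive for ROMA, got {he4}")
    if not ca125 > 0:
        raise ValueError(f"ca125: must be strictly positive for ROMA, got {ca125}")
    a, b_he4, b_ca = ROMA_COEFFICIENTS[menopausal]
    return a + b_he4 * math.log(he4) + b_ca * math.log(ca125)


def roma_score(pi: float) -> float:
    """Logistic transform of the predictive index, as a percentage."""
    # evaluate the stable branch so large |pi| cannot overflow exp()
    if pi >= 0:
        return 100.0 / (1.0 + math.exp(-pi))
    e = math.exp(pi)
    return 100.0 * e / (1.0 + e)


def classify_roma(score: float, menopausal: str, thresholds: Thresholds = Thresholds()) -> str:
    return "high" if score >= thresholds.roma_cut(menopausal) else "low"


def roma(he4: float, ca125: float, menopausal: str, thresholds: Thresholds = Thresholds()) -> RomaResult:
    pi = roma_pi(he4, ca125, menopausal)
    score = roma_score(pi)
    return RomaResult(pi=pi, score=score, call=classify_roma(score, menopausal, thresholds))


def rmi_ultrasound_score(exam: UltrasoundExam) -> float:
    """U = 0 / 1 / 3 for zero / one / two-or-more RMI features present."""
    count = sum(getattr(exam, name) for name in RMI_FLAGS)
    if count == 0:
        return 0.0
    return 1.0 if count == 1 else 3.0


def classify_rmi(rmi_value: float, thresholds: Thresholds = Thresholds()) -> str:
    return "high" if rmi_value >= thresholds.rmi_cut else "low"


def rmi_score(u: float, menopausal: str, ca125: float, thresholds: Thresholds = Thresholds()) -> RmiResult:
    if not ca125 >= 0:
        raise ValueError(f"ca125: must be non-negative, got {ca125}")
    m = RMI_MENOPAUSAL_SCORE[menopausal]
    value = u * m * ca125
    return RmiResult(u=u, m=m, rmi=value, call=classify_rmi(value, thresholds))


def rmi(exam: UltrasoundExam, menopausal: str, ca125: float, thresholds: Thresholds = Thresholds()) -> RmiResult:
    return rmi_score(rmi_ultrasound_score(exam), menopausal, ca125, thresholds)
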