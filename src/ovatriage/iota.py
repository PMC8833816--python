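"""IOTA simple rules: three-way classification of an adnexal mass.

The rules use five benign features (B-features) and five malignant features
(M-features) recorded at ultrasound.  A mass is called malignant if at
least one M-feature is present and no B-feature, benign if at least one
B-feature is present and no M-feature, and inconclusive otherwise (no
features at all, or features of both kinds).
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import IOTA_B_FLAGS, IOTA_M_FLAGS, UltrasoundExam

IOTA_CALLS = ("benign", "malignant", "inconclusive")


@dataclass(frozen=True)
class IotaResult:
    n_b: int  # number of B-features present (0-5)
    n_m: int  # number of M-features present (0-5)
    call: str  # benign | malignant | inconclusive

    @property
    def conclusive(self) -> bool:
        return self.call != "inconclusive"


def count_features(exam: UltrasoundExam) -> tuple[int, int]:
    """Count (B-features, M-features) present on the exam."""
    n_b = sum(getattr(exam, name) for name in IOTA_B_FLAGS)
    n_m = sum(getattr(exam, name) for name in IOTA_M_FLAGS)
    return n_b, n_m


def classify_iota(exam: UltrasoundExam) -> IotaResult:
    n_b, n_m = count_features(exam)
    if n_m >= 1 and n_b == 0:
        call = "malignant"
    elif n_b >= 1 and n_m == 0:
        call = "benign"
    else:
        call = "inconclusive"
    return IotaResult(n_b=n_b, n_m=n_m, call=call)
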