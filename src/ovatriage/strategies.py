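"""Triage strategies composing IOTA simple rules with a fallback test.

Five strategies are evaluated per woman, plus a conclusive-only pseudo
strategy:

* ``IOTA_EXPERT`` - IOTA first; inconclusive masses go to the recorded
  subjective expert-ultrasound call.
* ``IOTA_ROMA`` / ``IOTA_RMI`` - IOTA first; inconclusive masses are
  classified by ROMA / RMI.
* ``ROMA_ALONE`` / ``RMI_ALONE`` - the marker score on every woman,
  ignoring IOTA.
* ``IOTA_ONLY`` - IOTA by itself, defined only where it is conclusive
  (used for the conclusive-stratum tables).

A record missing a component a strategy needs (HE4 for ROMA paths, the
expert call for ``IOTA_EXPERT`` on an inconclusive mass) is flagged
non-evaluable with a reason, never silently dropped and never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import Cohort, PatientRecord
from .iota import IotaResult, classify_iota
from .scores import RmiResult, RomaResult, Thresholds, rmi, roma

#: The five published strategies, then the conclusive-only pseudo strategy.
STRATEGIES = ("IOTA_EXPERT", "IOTA_ROMA", "IOTA_RMI", "ROMA_ALONE", "RMI_ALONE", "IOTA_ONLY")

#: Strategies that consult IOTA first and fall back only when inconclusive.
IOTA_FIRST = ("IOTA_EXPERT", "IOTA_ROMA", "IOTA_RMI")


@dataclass(frozen=True)
class RiskCall:
    """A binary high/low call plus the intermediates that produced it."""

    patient_id: str
    strategy: str
    call: str | None  # high | low | None when not evaluable
    iota: IotaResult
    fallback_used: bool
    evaluable: bool
    reason: str | None = None
    roma: RomaResult | None = None
    rmi: RmiResult | None = None
    expert_call: str | None = None


def _not_evaluable(record: PatientRecord, strategy: str, iota: IotaResult, reason: str) -> RiskCall:
    return RiskCall(
        patient_id=record.patient_id,
        strategy=strategy,
        call=None,
        iota=iota,
        fallback_used=False,
        evaluable=False,
        reason=reason,
    )


def _roma_component(record: PatientRecord, thresholds: Thresholds) -> RomaResult | None:
    if record.he4 is None or record.he4 <= 0 or record.ca125 <= 0:
        return None
    return roma(record.he4, record.ca125, record.menopausal, thresholds)


def apply_strategy(
    record: PatientRecord, strategy: str, thresholds: Thresholds = Thresholds()
) -> RiskCall:
    """Produce the strategy's risk call for one record.

    IOTA-first strategies return high/low directly when IOTA is conclusive
    and otherwise delegate to their fallback; the standalone strategies
    ignore IOTA (its result is attached for information only).
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    iota = classify_iota(record.exam)

    if strategy == "IOTA_ONLY":
        if not iota.conclusive:
            return _not_evaluable(record, strategy, iota, "iota inconclusive")
        return RiskCall(
            patient_id=record.patient_id,
            strategy=strategy,
            call="high" if iota.call == "malignant" else "low",
            iota=iota,
            fallback_used=False,
            evaluable=True,
        )

    if strategy in IOTA_FIRST and iota.conclusive:
        return RiskCall(
            patient_id=record.patient_id,
            strategy=strategy,
            call="high" if iota.call == "malignant" else "low",
            iota=iota,
            fallback_used=False,
            evaluable=True,
        )

    # fallback / standalone component
    if strategy == "IOTA_EXPERT":
        if record.expert_call is None:
            return _not_evaluable(record, strategy, iota, "expert call missing")
        return RiskCall(
            patient_id=record.patient_id,
            strategy=strategy,
            call="high" if record.expert_call == "malignant" else "low",
            iota=iota,
            fallback_used=True,
            evaluable=True,
            expert_call=record.expert_call,
        )

    if strategy in ("IOTA_ROMA", "ROMA_ALONE"):
        component = _roma_component(record, thresholds)
        if component is None:
            return _not_evaluable(record, strategy, iota, "he4/ca125 unavailable for ROMA")
        return RiskCall(
            patient_id=record.patient_id,
            strategy=strategy,
            call=component.call,
            iota=iota,
            fallback_used=strategy == "IOTA_ROMA",
            evaluable=True,
            roma=component,
        )

    # IOTA_RMI or RMI_ALONE
    component = rmi(record.exam, record.menopausal, record.ca125, thresholds)
    return RiskCall(
        patient_id=record.patient_id,
        strategy=strategy,
        call=component.call,
        iota=iota,
        fallback_used=strategy == "IOTA_RMI",
        evaluable=True,
        rmi=component,
    )


def run_all_strategies(cohort: Cohort, thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Prediction table: one row per record x strategy.

    Columns: patient_id, strategy, call, iota_call, n_b, n_m,
    fallback_used, evaluable, reason, roma_score, rmi_value.  Non-evaluable
    pairs keep their row with ``evaluable=False`` and a reason.
    """
    rows = []
    for record in cohort:
        for strategy in STRATEGIES:
            rc = apply_strategy(record, strategy, thresholds)
            rows.append(
                {
                    "patient_id": rc.patient_id,
                    "strategy": rc.strategy,
                    "call": rc.call,
                    "iota_call": rc.iota.call,
                    "n_b": rc.iota.n_b,
                    "n_m": rc.iota.n_m,
                    "fallback_used": rc.fallback_used,
                    "evaluable": rc.evaluable,
                    "reason": rc.reason,
                    "roma_score": None if rc.roma is None else rc.roma.score,
                    "rmi_value": None if rc.rmi is None else rc.rmi.rmi,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "strategy",
            "call",
            "iota_call",
            "n_b",
            "n_m",
            "fallback_used",
            "evaluable",
            "reason",
            "roma_score",
            "rmi_value",
        ],
    )
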