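"""Diagnostic-accuracy evaluation: 2x2 tables, binomial CIs, paired tests.

Sensitivity is the proportion of histology-malignant masses (borderline
included) called high risk; specificity the proportion of benign masses
called low risk; accuracy the proportion of all analysed masses called
correctly.  Confidence intervals are exact Clopper-Pearson by default
(Wilson selectable).  Two strategies evaluated on the same women are
compared with the McNemar test on the discordant pairs: sensitivity on
the diseased, specificity on the non-diseased, accuracy on everyone.
No multiplicity adjustment is applied; p-values are reported raw.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .cohort import Cohort, PatientRecord

CI_METHODS = ("clopper_pearson", "wilson")
_STATSMODELS_METHOD = {"clopper_pearson": "beta", "wilson": "wilson"}

METRIC_NAMES = ("sensitivity", "specificity", "accuracy")


class PredictionIntegrityError(ValueError):
    """A prediction row has no matching cohort record (or misaligned flags)."""


@dataclass(frozen=True)
class TwoByTwo:
    """Prediction (high/low) versus histology (malignant/benign) counts."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name}: count must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def diseased(self) -> int:
        return self.tp + self.fn

    @property
    def non_diseased(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class MetricEstimate:
    name: str
    numerator: int
    denominator: int
    point: float
    ci_low: float
    ci_high: float
    method: str = "clopper_pearson"
    level: float = 0.95
    defined: bool = True


@dataclass(frozen=True)
class PairedComparison:
    """McNemar comparison of two classifiers on one metric and subset.

    ``b`` counts records correct by A only, ``c`` correct by B only.
    ``p_exact`` is the two-sided exact binomial tail at p = 1/2 on
    (min(b, c), b + c), capped at 1; ``p_cc`` the continuity-corrected
    chi-square p.  By convention p = 1 when b + c = 0.
    """

    metric: str
    subset: str
    b: int
    c: int
    statistic: float
    p_exact: float
    p_cc: float
    n: int


def proportion_ci(
    x: int, n: int, method: str = "clopper_pearson", level: float = 0.95
) -> tuple[float, float]:
    """Binomial confidence interval for x successes in n trials."""
    if not 0 <= x <= n or n < 1:
        raise ValueError(f"require 0 <= x <= n and n >= 1, got x={x}, n={n}")
    if method not in CI_METHODS:
        raise ValueError(f"method must be one of {CI_METHODS}")
    low, high = proportion_confint(x, n, alpha=1 - level, method=_STATSMODELS_METHOD[method])
    # degenerate boundaries are exact by construction; clip floating fuzz
    low = 0.0 if x == 0 else min(max(float(low), 0.0), 1.0)
    high = 1.0 if x == n else min(max(float(high), 0.0), 1.0)
    return low, high


def _estimate(name: str, x: int, n: int, method: str, level: float) -> MetricEstimate:
    if n == 0:
        return MetricEstimate(
            name=name, numerator=0, denominator=0, point=float("nan"),
            ci_low=float("nan"), ci_high=float("nan"), method=method, level=level,
            defined=False,
        )
    low, high = proportion_ci(x, n, method=method, level=level)
    return MetricEstimate(
        name=name, numerator=x, denominator=n, point=x / n,
        ci_low=low, ci_high=high, method=method, level=level,
    )


def sens_spec_accuracy(
    table: TwoByTwo, method: str = "clopper_pearson", level: float = 0.95
) -> dict[str, MetricEstimate]:
    """Sensitivity, specificity and accuracy with binomial CIs.

    A zero denominator (e.g. no benign masses in a stage-restricted
    subset) yields an estimate flagged ``defined=False`` rather than a
    propagated NaN surprise downstream.
    """
    return {
        "sensitivity": _estimate("sensitivity", table.tp, table.diseased, method, level),
        "specificity": _estimate("specificity", table.tn, table.non_diseased, method, level),
        "accuracy": _estimate("accuracy", table.tp + table.tn, table.n, method, level),
    }


def confusion_table(
    predictions: pd.DataFrame,
    cohort: Cohort,
    strategy: str,
    subset: Callable[[PatientRecord], bool] | None = None,
) -> TwoByTwo:
    """Cross-tabulate one strategy's evaluable calls against histology.

    ``subset`` restricts the analysed records (e.g. inconclusive-IOTA
    stratum, one hospital type); non-evaluable rows are excluded, so
    ``n`` equals the evaluable analysed count.
    """
    by_id = cohort.by_id()
    rows = predictions[(predictions["strategy"] == strategy) & predictions["evaluable"]]
    tp = fp = fn = tn = 0
    for pid, call in zip(rows["patient_id"], rows["call"]):
        record = by_id.get(pid)
        if record is None:
            raise PredictionIntegrityError(f"prediction for unknown patient_id {pid!r}")
        if subset is not None and not subset(record):
            continue
        high = call == "high"
        if record.truth_malignant:
            tp += high
            fn += not high
        else:
            fp += high
            tn += not high
    return TwoByTwo(tp=tp, fp=fp, fn=fn, tn=tn)


def mcnemar_paired(
    correct_a: Sequence[bool] | np.ndarray,
    correct_b: Sequence[bool] | np.ndarray,
    metric: str = "accuracy",
    subset: str = "all",
) -> PairedComparison:
    """McNemar test from aligned per-record correctness indicators."""
    a = np.asarray(correct_a, dtype=bool)
    bb = np.asarray(correct_b, dtype=bool)
    if a.shape != bb.shape:
        raise PredictionIntegrityError(
            f"correctness vectors misaligned: {a.shape} vs {bb.shape}"
        )
    b = int(np.sum(a & ~bb))
    c = int(np.sum(~a & bb))
    nd = b + c
    if nd == 0:
        statistic, p_exact, p_cc = 0.0, 1.0, 1.0
    else:
        statistic = (abs(b - c) - 1) ** 2 / nd
        p_cc = float(stats.chi2.sf(statistic, df=1))
        p_exact = float(min(1.0, 2.0 * stats.binom.cdf(min(b, c), nd, 0.5)))
    return PairedComparison(
        metric=metric, subset=subset, b=b, c=c,
        statistic=statistic, p_exact=p_exact, p_cc=p_cc, n=int(a.size),
    )


@dataclass(frozen=True)
class StrategyComparison:
    strategy_a: str
    strategy_b: str
    subset: str
    n_common: int
    comparisons: dict[str, PairedComparison]
    estimates_a: dict[str, MetricEstimate]
    estimates_b: dict[str, MetricEstimate]


def _correctness(call: str, truth_malignant: bool) -> bool:
    return (call == "high") == truth_malignant


def compare_strategies(
    cohort: Cohort,
    predictions: pd.DataFrame,
    strategy_a: str,
    strategy_b: str,
    subset: Callable[[PatientRecord], bool] | None = None,
    subset_name: str = "all",
    method: str = "clopper_pearson",
    level: float = 0.95,
) -> StrategyComparison:
    """Paired comparison of two strategies on their common evaluable records.

    Sensitivity is compared on the histology-malignant records, specificity
    on the benign, accuracy on all; the same record subset feeds both
    strategies (intersection of evaluable records).
    """
    by_id = cohort.by_id()

    def calls_for(strategy: str) -> dict[str, str]:
        rows = predictions[(predictions["strategy"] == strategy) & predictions["evaluable"]]
        return dict(zip(rows["patient_id"], rows["call"]))

    calls_a, calls_b = calls_for(strategy_a), calls_for(strategy_b)
    common = [
        by_id[pid]
        for pid in calls_a
        if pid in calls_b and pid in by_id and (subset is None or subset(by_id[pid]))
    ]

    def table_for(calls: dict[str, str]) -> TwoByTwo:
        tp = fp = fn = tn = 0
        for r in common:
            high = calls[r.patient_id] == "high"
            if r.truth_malignant:
                tp += high
                fn += not high
            else:
                fp += high
                tn += not high
        return TwoByTwo(tp, fp, fn, tn)

    comparisons: dict[str, PairedComparison] = {}
    for metric in METRIC_NAMES:
        if metric == "sensitivity":
            records = [r for r in common if r.truth_malignant]
        elif metric == "specificity":
            records = [r for r in common if not r.truth_malignant]
        else:
            records = common
        ca = [_correctness(calls_a[r.patient_id], r.truth_malignant) for r in records]
        cb = [_correctness(calls_b[r.patient_id], r.truth_malignant) for r in records]
        comparisons[metric] = mcnemar_paired(ca, cb, metric=metric, subset=subset_name)

    return StrategyComparison(
        strategy_a=strategy_a,
        strategy_b=strategy_b,
        subset=subset_name,
        n_common=len(common),
        comparisons=comparisons,
        estimates_a=sens_spec_accuracy(table_for(calls_a), method, level),
        estimates_b=sens_spec_accuracy(table_for(calls_b), method, level),
    )


# ---------------------------------------------------------------------------
# Subgroup analyses

GROUPINGS = ("menopause", "site", "figo_stage", "histology_class", "iota_conclusiveness")


def _group_key(record: PatientRecord, grouping: str, iota_calls: dict[str, str]) -> str | None:
    if grouping == "menopause":
        return record.menopausal
    if grouping == "site":
        return record.site
    if grouping == "figo_stage":
        return record.figo_stage  # None for benign / unstaged-absent records
    if grouping == "histology_class":
        return record.histology
    if grouping == "iota_conclusiveness":
        call = iota_calls.get(record.patient_id)
        return "inconclusive" if call == "inconclusive" else "conclusive"
    raise ValueError(f"grouping must be one of {GROUPINGS}")


def subgroup_analysis(
    cohort: Cohort,
    predictions: pd.DataFrame,
    grouping: str,
    strategies: Iterable[str] | None = None,
    method: str = "clopper_pearson",
    level: float = 0.95,
) -> dict[str, pd.DataFrame]:
    """Per-group metric tables, one row per strategy.

    Groups with no analysable records are omitted.  Single-class groups
    (e.g. a FIGO-stage group, which contains no benign masses) simply
    yield rows whose specificity is flagged undefined, mirroring the
    sensitivity-only structure of stage-restricted tables.
    """
    from .strategies import STRATEGIES  # local import to avoid cycle

    strategies = list(strategies) if strategies is not None else list(STRATEGIES)
    iota_rows = predictions[predictions["strategy"] == predictions["strategy"].iloc[0]] if len(predictions) else predictions
    iota_calls = dict(zip(iota_rows["patient_id"], iota_rows["iota_call"]))

    levels: list[str] = []
    for record in cohort:
        key = _group_key(record, grouping, iota_calls)
        if key is not None and key not in levels:
            levels.append(key)

    out: dict[str, pd.DataFrame] = {}
    for level_name in sorted(levels):
        def in_group(r: PatientRecord, _lv=level_name) -> bool:
            return _group_key(r, grouping, iota_calls) == _lv

        rows = []
        for strategy in strategies:
            table = confusion_table(predictions, cohort, strategy, subset=in_group)
            if table.n == 0:
                continue
            est = sens_spec_accuracy(table, method=method, level=level)
            row: dict = {"strategy": strategy, "n": table.n, "tp": table.tp,
                         "fp": table.fp, "fn": table.fn, "tn": table.tn}
            for name, e in est.items():
                row[name] = e.point
                row[f"{name}_low"] = e.ci_low
                row[f"{name}_high"] = e.ci_high
                row[f"{name}_defined"] = e.defined
            rows.append(row)
        if rows:
            out[level_name] = pd.DataFrame(rows)
    return out
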