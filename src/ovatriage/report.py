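"""End-to-end pipeline: cohort in, report tables out.

``run_pipeline`` takes a cohort (from a CSV file or freshly generated),
runs every triage strategy, and emits the study-style report tables:

* ``inconclusive``  - expert ultrasound, ROMA and RMI on the
  inconclusive-IOTA stratum;
* ``conclusive``    - IOTA, ROMA and RMI on the conclusive stratum;
* ``overall``       - the five combined strategies on women with ovarian
  pathology;
* ``menopause`` / ``site``          - subgroup tables;
* ``stage_I``       - sensitivity for stage-I cancers (no benign masses
  in the group, so only sensitivity is defined);
* ``histology``     - per-histology-class sensitivity rows.

Every table is written both as CSV (full precision) and as aligned text
with percentages rounded half-up to one decimal and "(low-high)" 95% CI
formatting; rounding is display-only.  A JSON manifest accounts for every
input record and every per-strategy exclusion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .cohort import Cohort, read_cohort
from .metrics import subgroup_analysis
from .scores import Thresholds
from .strategies import STRATEGIES, run_all_strategies
from .synth import GeneratorParams, generate_cohort, params_digest


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """Exactly one of ``input_path`` / ``generator`` must be set."""

    input_path: str | None = None
    generator: GeneratorParams | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    ci_method: str = "clopper_pearson"
    subgroups: tuple[str, ...] = ("menopause", "site", "figo_stage", "histology_class")
    output_dir: str | None = None
    strict: bool = True

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise ConfigError("exactly one of input_path / generator must be given")


@dataclass
class ReportBundle:
    tables: dict[str, pd.DataFrame]
    manifest: dict

    def table_names(self) -> list[str]:
        return list(self.tables)


def format_pct(value: float, decimals: int = 1) -> str:
    """Percentage rounded half-up, e.g. 0.80672 -> '80.7%'."""
    q = Decimal(str(value * 100)).quantize(Decimal(f"1.{'0' * decimals}"), rounding=ROUND_HALF_UP)
    return f"{q}%"


def format_estimate(point: float, low: float, high: float) -> str:
    return f"{format_pct(point)} ({format_pct(low)[:-1]}–{format_pct(high)})"


def render_table(table: pd.DataFrame, style: str = "text") -> str:
    """Serialize a metrics table as CSV or paper-style aligned text."""
    if style == "csv":
        return table.to_csv(index=False)
    if style != "text":
        raise ValueError("style must be 'csv' or 'text'")
    metric_cols = [m for m in ("sensitivity", "specificity", "accuracy") if m in table.columns]
    header = ["strategy", "n"] + [f"{m} (95% CI)" for m in metric_cols]
    lines = []
    for _, row in table.iterrows():
        cells = [str(row["strategy"]), str(int(row["n"]))]
        for m in metric_cols:
            if f"{m}_defined" in table.columns and not row[f"{m}_defined"]:
                cells.append("-")
            else:
                cells.append(format_estimate(row[m], row[f"{m}_low"], row[f"{m}_high"]))
        lines.append(cells)
    widths = [max(len(header[j]), *(len(r[j]) for r in lines)) if lines else len(header[j])
              for j in range(len(header))]
    out = ["  ".join(h.ljust(w) for h, w in zip(header, widths))]
    for cells in lines:
        out.append("  ".join(c.ljust(w) for c, w in zip(cells, widths)))
    return "\n".join(out) + "\n"


def _metrics_frame(cohort: Cohort, predictions: pd.DataFrame, strategies, subset, ci_method) -> pd.DataFrame:
    from .metrics import confusion_table, sens_spec_accuracy

    rows = []
    for strategy in strategies:
        table = confusion_table(predictions, cohort, strategy, subset=subset)
        if table.n == 0:
            continue
        est = sens_spec_accuracy(table, method=ci_method)
        row: dict = {"strategy": strategy, "n": table.n, "tp": table.tp, "fp": table.fp,
                     "fn": table.fn, "tn": table.tn}
        for name, e in est.items():
            row[name] = e.point
            row[f"{name}_low"] = e.ci_low
            row[f"{name}_high"] = e.ci_high
            row[f"{name}_defined"] = e.defined
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the full analysis; write tables/manifest if an output dir is set."""
    if config.input_path is not None:
        cohort = read_cohort(config.input_path, strict=config.strict)
        source = {"input_path": str(config.input_path), "dropped": len(cohort.read_log)}
    else:
        assert config.generator is not None
        cohort = generate_cohort(config.generator)
        source = {"generator_digest": params_digest(config.generator), "seed": config.generator.seed}

    predictions = run_all_strategies(cohort, config.thresholds)
    iota_rows = predictions[predictions["strategy"] == "IOTA_ONLY"]
    inconclusive_ids = set(iota_rows.loc[iota_rows["iota_call"] == "inconclusive", "patient_id"])

    def inconclusive(r) -> bool:
        return r.patient_id in inconclusive_ids

    def conclusive(r) -> bool:
        return r.patient_id not in inconclusive_ids

    def ovarian(r) -> bool:
        return r.ovarian

    tables: dict[str, pd.DataFrame] = {}
    tables["inconclusive"] = _metrics_frame(
        cohort, predictions, ("IOTA_EXPERT", "ROMA_ALONE", "RMI_ALONE"), inconclusive, config.ci_method
    )
    tables["conclusive"] = _metrics_frame(
        cohort, predictions, ("IOTA_ONLY", "ROMA_ALONE", "RMI_ALONE"), conclusive, config.ci_method
    )
    five = ("IOTA_EXPERT", "IOTA_ROMA", "IOTA_RMI", "ROMA_ALONE", "RMI_ALONE")
    tables["overall"] = _metrics_frame(cohort, predictions, five, ovarian, config.ci_method)

    for grouping in config.subgroups:
        groups = subgroup_analysis(cohort, predictions, grouping, strategies=five, method=config.ci_method)
        for level_name, frame in groups.items():
            tables[f"{grouping}_{level_name}"] = frame
    # stage-I sensitivity table under its study-style name
    if "figo_stage_I" in tables:
        tables["stage_I"] = tables.pop("figo_stage_I")

    evaluable_counts = (
        predictions.groupby("strategy", sort=False)["evaluable"].sum().astype(int).to_dict()
    )
    exclusions = (
        predictions.loc[~predictions["evaluable"]]
        .groupby(["strategy", "reason"])  # type: ignore[list-item]
        .size()
        .reset_index(name="count")
        .to_dict(orient="records")
    )
    manifest = {
        "source": source,
        "n_records": len(cohort),
        "n_inconclusive_iota": len(inconclusive_ids),
        "thresholds": {
            "roma_pre": config.thresholds.roma_pre,
            "roma_post": config.thresholds.roma_post,
            "rmi_cut": config.thresholds.rmi_cut,
        },
        "ci_method": config.ci_method,
        "evaluable_per_strategy": {s: evaluable_counts.get(s, 0) for s in STRATEGIES},
        "exclusions": exclusions,
        "tables": list(tables),
    }

    bundle = ReportBundle(tables=tables, manifest=manifest)
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in tables.items():
            frame.to_csv(out / f"{name}.csv", index=False)
            (out / f"{name}.txt").write_text(render_table(frame, style="text"))
        predictions.to_csv(out / "predictions.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return bundle
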