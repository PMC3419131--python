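"""End-to-end reporting: group comparisons, correlations, diagnostic accuracy.

:func:`run_pipeline` takes a cohort (records or CSV), drops records flagged
non-diagnostic, and emits the study-style tables:

* ``per_patient`` — the analysis table after exclusions;
* ``group_comparison`` — per metric, mean ± SD per group with the two-group
  p-value (Student t);
* ``correlations`` — Pearson r and p of every metric against mPAP and PVR;
* ``diagnostics`` — one row per threshold rule: counts, sensitivity,
  specificity, PPV, NPV, binary AUC, continuous ROC AUC, Fisher exact p;
* ``denominators`` — per-analysis n (records missing a metric are dropped
  from that metric's row only, mirroring sub-study coverage).

Rounding (integer percents half-up, AUC/r to 2 dp) is applied only here, at
the reporting layer; everything upstream keeps full precision. Outputs are
deterministic functions of the inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .io import cohort_to_dataframe, read_rules
from .stats import (
    AgreementResult,
    Direction,
    Group,
    PatientRecord,
    ThresholdRule,
    bland_altman,
    confusion_counts,
    confusion_metrics,
    group_compare,
    pearson_r,
    roc_auc,
    rounded_accuracy_row,
)
from .units import round_half_up


def default_rules() -> list[ThresholdRule]:
    """The packaged screening rule set (see data/rules_default.yaml)."""
    with resources.as_file(resources.files("rhcmr.data") / "rules_default.yaml") as p:
        return read_rules(p)


@dataclass
class AnalysisConfig:
    """Pipeline configuration; round-trips losslessly through YAML."""

    rules: list[ThresholdRule] = field(default_factory=default_rules)
    round_percents: bool = True
    seed: int = 0

    def to_yaml(self, path) -> None:
        doc = {
            "round_percents": self.round_percents,
            "seed": self.seed,
            "rules": [
                {"metric": r.metric_name, "cutpoint": r.cutpoint, "direction": r.direction.value}
                for r in self.rules
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            rules=read_rules(path),
            round_percents=bool(doc.get("round_percents", True)),
            seed=int(doc.get("seed", 0)),
        )


@dataclass
class ReportBundle:
    per_patient: pd.DataFrame
    group_comparison: pd.DataFrame
    correlations: pd.DataFrame
    diagnostics: pd.DataFrame
    denominators: dict[str, int]
    summary_markdown: str


def _metric_series(records: list[PatientRecord], name: str) -> tuple[np.ndarray, np.ndarray]:
    """(values, is_PH labels) over records carrying the metric."""
    vals, labels = [], []
    for r in records:
        if name == "lge":
            if r.lge_present is None:
                continue
            vals.append(1.0 if r.lge_present else 0.0)
        else:
            v = r.metrics.get(name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            vals.append(float(v))
        labels.append(r.group is Group.PH)
    return np.asarray(vals), np.asarray(labels, dtype=bool)


def analysis_cohort(records: list[PatientRecord]) -> list[PatientRecord]:
    """Drop records flagged non-diagnostic (the study-profile exclusion)."""
    return [r for r in records if not r.non_diagnostic]


def group_comparison_table(records: list[PatientRecord]) -> pd.DataFrame:
    metric_names = sorted({m for r in records for m in r.metrics})
    rows = []
    for name in metric_names:
        vals, labels = _metric_series(records, name)
        no_ph = vals[~labels]
        ph = vals[labels]
        if len(no_ph) < 2 or len(ph) < 2:
            continue
        cmp = group_compare(vals, np.where(labels, "PH", "NO_PH"))
        rows.append(
            {
                "metric": name,
                "n": len(vals),
                "no_ph_mean": no_ph.mean(),
                "no_ph_sd": no_ph.std(ddof=1),
                "ph_mean": ph.mean(),
                "ph_sd": ph.std(ddof=1),
                "t_statistic": cmp.statistic,
                "p_value": cmp.p_value,
            }
        )
    return pd.DataFrame(rows)


def correlation_table(records: list[PatientRecord]) -> pd.DataFrame:
    metric_names = sorted({m for r in records for m in r.metrics})
    rows = []
    for name in metric_names:
        row: dict[str, object] = {"metric": name}
        for target in ("mpap", "pvr"):
            pairs = []
            for r in records:
                v = r.metrics.get(name)
                t = r.mpap if target == "mpap" else r.pvr
                if v is None or t is None or math.isnan(v) or math.isnan(t):
                    continue
                pairs.append((v, t))
            if len(pairs) >= 3:
                x, y = zip(*pairs)
                r_val, p_val = pearson_r(x, y)
                row[f"{target}_r"] = round_half_up(r_val, 2)
                row[f"{target}_p"] = p_val
                row[f"{target}_n"] = len(pairs)
            else:
                row[f"{target}_r"] = math.nan
                row[f"{target}_p"] = math.nan
                row[f"{target}_n"] = len(pairs)
        rows.append(row)
    return pd.DataFrame(rows)


def diagnostic_table(
    records: list[PatientRecord],
    rules: list[ThresholdRule],
    include_lge: bool = True,
    round_percents: bool = True,
) -> pd.DataFrame:
    rows = []
    for rule in rules:
        tp, fp, fn, tn = confusion_counts(rule, records)
        if tp + fn == 0 or fp + tn == 0:
            continue
        result = confusion_metrics(tp, fp, fn, tn)
        vals, labels = _metric_series(records, rule.metric_name)
        continuous_auc = roc_auc(vals, labels, rule.direction)
        row = {
            "metric": rule.metric_name,
            "cutpoint": rule.cutpoint,
            "direction": rule.direction.value,
            "tp": tp, "fp": fp, "fn": fn, "tn": tn, "n": result.n,
            "roc_auc": round_half_up(continuous_auc, 2),
        }
        row.update(
            rounded_accuracy_row(result)
            if round_percents
            else {
                "sensitivity": result.sensitivity,
                "specificity": result.specificity,
                "ppv": result.ppv,
                "npv": result.npv,
                "auc": result.auc,
                "fisher_p": result.fisher_p,
            }
        )
        rows.append(row)
    if include_lge:
        tp = fp = fn = tn = 0
        for r in records:
            if r.lge_present is None:
                continue
            if r.lge_present and r.group is Group.PH:
                tp += 1
            elif r.lge_present:
                fp += 1
            elif r.group is Group.PH:
                fn += 1
            else:
                tn += 1
        if tp + fn > 0 and fp + tn > 0:
            result = confusion_metrics(tp, fp, fn, tn)
            row = {
                "metric": "lge", "cutpoint": math.nan, "direction": "GE_POSITIVE",
                "tp": tp, "fp": fp, "fn": fn, "tn": tn, "n": result.n,
                "roc_auc": round_half_up(result.auc, 2),
            }
            row.update(rounded_accuracy_row(result) if round_percents else {})
            rows.append(row)
    return pd.DataFrame(rows)


def agreement_report(obs1, obs2) -> AgreementResult:
    """Bland–Altman inter-observer agreement (thin pass-through)."""
    return bland_altman(obs1, obs2)


def _summary_markdown(bundle_parts: dict, denominators: dict[str, int]) -> str:
    lines = ["# Right-heart CMR analysis summary", ""]
    lines.append("## Denominators")
    for k, v in denominators.items():
        lines.append(f"- {k}: {v}")
    lines.append("")
    lines.append("## Diagnostic accuracy")
    diag = bundle_parts["diagnostics"]
    for _, row in diag.iterrows():
        lines.append(
            f"- {row['metric']}: sens {row['sensitivity']:.0f}%, spec {row['specificity']:.0f}%, "
            f"PPV {row['ppv']:.0f}%, NPV {row['npv']:.0f}%, AUC {row['auc']:.2f} (n={row['n']})"
        )
    lines.append("")
    return "\n".join(lines) + "\n"


def run_pipeline(records: list[PatientRecord], config: AnalysisConfig | None = None) -> ReportBundle:
    """Compute every report table from a cohort of patient records."""
    if not records:
        raise ValidationError("cohort is empty")
    config = config or AnalysisConfig()
    analysis = analysis_cohort(records)
    if not analysis:
        raise ValidationError("no diagnostic-quality records remain after exclusions")
    n_ph = sum(1 for r in analysis if r.group is Group.PH)
    denominators = {
        "input_records": len(records),
        "excluded_non_diagnostic": len(records) - len(analysis),
        "analysis_n": len(analysis),
        "ph_n": n_ph,
        "no_ph_n": len(analysis) - n_ph,
        "lge_n": sum(1 for r in analysis if r.lge_present is not None),
        "phase_contrast_n": sum(1 for r in analysis if "pa_average_velocity" in r.metrics),
        "echo_n": sum(1 for r in analysis if "echo_mpap" in r.metrics),
    }
    diagnostics = diagnostic_table(analysis, config.rules, round_percents=config.round_percents)
    parts = {
        "per_patient": cohort_to_dataframe(analysis),
        "group_comparison": group_comparison_table(analysis),
        "correlations": correlation_table(analysis),
        "diagnostics": diagnostics,
    }
    return ReportBundle(
        per_patient=parts["per_patient"],
        group_comparison=parts["group_comparison"],
        correlations=parts["correlations"],
        diagnostics=diagnostics,
        denominators=denominators,
        summary_markdown=_summary_markdown(parts, denominators),
    )


def write_report_bundle(bundle: ReportBundle, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle.per_patient.to_csv(out_dir / "per_patient.csv", index=False, lineterminator="\n")
    bundle.group_comparison.to_csv(out_dir / "group_comparison.csv", index=False, lineterminator="\n")
    bundle.correlations.to_csv(out_dir / "correlations.csv", index=False, lineterminator="\n")
    bundle.diagnostics.to_csv(out_dir / "diagnostics.csv", index=False, lineterminator="\n")
    (out_dir / "summary.md").write_text(bundle.summary_markdown)
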