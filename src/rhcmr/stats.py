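"""Threshold-based diagnostic accuracy, ROC analysis, correlations, group
comparisons and inter-observer agreement.

The disease label throughout is pulmonary hypertension at right heart
catheterisation, mPAP >= 25 mmHg. Threshold rules carry an explicit
direction — GE_POSITIVE ("VMI >= 0.4 is test-positive") or LE_POSITIVE
("TAPSE <= 2 cm is test-positive") — and the same direction drives ROC
orientation; directions are declared per metric, never inferred from data.

Records missing a metric are dropped from that metric's analysis only, which
reproduces per-metric denominators when sub-studies (phase contrast, late
gadolinium enhancement, echo) cover subsets of the cohort.

Internal values keep full precision; table-style rounding (integer percents
half-up, AUC to 2 dp, r to 2 dp) belongs to the reporting layer.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .units import round_half_up

PH_MPAP_THRESHOLD_MMHG = 25.0


class Group(str, enum.Enum):
    NO_PH = "NO_PH"
    PH = "PH"


class Subgroup(str, enum.Enum):
    IPAH = "IPAH"
    PAH_CTD = "PAH_CTD"
    PAH_OTHER = "PAH_OTHER"
    PH_LHD = "PH_LHD"
    PH_RESP = "PH_RESP"
    CTEPH = "CTEPH"
    NONE = "NONE"


class Direction(str, enum.Enum):
    GE_POSITIVE = "GE_POSITIVE"  # value >= cutpoint is test-positive
    LE_POSITIVE = "LE_POSITIVE"  # value <= cutpoint is test-positive


@dataclass
class PatientRecord:
    """One analysis-table row: haemodynamics plus every imaging metric."""

    patient_id: str
    group: Group
    mpap: float
    subgroup: Subgroup = Subgroup.NONE
    pvr: float | None = None
    bsa: float | None = None
    metrics: dict[str, float] = field(default_factory=dict)
    lge_present: bool | None = None
    non_diagnostic: bool = False

    def __post_init__(self) -> None:
        expected = Group.PH if self.mpap >= PH_MPAP_THRESHOLD_MMHG else Group.NO_PH
        if self.group != expected:
            raise ValueError(
                f"patient {self.patient_id!r}: group {self.group.value} inconsistent "
                f"with mpap {self.mpap} (PH iff mpap >= {PH_MPAP_THRESHOLD_MMHG})"
            )


@dataclass(frozen=True)
class ThresholdRule:
    """A screening rule: metric, cutpoint and which side is test-positive."""

    metric_name: str
    cutpoint: float
    direction: Direction


@dataclass
class DiagnosticResult:
    """2×2 counts and the accuracy summary for one threshold rule."""

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float  # percent
    specificity: float  # percent
    ppv: float  # percent (NaN if no test-positives)
    npv: float  # percent (NaN if no test-negatives)
    auc: float  # [0, 1]
    fisher_p: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class AgreementResult:
    """Bland–Altman summary of paired observer differences (obs1 − obs2)."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


def classify(rule: ThresholdRule, record: PatientRecord) -> bool | None:
    """Apply one threshold rule to one record.

    Returns True/False for test-positive/negative, or None when the metric is
    absent so the record is excluded from that rule's analysis (not an
    error). Cutpoints are inclusive on the positive side.
    """
    value = record.metrics.get(rule.metric_name)
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if rule.direction is Direction.GE_POSITIVE:
        return value >= rule.cutpoint
    return value <= rule.cutpoint


def confusion_counts(
    rule: ThresholdRule, records: Iterable[PatientRecord]
) -> tuple[int, int, int, int]:
    """(tp, fp, fn, tn) of a rule over a cohort, skipping missing metrics."""
    tp = fp = fn = tn = 0
    for rec in records:
        result = classify(rule, rec)
        if result is None:
            continue
        diseased = rec.group is Group.PH
        if result and diseased:
            tp += 1
        elif result and not diseased:
            fp += 1
        elif not result and diseased:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> DiagnosticResult:
    """Sensitivity/specificity/PPV/NPV (percent), binary AUC and Fisher p.

    Requires at least one diseased (tp+fn) and one non-diseased (fp+tn)
    subject. PPV/NPV are NaN when their denominator is zero.
    """
    if tp + fn == 0 or fp + tn == 0:
        raise ValueError("need both diseased (tp+fn) and non-diseased (fp+tn) subjects")
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (fp + tn)
    ppv = 100.0 * tp / (tp + fp) if tp + fp > 0 else math.nan
    npv = 100.0 * tn / (tn + fn) if tn + fn > 0 else math.nan
    return DiagnosticResult(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        auc=binary_test_auc(tp, fp, fn, tn),
        fisher_p=fisher_exact_p(tp, fp, fn, tn),
    )


def fisher_exact_p(tp: int, fp: int, fn: int, tn: int) -> float:
    """Two-sided Fisher exact p for the 2×2 table [[tp, fp], [fn, tn]].

    Two-sided by summing hypergeometric probabilities of all tables (with the
    observed margins) at most as probable as the observed one; degenerate
    margins give p = 1.
    """
    for c in (tp, fp, fn, tn):
        if c < 0:
            raise ValueError("counts must be non-negative")
    _, p = sps.fisher_exact([[tp, fp], [fn, tn]], alternative="two-sided")
    return float(min(p, 1.0))


def roc_auc(values: Sequence[float], labels: Sequence[bool], direction: Direction) -> float:
    """Rank-based (Mann–Whitney) area under the ROC curve with midrank ties.

    ``labels`` marks diseased subjects True. ``direction`` states which end of
    the metric indicates disease: GE_POSITIVE means higher values are
    test-positive, LE_POSITIVE flips the orientation.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("values and labels must be equal-length 1-D sequences")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    if direction is Direction.LE_POSITIVE:
        x = -x
    ranks = sps.rankdata(x)  # midranks
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return float(auc)


def binary_test_auc(tp: int, fp: int, fn: int, tn: int) -> float:
    """AUC of a binary marker: (sensitivity + specificity)/2 on [0, 1].

    Equals the trapezoidal area of the two-point ROC through (1−spec, sens),
    and coincides with the midrank Mann–Whitney AUC of the 0/1 marker.
    """
    if tp + fn == 0 or fp + tn == 0:
        raise ValueError("need both diseased and non-diseased subjects")
    sens = tp / (tp + fn)
    spec = tn / (fp + tn)
    return (sens + spec) / 2.0


def ppv_from_sens_spec(
    sensitivity_pct: float, specificity_pct: float, n_pos: int, n_neg: int
) -> float:
    """Positive predictive value (percent) implied by sens/spec at a prevalence.

    Bayes: PPV = s·p / (s·p + (1−c)·(1−p)) with p = n_pos/(n_pos+n_neg); used
    to reconstruct PPVs from published sensitivity/specificity and group
    sizes.
    """
    s = sensitivity_pct / 100.0
    c = specificity_pct / 100.0
    p = n_pos / (n_pos + n_neg)
    denom = s * p + (1.0 - c) * (1.0 - p)
    return 100.0 * s * p / denom if denom > 0 else math.nan


def evaluate_rule(rule: ThresholdRule, records: Iterable[PatientRecord]) -> DiagnosticResult:
    """Confusion counts + accuracy summary of one rule over a cohort."""
    tp, fp, fn, tn = confusion_counts(rule, records)
    return confusion_metrics(tp, fp, fn, tn)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with the t-distribution p (n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class GroupComparison:
    """Result of a two-group or multi-group comparison."""

    test: str  # "t", "chi2", "anova"
    statistic: float
    p_value: float
    pairwise: dict[tuple[str, str], float] | None = None  # Bonferroni-adjusted p


def group_compare(
    values: Sequence[float] | Sequence[str],
    groups: Sequence[str],
    categorical: bool = False,
    equal_var: bool = True,
) -> GroupComparison:
    """Compare a variable across patient groups.

    Two groups, continuous: independent-samples t-test (Student pooled
    variance by default; ``equal_var=False`` selects Welch). Categorical:
    chi-square on the contingency table. More than two groups: one-way ANOVA
    plus pairwise t-tests with Bonferroni adjustment (factor = number of
    pairwise comparisons, capped at 1).
    """
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    if categorical:
        cats = sorted(set(values))
        table = np.array(
            [[sum(1 for v, g in zip(values, groups) if g == lab and v == c) for c in cats]
             for lab in labels]
        )
        chi2, p, _, _ = sps.chi2_contingency(table)
        return GroupComparison(test="chi2", statistic=float(chi2), p_value=float(p))
    vals = np.asarray(values, dtype=float)
    by_group = {lab: vals[groups == lab] for lab in labels}
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if len(labels) == 2:
        a, b = (by_group[lab] for lab in labels)
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
        return GroupComparison(test="t", statistic=float(t), p_value=float(p))
    f, p = sps.f_oneway(*(by_group[lab] for lab in labels))
    n_pairs = len(labels) * (len(labels) - 1) // 2
    pairwise: dict[tuple[str, str], float] = {}
    for la, lb in itertools.combinations(labels, 2):
        _, pp = sps.ttest_ind(by_group[la], by_group[lb], equal_var=equal_var)
        pairwise[(la, lb)] = float(min(1.0, pp * n_pairs))
    return GroupComparison(test="anova", statistic=float(f), p_value=float(p), pairwise=pairwise)


def bland_altman(obs1: Sequence[float], obs2: Sequence[float]) -> AgreementResult:
    """Bland–Altman agreement of paired measurements.

    Differences are obs1 − obs2; bias is their mean, sd_diff the sample SD
    (ddof = 1), and the 95% limits of agreement are bias ± 1.96·sd_diff.
    """
    a = np.asarray(obs1, dtype=float)
    b = np.asarray(obs2, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need equal-length paired samples with n >= 2")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=int(a.size),
    )


def rounded_accuracy_row(result: DiagnosticResult) -> dict[str, float]:
    """Table-style presentation: integer percents (half-up), AUC to 2 dp."""
    return {
        "sensitivity": round_half_up(result.sensitivity),
        "specificity": round_half_up(result.specificity),
        "ppv": round_half_up(result.ppv) if not math.isnan(result.ppv) else math.nan,
        "npv": round_half_up(result.npv) if not math.isnan(result.npv) else math.nan,
        "auc": round_half_up(result.auc, 2),
        "fisher_p": result.fisher_p,
    }
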