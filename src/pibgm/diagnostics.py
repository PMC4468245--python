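"""Cohort-level diagnostics: DANP cutoffs, classification, t-tests, ROC.

The decision rule is one-sided on a scalar biomarker (per-patient mean SUV
or a PIBGM value): a patient is called abnormal when the biomarker strictly
exceeds a cutoff.  Cutoffs are set by the DANP rule -- the Discriminative
Ability for the Normal Person, i.e. the fraction of normal subjects the
cutoff must classify correctly.  With DANP = d and n normal subjects the
cutoff is the ceil(d*n)-th order statistic of the normal biomarker values,
so at least that many normals sit at or below it; with all values distinct
the specificity on the defining set equals ceil(d*n)/n exactly, at every
biomarker (and every SUV-cutoff t) by construction.

The default decision biomarker is the cortex PIBGM at SUV cutoff t = 1.2,
the setting where the sweep peaks; both the region and t are configurable.
Group comparisons use Welch's unequal-variance t-test (two-sided, raw
p-values -- no multiplicity correction is applied across the t grid).
ROC curves are built from all score thresholds and graded qualitatively by
AUC band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .errors import ConfigError
from .phantom import GROUPS

#: Qualitative AUC grading bands (upper-open except the top band).
AUC_GRADES = (
    (0.9, 1.01, "Excellent"),
    (0.8, 0.9, "Good"),
    (0.7, 0.8, "Worthless"),
    (0.6, 0.7, "Not good"),
)


@dataclass
class DiagnosticReport:
    """Confusion counts and derived rates for one cutoff.

    Rates with a zero denominator are reported as ``None`` (absent), never
    as zero.  ``per_etiology`` maps each disease group to its detection rate.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float
    cutoff: float | None = None
    danp: float | None = None
    t: float | None = None
    per_etiology: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def danp_cutoff(normal_values, danp: float) -> float:
    """Biomarker cutoff achieving the requested DANP on the normal subjects.

    cutoff = k-th order statistic with k = ceil(danp * n): at least k normals
    satisfy value <= cutoff and are classified normal under the strict
    'abnormal iff greater' rule.
    """
    values = np.asarray(normal_values, dtype=float)
    if values.size == 0:
        raise ConfigError("danp_cutoff: no normal values given")
    if not 0.0 < danp <= 1.0:
        raise ConfigError("danp must be in (0, 1]")
    k = math.ceil(danp * values.size)
    return float(np.sort(values, kind="stable")[k - 1])


def classify(values, cutoff: float) -> np.ndarray:
    """Boolean abnormal flags: abnormal iff value > cutoff (strict)."""
    if not np.isfinite(cutoff):
        raise ConfigError("cutoff must be finite")
    return np.asarray(values, dtype=float) > cutoff


def _rate(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def confusion_metrics(pred, truth, *, cutoff=None, danp=None, t=None,
                      per_etiology=None) -> DiagnosticReport:
    """Confusion counts and the five rates for binary predictions.

    ``truth`` marks diseased (FUO) as True/1, normal as False/0.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ConfigError(
            f"prediction/truth length mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return DiagnosticReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=_rate(tp, tp + fn),
        specificity=_rate(tn, tn + fp),
        ppv=_rate(tp, tp + fp),
        npv=_rate(tn, tn + fn),
        accuracy=(tp + tn) / max(1, tp + fp + tn + fn),
        cutoff=cutoff, danp=danp, t=t,
        per_etiology=dict(per_etiology or {}),
    )


def welch_ttest(sample_a, sample_b) -> tuple[float, float]:
    """Welch's unequal-variance t-test with Satterthwaite df (two-sided)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ConfigError("welch_ttest needs n >= 2 per sample")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ConfigError("welch_ttest: both samples have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def auc_grade(auc: float) -> str:
    """Qualitative band for an AUC value (bands cover 0.6 and up)."""
    for lo, hi, name in AUC_GRADES:
        if lo <= auc < hi:
            return name
    return "Fail"


@dataclass
class ROCCurve:
    """ROC point set (sorted by FPR), trapezoid AUC, and qualitative grade."""

    points: np.ndarray  # (n, 2) array of (FPR, TPR)
    auc: float
    grade: str


def roc_auc(scores, truth) -> ROCCurve:
    """ROC curve over all score thresholds; AUC by the trapezoid rule.

    The AUC equals the tie-corrected Mann-Whitney concordance probability.
    Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise ConfigError("roc_auc requires both classes in the truth labels")
    fpr, tpr, _ = roc_curve(truth.astype(int), scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(points=np.column_stack([fpr, tpr]), auc=auc,
                    grade=auc_grade(auc))


# ---------------------------------------------------------------------------
# Cohort table and the DANP x t sweep
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Tidy per-patient biomarker table.

    One row per (patient, region, mode, t) with columns
    ``patient_id, group, region, mode, t, value``.  Patient ids are unique
    within each biomarker key; group labels come from the declared set.
    """

    frame: pd.DataFrame

    REQUIRED = ("patient_id", "group", "region", "mode", "t", "value")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ConfigError(f"CohortTable missing columns {missing}")
        bad = set(self.frame["group"]) - set(GROUPS)
        if bad:
            raise ConfigError(f"unknown group labels {sorted(bad)}")
        dup = self.frame.duplicated(subset=["patient_id", "region", "mode", "t"])
        if dup.any():
            raise ConfigError("duplicate (patient, region, mode, t) rows")

    @classmethod
    def from_profiles(cls, records) -> "CohortTable":
        """Build from records of (patient_id, group, region, mode, {t: value})."""
        rows = []
        for patient_id, group, region, mode, profile in records:
            for t, value in profile.items():
                rows.append({"patient_id": patient_id, "group": group,
                             "region": region, "mode": mode,
                             "t": float(t), "value": float(value)})
        return cls(pd.DataFrame(rows))

    @property
    def patients(self) -> pd.DataFrame:
        return (self.frame[["patient_id", "group"]]
                .drop_duplicates().reset_index(drop=True))

    def t_values(self, region: str, mode: str) -> np.ndarray:
        sub = self.frame[(self.frame.region == region) & (self.frame["mode"] == mode)]
        return np.sort(sub["t"].unique())

    def biomarker(self, region: str, mode: str, t: float) -> pd.DataFrame:
        """Per-patient values at one biomarker key, one row per patient."""
        sub = self.frame[
            (self.frame.region == region) & (self.frame["mode"] == mode)
            & np.isclose(self.frame["t"], t)
        ]
        if sub.empty:
            raise ConfigError(f"no biomarker values for ({region}, {mode}, t={t})")
        return sub.reset_index(drop=True)


def danp_sweep(cohort: CohortTable, danp_grid=(0.95,), t_grid=None,
               region: str = "cortex", mode: str = "bw") -> list[DiagnosticReport]:
    """Full DANP x SUV-cutoff sweep of the diagnostic rule.

    For each (danp, t): the cutoff comes from the normal subjects' biomarker
    values at that t, every patient is classified, and a report with the
    five rates plus per-etiology detection rates is produced.  Specificity
    on the defining normals is >= danp by construction of the cutoff.
    """
    t_grid = cohort.t_values(region, mode) if t_grid is None else np.asarray(t_grid, float)
    groups = set(cohort.patients["group"])
    if "normal" not in groups or not (groups - {"normal"}):
        raise ConfigError("danp_sweep needs normal subjects and at least one FUO group")
    reports = []
    for t in t_grid:
        sub = cohort.biomarker(region, mode, t)
        values = sub["value"].to_numpy()
        group = sub["group"].to_numpy()
        normals = values[group == "normal"]
        truth = group != "normal"
        for danp in danp_grid:
            cutoff = danp_cutoff(normals, danp)
            pred = classify(values, cutoff)
            per_et = {g: float(np.mean(pred[group == g]))
                      for g in GROUPS[1:] if (group == g).any()}
            reports.append(confusion_metrics(
                pred, truth, cutoff=cutoff, danp=float(danp), t=float(t),
                per_etiology=per_et))
    return reports


def sweep_frame(reports: list[DiagnosticReport]) -> pd.DataFrame:
    """Tidy DataFrame view of a DANP sweep (one row per danp x t)."""
    rows = []
    for r in reports:
        row = {"danp": r.danp, "t": r.t, "cutoff": r.cutoff,
               "tp": r.tp, "fp": r.fp, "tn": r.tn, "fn": r.fn,
               "sensitivity": r.sensitivity, "specificity": r.specificity,
               "ppv": r.ppv, "npv": r.npv, "accuracy": r.accuracy}
        for g, v in r.per_etiology.items():
            row[f"detect_{g}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
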