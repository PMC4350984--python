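"""Internal validation and stratified-audit quality estimation.

Two layers of evaluation are provided:

* **Internal validation** — seeded train/validation/test partitioning,
  confusion matrices against the recorded intent-flag, accuracy with a
  Wilson 95% CI, and diagnostic metrics (sensitivity, specificity, PPV,
  NPV) with palliation as the target outcome.

* **Manual-audit machinery** — the recorded intent-flag is itself noisy, so
  true error rates are estimated from an audit of a stratified random
  sample of patients (strata: treatment centre, treatment period, and
  whether the classifier agreed with the intent-flag). All treatments of a
  sampled patient are audited. Population quantities are recovered with
  expansion weights w_h = N_h / n_h: every metric is a ratio of
  expansion-weighted counts, with a normal-approximation CI from the
  stratified binomial variance. CIs do not model within-patient clustering
  of records (a known limitation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .records import CURATIVE, PALLIATIVE


class MetricEstimate(NamedTuple):
    value: float
    ci_low: float
    ci_high: float
    n: int  # denominator size (unweighted)


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PartitionSpec:
    """Random train/validation/test partition (default 40/30/30)."""

    fractions: tuple[float, float, float] = (0.40, 0.30, 0.30)
    seed: int = 0

    def __post_init__(self):
        f = np.asarray(self.fractions, dtype=float)
        if len(f) != 3 or np.any(f <= 0) or np.any(f >= 1):
            raise ValueError("fractions must be three values in (0, 1)")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def split_dataset(records: pd.DataFrame, spec: PartitionSpec | None = None):
    """Disjoint, exhaustive, seeded multinomial assignment of rows to
    (train, valid, test); reproducible per seed."""
    if spec is None:
        spec = PartitionSpec()
    rng = np.random.default_rng(spec.seed)
    assignment = rng.choice(3, size=len(records), p=list(spec.fractions))
    return tuple(records[assignment == i] for i in range(3))


# ---------------------------------------------------------------------------
# confusion and diagnostics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts indexed true-class x predicted-class over {C, P}.

    ``rate_c_to_p`` is the share of all records with a curative reference
    classified palliative (and vice versa); accuracy and the two off-rates
    sum to 1 exactly.
    """

    n_cc: int
    n_cp: int
    n_pc: int
    n_pp: int

    def __post_init__(self):
        if min(self.n_cc, self.n_cp, self.n_pc, self.n_pp) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_cc + self.n_cp + self.n_pc + self.n_pp

    @property
    def accuracy(self) -> float:
        return (self.n_cc + self.n_pp) / self.total

    @property
    def rate_c_to_p(self) -> float:
        return self.n_cp / self.total

    @property
    def rate_p_to_c(self) -> float:
        return self.n_pc / self.total

    def accuracy_ci(self, level: float = 0.95) -> tuple[float, float]:
        lo, hi = proportion_confint(self.n_cc + self.n_pp, self.total,
                                    alpha=1 - level, method="wilson")
        return float(lo), float(hi)


def confusion_matrix(predicted, reference) -> ConfusionMatrix:
    """Exact confusion counts of predicted vs reference labels in {C, P}."""
    pred = np.asarray(list(predicted), dtype=object)
    ref = np.asarray(list(reference), dtype=object)
    if len(pred) != len(ref):
        raise ValueError(f"length mismatch: {len(pred)} predictions vs {len(ref)} references")
    valid = {CURATIVE, PALLIATIVE}
    if not set(pred) <= valid or not set(ref) <= valid:
        raise ValueError("labels must be in {C, P}")
    return ConfusionMatrix(
        n_cc=int(np.sum((ref == CURATIVE) & (pred == CURATIVE))),
        n_cp=int(np.sum((ref == CURATIVE) & (pred == PALLIATIVE))),
        n_pc=int(np.sum((ref == PALLIATIVE) & (pred == CURATIVE))),
        n_pp=int(np.sum((ref == PALLIATIVE) & (pred == PALLIATIVE))),
    )


def _wilson(count: int, nobs: int, level: float) -> MetricEstimate | None:
    if nobs == 0:
        return None
    lo, hi = proportion_confint(count, nobs, alpha=1 - level, method="wilson")
    return MetricEstimate(count / nobs, float(lo), float(hi), nobs)


def diagnostic_metrics(cm: ConfusionMatrix, level: float = 0.95) -> dict:
    """Sensitivity/specificity/PPV/NPV with palliation as target outcome.

    Wilson CIs; a metric with a zero denominator is reported as ``None``
    (undefined).
    """
    return {
        "sensitivity": _wilson(cm.n_pp, cm.n_pp + cm.n_pc, level),
        "specificity": _wilson(cm.n_cc, cm.n_cc + cm.n_cp, level),
        "ppv": _wilson(cm.n_pp, cm.n_pp + cm.n_cp, level),
        "npv": _wilson(cm.n_cc, cm.n_cc + cm.n_pc, level),
    }


# ---------------------------------------------------------------------------
# audit strata and sampling
# ---------------------------------------------------------------------------

AGREE = "agree"
DISAGREE = "disagree"
INTENT_MISSING = "intent_missing"


@dataclass(frozen=True)
class AuditDesign:
    """Stratified patient-level audit design.

    ``strata_by`` may contain ``"centre"``, ``"period"`` and
    ``"agreement"``. ``n_per_stratum`` is either an int (same patient count
    everywhere, truncated to the stratum size) or a dict stratum-key ->
    count. ``period_break`` splits the treatment period by the patient's
    first treatment date.
    """

    strata_by: tuple[str, ...] = ("centre", "period", "agreement")
    n_per_stratum: int | dict = 100
    period_break: str = "2005-04-01"
    seed: int = 0


def assign_audit_strata(
    records: pd.DataFrame,
    design: AuditDesign,
    classifier_col: str = "trr_label",
    intent_col: str = "intent_flag",
) -> pd.DataFrame:
    """Return a copy of ``records`` with a patient-level ``audit_stratum``.

    A patient is in the ``disagree`` stratum if any of their records has a
    non-missing intent disagreeing with the classifier, else in
    ``intent_missing`` if any intent is missing, else ``agree``.
    """
    df = records.copy()
    parts = []
    if "centre" in design.strata_by:
        centre = df["centre"].astype(str)
        parts.append(centre.groupby(df["patient_id"]).transform("first"))
    if "period" in design.strata_by:
        first = pd.to_datetime(df["treat_date"]).groupby(df["patient_id"]).transform("min")
        parts.append(
            np.where(first < pd.Timestamp(design.period_break), "pre", "post")
        )
    if "agreement" in design.strata_by:
        intent = df[intent_col]
        disagrees = intent.notna() & (intent != df[classifier_col])
        missing = intent.isna()
        any_disagree = disagrees.groupby(df["patient_id"]).transform("any")
        any_missing = missing.groupby(df["patient_id"]).transform("any")
        parts.append(
            np.where(any_disagree, DISAGREE, np.where(any_missing, INTENT_MISSING, AGREE))
        )
    if not parts:
        raise ValueError("design.strata_by must name at least one stratifier")
    stratum = parts[0] if len(parts) == 1 else pd.Series(
        ["|".join(vals) for vals in zip(*(np.asarray(p, dtype=object) for p in parts))],
        index=df.index,
    )
    df["audit_stratum"] = np.asarray(stratum, dtype=object)
    return df


def stratified_audit_sample(records: pd.DataFrame, design: AuditDesign):
    """Seeded simple random sample of patients within each stratum.

    ``records`` must already carry ``audit_stratum`` (see
    :func:`assign_audit_strata`). Returns ``(sample, design_table)``: the
    sample holds every treatment record of each sampled patient plus an
    expansion ``weight`` column (N_h patients / n_h patients); the design
    table lists per-stratum patient and record totals.
    """
    if "audit_stratum" not in records.columns:
        raise ValueError("records must carry 'audit_stratum'; call assign_audit_strata first")
    rng = np.random.default_rng(design.seed)
    patients = (
        records.groupby("patient_id", sort=True)["audit_stratum"].first().reset_index()
    )
    chosen_frames = []
    rows = []
    for stratum, group in patients.groupby("audit_stratum", sort=True):
        big_n = len(group)
        if isinstance(design.n_per_stratum, dict):
            if stratum not in design.n_per_stratum:
                continue
            small_n = int(design.n_per_stratum[stratum])
        else:
            small_n = min(int(design.n_per_stratum), big_n)
        if small_n > big_n:
            raise ValueError(f"stratum {stratum!r}: requested n={small_n} > N={big_n}")
        if small_n <= 0:
            continue
        ids = np.sort(group["patient_id"].to_numpy())
        take = rng.choice(ids, size=small_n, replace=False)
        sub = records[records["patient_id"].isin(take)].copy()
        sub["weight"] = big_n / small_n
        chosen_frames.append(sub)
        rows.append(
            {
                "audit_stratum": stratum,
                "N_patients": big_n,
                "n_patients": small_n,
                "weight": big_n / small_n,
                "N_records": int((records["audit_stratum"] == stratum).sum()),
            }
        )
    if not chosen_frames:
        raise ValueError("empty audit sample: no stratum received a positive allocation")
    sample = pd.concat(chosen_frames, axis=0)
    design_table = pd.DataFrame(rows)
    return sample, design_table


# ---------------------------------------------------------------------------
# expansion-weighted estimation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AuditEstimate:
    """Expansion-weighted diagnostic metrics from a stratified audit."""

    sensitivity: MetricEstimate | None
    specificity: MetricEstimate | None
    ppv: MetricEstimate | None
    npv: MetricEstimate | None
    pct_correct: MetricEstimate | None
    pct_incorrect: MetricEstimate | None


def _weighted_ratio(num, den, weights, level: float = 0.95) -> MetricEstimate | None:
    """Ratio of expansion-weighted counts with a linearised normal CI.

    ``num``/``den`` are per-stratum counts (numerator events, denominator
    size) and ``weights`` the expansion weights w_h. Within-stratum
    numerators are treated as binomial in the denominator.
    """
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("expansion weights must be positive")
    wden = float(np.sum(w * den))
    if wden == 0:
        return None
    p = float(np.sum(w * num) / wden)
    with np.errstate(divide="ignore", invalid="ignore"):
        ph = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    var = float(np.sum(w**2 * den * ph * (1 - ph)) / wden**2)
    from scipy.stats import norm

    z = float(norm.ppf(1 - (1 - level) / 2))
    half = z * np.sqrt(var)
    return MetricEstimate(p, max(0.0, p - half), min(1.0, p + half), int(den.sum()))


def stratified_estimates(stratum_counts: pd.DataFrame, level: float = 0.95) -> AuditEstimate:
    """Expansion-weighted diagnostics from per-stratum confusion counts.

    ``stratum_counts`` needs columns ``n_cc``, ``n_cp``, ``n_pc``, ``n_pp``
    and ``weight`` (one row per stratum, strata disjoint). Each metric is a
    ratio of expansion-weighted counts, e.g. sensitivity =
    sum_h w_h TP_h / sum_h w_h (TP_h + FN_h). With a single stratum of
    weight 1 the point estimates reduce exactly to the pooled
    :func:`diagnostic_metrics`.
    """
    t = stratum_counts
    w = t["weight"].to_numpy(dtype=float)
    n_cc, n_cp = t["n_cc"].to_numpy(float), t["n_cp"].to_numpy(float)
    n_pc, n_pp = t["n_pc"].to_numpy(float), t["n_pp"].to_numpy(float)
    total = n_cc + n_cp + n_pc + n_pp
    return AuditEstimate(
        sensitivity=_weighted_ratio(n_pp, n_pp + n_pc, w, level),
        specificity=_weighted_ratio(n_cc, n_cc + n_cp, w, level),
        ppv=_weighted_ratio(n_pp, n_pp + n_cp, w, level),
        npv=_weighted_ratio(n_cc, n_cc + n_pc, w, level),
        pct_correct=_weighted_ratio(n_cc + n_pp, total, w, level),
        pct_incorrect=_weighted_ratio(n_cp + n_pc, total, w, level),
    )


def audit_confusion_by_stratum(
    sample: pd.DataFrame,
    truth_col: str,
    pred_col: str,
) -> pd.DataFrame:
    """Per-stratum confusion counts of ``pred_col`` against audited truth.

    Rows with a missing prediction are dropped (they cannot enter a
    confusion matrix); the per-stratum expansion weight is carried through.
    """
    rows = []
    for stratum, group in sample.groupby("audit_stratum", sort=True):
        ok = group[pred_col].notna() & group[truth_col].notna()
        g = group[ok]
        ref, pred = g[truth_col], g[pred_col]
        rows.append(
            {
                "audit_stratum": stratum,
                "weight": float(group["weight"].iloc[0]),
                "n_cc": int(((ref == CURATIVE) & (pred == CURATIVE)).sum()),
                "n_cp": int(((ref == CURATIVE) & (pred == PALLIATIVE)).sum()),
                "n_pc": int(((ref == PALLIATIVE) & (pred == CURATIVE)).sum()),
                "n_pp": int(((ref == PALLIATIVE) & (pred == PALLIATIVE)).sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# population quality report
# ---------------------------------------------------------------------------


def population_quality_report(
    records: pd.DataFrame,
    sample: pd.DataFrame,
    truth_col: str,
    classifier_col: str = "trr_label",
    intent_col: str = "intent_flag",
    assume_unaudited_agreement_correct: bool = False,
    level: float = 0.95,
) -> pd.DataFrame:
    """% correct / % incorrect / % missing for the classifier and the
    intent-flag, projected to the full record set from stratum-specific
    audited error rates.

    ``records`` must carry ``audit_stratum`` (every record assigned);
    ``sample`` is the audited subset with the ``truth_col`` labels. The
    intent-flag's % missing is observed directly on the full record set
    (reported without a CI); % incorrect is estimated from the audit and
    % correct is the remainder, so the three rows sum to 100 exactly.
    Strata without audited records make the estimate unavailable (NaN)
    unless ``assume_unaudited_agreement_correct`` is set and the stratum is
    an all-agree stratum, in which case both classifier and intent are
    taken as correct there — the targeted, disagreement-only audit design.

    Returns a tidy frame: columns ``metric``, ``method``, ``value``,
    ``ci_low``, ``ci_high`` (percentages of all records).
    """
    from scipy.stats import norm

    z = float(norm.ppf(1 - (1 - level) / 2))
    n_total = len(records)
    strata = records.groupby("audit_stratum", sort=True).size().rename("N_records")

    cls_missing_share = float(records[classifier_col].isna().mean())
    intent_missing_share = float(records[intent_col].isna().mean())

    def project(err_fn):
        """Sum_h (N_h/N) * stratum error rate, with stratified variance."""
        estimate = 0.0
        variance = 0.0
        for stratum, big_n in strata.items():
            share = big_n / n_total
            in_sample = sample[sample["audit_stratum"] == stratum]
            if len(in_sample) == 0:
                if assume_unaudited_agreement_correct and str(stratum).split("|")[-1] == AGREE:
                    continue  # error contribution 0
                return np.nan, np.nan
            p = err_fn(in_sample)
            estimate += share * p
            variance += share**2 * p * (1 - p) / len(in_sample)
        return estimate, variance

    def cls_err(g):
        ok = g[classifier_col].notna()
        return float((g[ok][classifier_col] != g[ok][truth_col]).mean()) if ok.any() else 0.0

    def intent_err(g):
        present = g[intent_col].notna()
        return float((present & (g[intent_col] != g[truth_col])).mean())

    cls_inc, cls_var = project(cls_err)
    int_inc, int_var = project(intent_err)

    rows = []

    def add(metric, method, value, var=None):
        half = z * np.sqrt(var) * 100 if var is not None and np.isfinite(var) else np.nan
        rows.append(
            {
                "metric": metric,
                "method": method,
                "value": value * 100 if np.isfinite(value) else np.nan,
                "ci_low": value * 100 - half if np.isfinite(half) else np.nan,
                "ci_high": value * 100 + half if np.isfinite(half) else np.nan,
            }
        )

    add("% correct", "classification_rules", 1.0 - cls_missing_share - cls_inc, cls_var)
    add("% incorrect", "classification_rules", cls_inc, cls_var)
    add("% missing", "classification_rules", cls_missing_share)
    add("% correct", "intent_flag", 1.0 - intent_missing_share - int_inc, int_var)
    add("% incorrect", "intent_flag", int_inc, int_var)
    add("% missing", "intent_flag", intent_missing_share)
    return pd.DataFrame(rows)


def format_quality_report(report: pd.DataFrame) -> str:
    """Aligned plain-text rendering of a population quality report."""
    lines = [f"{'':14s} {'classification rules':>28s} {'intent-flag':>28s}"]
    for metric in ("% correct", "% incorrect", "% missing"):
        cells = []
        for method in ("classification_rules", "intent_flag"):
            row = report[(report["metric"] == metric) & (report["method"] == method)].iloc[0]
            if np.isfinite(row["ci_low"]):
                cells.append(f"{row['value']:6.1f} ({row['ci_low']:5.1f}, {row['ci_high']:5.1f})")
            elif np.isfinite(row["value"]):
                cells.append(f"{row['value']:6.1f}")
            else:
                cells.append("unavailable")
        lines.append(f"{metric:14s} {cells[0]:>28s} {cells[1]:>28s}")
    return "\n".join(lines) + "\n"
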