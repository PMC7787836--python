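"""Diagnostic test accuracy: 2x2 counts, point estimates, 95% confidence intervals.

Conventions follow the clinical diagnostic-accuracy literature:

* sensitivity = TP / (TP + FN), specificity = TN / (TN + FP)
* PLR = sens / (1 - spec), NLR = (1 - sens) / spec
* proportion CIs are unclipped Wald intervals p +/- 1.96 * sqrt(p(1-p)/n),
  which can exceed [0, 1] at extreme proportions and small n
* likelihood-ratio CIs use the standard log method (Simel et al.)
* AUC is the Mann-Whitney statistic with half credit for score ties,
  identical to the trapezoidal ROC area

Predictive values at an arbitrary disease prevalence follow Bayes' rule, so a
classifier validated at one malignancy rate can be projected onto the 20-40%
prevalence typical of cytologically indeterminate thyroid nodules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

Z95 = 1.96  # fixed 95% normal quantile, matching the reporting convention

__all__ = [
    "ConfusionCounts",
    "MetricEstimate",
    "DiagnosticReport",
    "confusion",
    "point_metrics",
    "wald_ci",
    "lr_ci",
    "predictive_values_at",
    "auc",
    "pathology_accuracy",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion table. Positive class = malignant (label 1)."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"confusion cell {name!r} must be a nonnegative integer, got {v!r}")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def n(self) -> int:
        return self.n_pos + self.n_neg


def confusion(calls, labels) -> ConfusionCounts:
    """Cross-tabulate binary calls against binary truth labels."""
    calls = np.asarray(calls)
    labels = np.asarray(labels)
    if calls.shape != labels.shape or calls.ndim != 1:
        raise ValueError(f"calls and labels must be aligned 1-d vectors, got shapes {calls.shape} and {labels.shape}")
    for name, v in (("calls", calls), ("labels", labels)):
        if not np.isin(v, (0, 1)).all():
            raise ValueError(f"{name} must be binary 0/1")
    return ConfusionCounts(
        tp=int(((calls == 1) & (labels == 1)).sum()),
        fn=int(((calls == 0) & (labels == 1)).sum()),
        tn=int(((calls == 0) & (labels == 0)).sum()),
        fp=int(((calls == 1) & (labels == 0)).sum()),
    )


def point_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Point estimates of the eight reported metrics from a 2x2 table.

    Metrics whose denominator is zero are reported as ``math.nan`` and listed
    under the ``"undefined"`` key rather than failing silently.
    """
    out: dict[str, float] = {}
    undefined: list[str] = []

    def ratio(name: str, num: float, den: float) -> float:
        if den == 0:
            undefined.append(name)
            return math.nan
        return num / den

    sens = ratio("sensitivity", c.tp, c.n_pos)
    spec = ratio("specificity", c.tn, c.n_neg)
    out["sensitivity"] = sens
    out["specificity"] = spec
    out["accuracy"] = ratio("accuracy", c.tp + c.tn, c.n)
    out["plr"] = ratio("plr", sens, 1.0 - spec) if not math.isnan(spec) else math.nan
    out["nlr"] = ratio("nlr", 1.0 - sens, spec) if not math.isnan(sens) else math.nan
    out["ppv"] = ratio("ppv", c.tp, c.tp + c.fp)
    out["npv"] = ratio("npv", c.tn, c.tn + c.fn)
    out["prevalence"] = ratio("prevalence", c.n_pos, c.n)
    out["undefined"] = undefined  # type: ignore[assignment]
    return out


def wald_ci(p: float, n: int, clip: bool = False) -> tuple[float, float]:
    """Unclipped 95% Wald interval for a proportion.

    Deliberately allowed to cross 0 and 1 (e.g. p = 71/72 at n = 72 gives an
    upper bound above 100%), matching the convention of clinical
    diagnostic-accuracy reports.  Set ``clip=True`` to truncate to [0, 1].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    half = Z95 * math.sqrt(p * (1.0 - p) / n)
    lo, hi = p - half, p + half
    if clip:
        lo, hi = max(lo, 0.0), min(hi, 1.0)
    return lo, hi


def lr_ci(c: ConfusionCounts) -> dict[str, tuple[float, float]]:
    """95% CIs for the likelihood ratios by the log method.

    Requires all four cells positive; a zero cell makes the log-variance
    undefined and is flagged with a ``ValueError``.
    """
    if min(c.tp, c.fn, c.tn, c.fp) == 0:
        raise ValueError("likelihood-ratio CI undefined with a zero confusion cell")
    sens = c.tp / c.n_pos
    spec = c.tn / c.n_neg
    plr = sens / (1.0 - spec)
    nlr = (1.0 - sens) / spec
    se_log_plr = math.sqrt((1.0 - sens) / (sens * c.n_pos) + spec / ((1.0 - spec) * c.n_neg))
    se_log_nlr = math.sqrt(sens / ((1.0 - sens) * c.n_pos) + (1.0 - spec) / (spec * c.n_neg))
    return {
        "plr": (math.exp(math.log(plr) - Z95 * se_log_plr), math.exp(math.log(plr) + Z95 * se_log_plr)),
        "nlr": (math.exp(math.log(nlr) - Z95 * se_log_nlr), math.exp(math.log(nlr) + Z95 * se_log_nlr)),
    }


def predictive_values_at(sens: float, spec: float, prevalence: float) -> tuple[float, float]:
    """PPV and NPV at an arbitrary prevalence via Bayes' rule."""
    for name, v in (("sens", sens), ("spec", spec), ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    pi = prevalence
    ppv_num = sens * pi
    ppv_den = ppv_num + (1.0 - spec) * (1.0 - pi)
    npv_num = spec * (1.0 - pi)
    npv_den = npv_num + (1.0 - sens) * pi
    ppv = ppv_num / ppv_den if ppv_den > 0 else math.nan
    npv = npv_num / npv_den if npv_den > 0 else 1.0  # no diseased and no false positives
    return ppv, npv


def auc(scores, labels) -> float:
    """Area under the ROC curve, computed as the Mann-Whitney statistic.

    Ties in the scores receive half credit, so the value equals the
    trapezoidal area under the empirical ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-d vectors")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(scores)  # midranks handle ties
    rank_sum_pos = ranks[labels == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def pathology_accuracy(calls, labels, pathology) -> pd.DataFrame:
    """Per-pathology accuracy table: correct / total (percent) per stratum.

    Strata with no samples are simply absent; unknown stratum names form their
    own rows.  Mirrors the count/total (%) cell format of per-histology
    accuracy tables.
    """
    calls = np.asarray(calls)
    labels = np.asarray(labels)
    pathology = np.asarray(pathology, dtype=object)
    if not (calls.shape == labels.shape == pathology.shape):
        raise ValueError("calls, labels and pathology must be aligned")
    correct = calls == labels
    rows = []
    for stratum in pd.unique(pathology):
        mask = pathology == stratum
        k, n = int(correct[mask].sum()), int(mask.sum())
        rows.append(
            {
                "pathology": stratum,
                "correct": k,
                "total": n,
                "accuracy": k / n,
                "display": f"{k}/{n} ({100.0 * k / n:.1f}%)",
            }
        )
    return pd.DataFrame(rows).set_index("pathology")


@dataclass(frozen=True)
class MetricEstimate:
    estimate: float
    ci_low: float = math.nan
    ci_high: float = math.nan

    def as_percent(self, digits: int = 1) -> str:
        if math.isnan(self.estimate):
            return "undefined"
        s = f"{100 * self.estimate:.{digits}f}%"
        if not math.isnan(self.ci_low):
            s += f" [{100 * self.ci_low:.{digits}f}–{100 * self.ci_high:.{digits}f}%]"
        return s

    def as_ratio(self, digits: int = 3) -> str:
        if math.isnan(self.estimate):
            return "undefined"
        s = f"{self.estimate:.{digits}f}"
        if not math.isnan(self.ci_low):
            s += f" [{self.ci_low:.{digits}f}–{self.ci_high:.{digits}f}]"
        return s


@dataclass
class DiagnosticReport:
    """The eight reported metrics with 95% CIs, plus prevalence and AUC."""

    counts: ConfusionCounts
    prevalence: MetricEstimate = field(init=False)
    auc: MetricEstimate | None = None
    accuracy: MetricEstimate = field(init=False)
    sensitivity: MetricEstimate = field(init=False)
    specificity: MetricEstimate = field(init=False)
    plr: MetricEstimate = field(init=False)
    nlr: MetricEstimate = field(init=False)
    ppv: MetricEstimate = field(init=False)
    npv: MetricEstimate = field(init=False)

    def __post_init__(self) -> None:
        c = self.counts
        pm = point_metrics(c)
        self.prevalence = MetricEstimate(pm["prevalence"])
        self.accuracy = MetricEstimate(pm["accuracy"], *wald_ci(pm["accuracy"], c.n))
        self.sensitivity = MetricEstimate(pm["sensitivity"], *wald_ci(pm["sensitivity"], c.n_pos))
        self.specificity = MetricEstimate(pm["specificity"], *wald_ci(pm["specificity"], c.n_neg))
        if min(c.tp, c.fn, c.tn, c.fp) > 0:
            ci = lr_ci(c)
            self.plr = MetricEstimate(pm["plr"], *ci["plr"])
            self.nlr = MetricEstimate(pm["nlr"], *ci["nlr"])
        else:
            self.plr = MetricEstimate(pm["plr"])
            self.nlr = MetricEstimate(pm["nlr"])
        n_called_pos = c.tp + c.fp
        n_called_neg = c.tn + c.fn
        self.ppv = MetricEstimate(
            pm["ppv"], *(wald_ci(pm["ppv"], n_called_pos) if n_called_pos else (math.nan, math.nan))
        )
        self.npv = MetricEstimate(
            pm["npv"], *(wald_ci(pm["npv"], n_called_neg) if n_called_neg else (math.nan, math.nan))
        )

    @classmethod
    def from_calls(cls, calls, labels, scores=None) -> "DiagnosticReport":
        rep = cls(confusion(calls, labels))
        if scores is not None:
            rep.auc = MetricEstimate(auc(scores, labels))
        return rep

    def summary(self) -> pd.DataFrame:
        """Table 3-style layout: metric, estimate, ci_low, ci_high."""
        rows = {
            "prevalence": self.prevalence,
            "auc": self.auc if self.auc is not None else MetricEstimate(math.nan),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "plr": self.plr,
            "nlr": self.nlr,
            "ppv": self.ppv,
            "npv": self.npv,
        }
        return pd.DataFrame(
            [(k, v.estimate, v.ci_low, v.ci_high) for k, v in rows.items()],
            columns=["metric", "estimate", "ci_low", "ci_high"],
        ).set_index("metric")

    def __str__(self) -> str:
        lines = [
            f"n = {self.counts.n} (pos {self.counts.n_pos}, neg {self.counts.n_neg})",
            f"prevalence   {self.prevalence.as_percent()}",
        ]
        if self.auc is not None:
            lines.append(f"auc          {self.auc.as_ratio()}")
        lines += [
            f"accuracy     {self.accuracy.as_percent()}",
            f"sensitivity  {self.sensitivity.as_percent()}",
            f"specificity  {self.specificity.as_percent()}",
            f"plr          {self.plr.as_ratio()}",
            f"nlr          {self.nlr.as_ratio()}",
            f"ppv          {self.ppv.as_percent()}",
            f"npv          {self.npv.as_percent()}",
        ]
        return "\n".join(lines)
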