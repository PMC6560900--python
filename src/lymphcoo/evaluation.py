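"""Diagnostic-performance harness.

Conventions: the positive class is GCB — a true positive is a GEP-GCB case
called GCB, a true negative a GEP-non-GCB case called non-GCB. Seven
metrics are reported per classifier (Acc, Sens, Spec, PPV, NPV, LR+, LR−),
agreement between labelings is Cohen's kappa with the usual qualitative
bands and a Pearson chi-square p-value, and classifiers are placed in ROC
space and ranked by accuracy.

Metrics are kept at full precision internally; rounding happens only when
reports are written (several published likelihood ratios are irreproducible
from their own rounded Sens/Spec cells, so intermediate rounding would
corrupt comparisons). Metrics with zero denominators are reported as
undefined (None), never coerced to 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .cohort import GCB, NON_GCB

METRIC_ORDER = ("Acc", "Sens", "Spec", "PPV", "NPV", "LR+", "LR-")

KAPPA_BANDS = (
    (0.0, "no agreement"),
    (0.20, "poor"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "good"),
    (1.0, "very good"),
)


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts under the GCB-positive convention."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    """The seven diagnostic metrics; ``None`` marks an undefined value."""

    acc: Optional[float]
    sens: Optional[float]
    spec: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    lr_pos: Optional[float]
    lr_neg: Optional[float]

    def as_dict(self, ndigits: Optional[int] = None) -> dict:
        vals = dict(
            zip(METRIC_ORDER, (self.acc, self.sens, self.spec, self.ppv,
                               self.npv, self.lr_pos, self.lr_neg))
        )
        if ndigits is not None:
            vals = {
                k: (round(v, ndigits) if v is not None and math.isfinite(v) else v)
                for k, v in vals.items()
            }
        return vals


@dataclass(frozen=True)
class KappaResult:
    kappa: Optional[float]
    band: Optional[str]
    p_value: Optional[float]


def confusion(truth: Sequence[str], predicted: Sequence[str]) -> ConfusionCounts:
    """Cross-tabulate binary truth against predictions (positive = GCB)."""
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise EvaluationError(
            f"length mismatch: {len(truth)} truth vs {len(predicted)} predicted"
        )
    valid = {GCB, NON_GCB}
    bad = (set(truth) | set(predicted)) - valid
    if bad:
        raise EvaluationError(f"labels must be GCB/non-GCB, got {sorted(bad)}")
    tp = sum(t == GCB and p == GCB for t, p in zip(truth, predicted))
    fn = sum(t == GCB and p == NON_GCB for t, p in zip(truth, predicted))
    fp = sum(t == NON_GCB and p == GCB for t, p in zip(truth, predicted))
    tn = sum(t == NON_GCB and p == NON_GCB for t, p in zip(truth, predicted))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: float, den: float, name: str) -> Optional[float]:
    if den == 0:
        if num == 0:
            warnings.warn(f"{name} undefined (0/0)", stacklevel=3)
            return None
        return math.inf
    return num / den


def likelihood_ratios(
    sens: float, spec: float
) -> tuple[Optional[float], Optional[float]]:
    """LR+ = Sens/(1−Spec) and LR− = (1−Sens)/Spec from sensitivity and
    specificity on [0, 1]."""
    lr_pos = _ratio(sens, 1.0 - spec, "LR+")
    lr_neg = _ratio(1.0 - sens, spec, "LR-")
    return lr_pos, lr_neg


def metrics(c: ConfusionCounts) -> MetricSet:
    """Seven diagnostic metrics from confusion counts (full precision)."""
    acc = _ratio(c.tp + c.tn, c.n, "Acc")
    sens = _ratio(c.tp, c.tp + c.fn, "Sens")
    spec = _ratio(c.tn, c.tn + c.fp, "Spec")
    ppv = _ratio(c.tp, c.tp + c.fp, "PPV")
    npv = _ratio(c.tn, c.tn + c.fn, "NPV")
    if sens is None or spec is None:
        lr_pos = lr_neg = None
        warnings.warn("likelihood ratios undefined without Sens and Spec")
    else:
        lr_pos, lr_neg = likelihood_ratios(sens, spec)
    return MetricSet(acc, sens, spec, ppv, npv, lr_pos, lr_neg)


def _crosstab(a: Sequence[str], b: Sequence[str]) -> np.ndarray:
    order = (GCB, NON_GCB)
    table = np.zeros((2, 2))
    for x, y in zip(a, b):
        table[order.index(x), order.index(y)] += 1
    return table


def cohen_kappa(a: Sequence[str], b: Sequence[str]) -> KappaResult:
    """Chance-corrected agreement between two binary labelings.

    kappa = (p_o − p_e)/(1 − p_e) with expected agreement from the marginal
    products; the p-value is a Pearson chi-square test (no continuity
    correction) on the 2x2 cross-tabulation. If both labelings are constant
    (p_e = 1), kappa is 1 when they are identical and undefined otherwise.
    """
    a, b = list(a), list(b)
    if len(a) != len(b):
        raise EvaluationError("labelings must have equal length")
    if len(a) == 0:
        raise EvaluationError("labelings are empty")
    table = _crosstab(a, b)
    n = table.sum()
    p_o = np.trace(table) / n
    row = table.sum(axis=1) / n
    col = table.sum(axis=0) / n
    p_e = float(row @ col)
    if p_e >= 1.0 - 1e-12:
        kappa = 1.0 if a == b else None
        if kappa is None:
            warnings.warn("kappa undefined: both labelings constant but different")
    else:
        kappa = float((p_o - p_e) / (1.0 - p_e))
    p_value: Optional[float]
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        p_value = None
    else:
        _, p_value, _, _ = chi2_contingency(table, correction=False)
        p_value = float(p_value)
    band = kappa_band(kappa) if kappa is not None else None
    return KappaResult(kappa=kappa, band=band, p_value=p_value)


def kappa_band(kappa: float) -> str:
    """Qualitative agreement band: <=0 none, then poor / fair / moderate /
    good / very good in 0.20-wide bands with inclusive upper edges."""
    if not -1.0 - 1e-12 <= kappa <= 1.0 + 1e-12:
        raise EvaluationError(f"kappa {kappa} outside [-1, 1]")
    for upper, label in KAPPA_BANDS:
        if kappa <= upper + 1e-12:
            return label
    return KAPPA_BANDS[-1][1]  # pragma: no cover


def agreement_matrix(labelings: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Symmetric matrix of pairwise kappas between named labelings
    (diagonal = 1)."""
    names = list(labelings)
    lengths = {len(v) for v in labelings.values()}
    if len(lengths) > 1:
        raise EvaluationError("all labelings must have the same length")
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, ni in enumerate(names):
        for j in range(i + 1, len(names)):
            nj = names[j]
            k = cohen_kappa(labelings[ni], labelings[nj]).kappa
            mat.loc[ni, nj] = mat.loc[nj, ni] = np.nan if k is None else k
    return mat


def roc_point(c: ConfusionCounts) -> tuple[float, float]:
    """(false-positive rate, true-positive rate) = (1 − Spec, Sens)."""
    m = metrics(c)
    if m.sens is None or m.spec is None:
        raise EvaluationError("ROC point undefined without Sens and Spec")
    return (1.0 - m.spec, m.sens)


def rank_by_accuracy(results: Mapping[str, MetricSet]) -> pd.DataFrame:
    """Rank classifiers by accuracy, descending; ties broken alphabetically
    for determinism. Undefined accuracies sort last."""
    rows = []
    for name, m in results.items():
        rows.append({"name": name, **m.as_dict()})
    if not rows:
        return pd.DataFrame(columns=["rank", "name", *METRIC_ORDER])
    df = pd.DataFrame(rows)
    df["_key"] = df["Acc"].map(
        lambda a: -a if a is not None and not math.isnan(a) else math.inf
    )
    df = df.sort_values(["_key", "name"]).drop(columns="_key").reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def count_algorithm_grid(n_structures: int, tree_specs) -> tuple[int, int]:
    """Size of the comparison: machine-learning classifiers are one per
    (structure, distinct antibody combination) pair; the total adds the
    decision trees themselves."""
    from .trees import unique_combinations

    ml = n_structures * len(unique_combinations(tree_specs))
    return ml, ml + len(tree_specs)


def metrics_table(results: Mapping[str, MetricSet], ndigits: int = 2) -> pd.DataFrame:
    """Report table in the canonical column order, rounded for display."""
    rows = [{"name": n, **m.as_dict(ndigits=ndigits)} for n, m in results.items()]
    return pd.DataFrame(rows, columns=["name", *METRIC_ORDER])
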