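"""Bayesian classifiers over binarized marker panels.

Three structures are provided, mirroring the B / BS / BN family the
comparison grid uses:

* ``B`` — joint-table Bayes: per-class empirical probabilities over all
  2^k binary marker patterns (the minimal-misclassification rule when the
  table is the truth);
* ``BS`` — "Bayesian simple": class-conditional independence with no
  smoothing (failing over to alpha = 0.5 with a warning when a zero count
  would produce a degenerate probability);
* ``BN`` — naive Bayes with Laplace smoothing (alpha = 1).

The PV (Perfecto-Villela) preset is the BS structure on the four-antibody
combination CD10, FOXP1, GCET1, MUM1 — deliberately without BCL6.

Markers are dichotomized at a single configurable cut-off scheme (uniform
30% by default). Posteriors are accumulated in log space.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.special import logsumexp

from .cohort import GCB, NON_GCB, Cohort
from .panel import (
    DEFAULT_CUTOFFS,
    CutoffScheme,
    MarkerProfile,
    binarize,
    is_missing,
    tags_to_markers,
)

CLASSES = (GCB, NON_GCB)
MAX_JOINT_MARKERS = 10


class BayesError(ValueError):
    pass


@dataclass
class BernoulliNBModel:
    """Independence ("simple"/naive) Bayes: priors plus per-class,
    per-marker positivity probabilities."""

    combination: tuple[int, ...]
    priors: dict[str, float]
    theta: dict[str, dict[str, float]]  # class -> marker -> P(positive | class)
    alpha: float
    cutoffs: dict[str, float]

    @property
    def markers(self) -> tuple[str, ...]:
        return tags_to_markers(self.combination)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": "naive",
                "combination": list(self.combination),
                "priors": self.priors,
                "theta": self.theta,
                "alpha": self.alpha,
                "cutoffs": self.cutoffs,
            },
            indent=2,
        )


@dataclass
class JointBayesModel:
    """Joint-table Bayes: priors plus a per-class probability table over
    every binary marker pattern."""

    combination: tuple[int, ...]
    priors: dict[str, float]
    tables: dict[str, dict[tuple[int, ...], float]]
    alpha: float
    cutoffs: dict[str, float]
    prior_fallback: bool = True  # unseen-in-both-classes patterns fall back to priors

    @property
    def markers(self) -> tuple[str, ...]:
        return tags_to_markers(self.combination)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": "joint",
                "combination": list(self.combination),
                "priors": self.priors,
                "tables": {
                    c: {"".join(map(str, k)): v for k, v in t.items()}
                    for c, t in self.tables.items()
                },
                "alpha": self.alpha,
                "cutoffs": self.cutoffs,
                "prior_fallback": self.prior_fallback,
            },
            indent=2,
        )


def model_from_json(text: str) -> Union[BernoulliNBModel, JointBayesModel]:
    d = json.loads(text)
    if d["kind"] == "naive":
        return BernoulliNBModel(
            combination=tuple(d["combination"]),
            priors=d["priors"],
            theta=d["theta"],
            alpha=d["alpha"],
            cutoffs=d["cutoffs"],
        )
    return JointBayesModel(
        combination=tuple(d["combination"]),
        priors=d["priors"],
        tables={
            c: {tuple(int(ch) for ch in k): v for k, v in t.items()}
            for c, t in d["tables"].items()
        },
        alpha=d["alpha"],
        cutoffs=d["cutoffs"],
        prior_fallback=d.get("prior_fallback", True),
    )


def _binary_design(cohort: Cohort, markers, cutoffs) -> tuple[np.ndarray, np.ndarray]:
    mask = cohort.complete_for(markers) & cohort.truth.notna().to_numpy()
    sub = cohort.df.loc[mask, list(markers)].to_numpy(float)
    thresh = np.array([cutoffs[m] for m in markers])
    X = (sub >= thresh).astype(int)
    y = cohort.truth[mask].to_numpy()
    return X, y


def fit_naive_bayes(
    cohort: Cohort,
    combination: Sequence[int],
    cutoffs: Optional[CutoffScheme] = None,
    alpha: float = 1.0,
) -> BernoulliNBModel:
    """Estimate priors and positivity probabilities with pseudocount alpha:
    theta = (positives + alpha) / (n_class + 2 alpha)."""
    markers = tags_to_markers(combination)
    cutoffs = {m: dict(cutoffs or DEFAULT_CUTOFFS)[m] for m in markers}
    X, y = _binary_design(cohort, markers, cutoffs)
    priors, theta = {}, {}
    for c in CLASSES:
        Xc = X[y == c]
        if len(Xc) == 0:
            raise BayesError(f"no complete {c} cases to fit on")
        priors[c] = len(Xc) / len(X)
        theta[c] = {
            m: float((Xc[:, j].sum() + alpha) / (len(Xc) + 2 * alpha))
            for j, m in enumerate(markers)
        }
    return BernoulliNBModel(
        combination=tuple(sorted(int(t) for t in combination)),
        priors=priors,
        theta=theta,
        alpha=alpha,
        cutoffs=cutoffs,
    )


def fit_joint_bayes(
    cohort: Cohort,
    combination: Sequence[int],
    cutoffs: Optional[CutoffScheme] = None,
    alpha: float = 0.0,
) -> JointBayesModel:
    """Estimate per-class pattern tables with additive smoothing over the
    2^k cells. Refuses combinations above 10 markers (table-size guard)."""
    markers = tags_to_markers(combination)
    if len(markers) > MAX_JOINT_MARKERS:
        raise BayesError(
            f"joint table over {len(markers)} markers exceeds the "
            f"{MAX_JOINT_MARKERS}-marker guard"
        )
    cutoffs = {m: dict(cutoffs or DEFAULT_CUTOFFS)[m] for m in markers}
    X, y = _binary_design(cohort, markers, cutoffs)
    patterns = list(itertools.product((0, 1), repeat=len(markers)))
    priors, tables = {}, {}
    for c in CLASSES:
        Xc = X[y == c]
        if len(Xc) == 0:
            raise BayesError(f"no complete {c} cases to fit on")
        priors[c] = len(Xc) / len(X)
        counts = {p: 0 for p in patterns}
        for row in map(tuple, Xc):
            counts[row] += 1
        denom = len(Xc) + alpha * len(patterns)
        tables[c] = {p: (counts[p] + alpha) / denom for p in patterns}
    return JointBayesModel(
        combination=tuple(sorted(int(t) for t in combination)),
        priors=priors,
        tables=tables,
        alpha=alpha,
        cutoffs=cutoffs,
    )


def fit_bayes_variant(
    cohort: Cohort,
    combination: Sequence[int],
    variant: str,
    cutoffs: Optional[CutoffScheme] = None,
) -> Union[BernoulliNBModel, JointBayesModel]:
    """Fit one of the B / BS / BN structures on a cohort."""
    variant = variant.upper()
    if variant == "B":
        return fit_joint_bayes(cohort, combination, cutoffs, alpha=0.0)
    if variant == "BS":
        model = fit_naive_bayes(cohort, combination, cutoffs, alpha=0.0)
        degenerate = any(
            t in (0.0, 1.0) for th in model.theta.values() for t in th.values()
        )
        if degenerate:
            warnings.warn(
                "BS fit produced a 0/1 positivity probability; "
                "refitting with alpha=0.5",
                stacklevel=2,
            )
            model = fit_naive_bayes(cohort, combination, cutoffs, alpha=0.5)
        return model
    if variant == "BN":
        return fit_naive_bayes(cohort, combination, cutoffs, alpha=1.0)
    raise BayesError(f"unknown Bayes variant {variant!r}; expected B, BS or BN")


def _pattern(model, profile: MarkerProfile, cutoffs=None) -> tuple[int, ...]:
    scheme = dict(cutoffs or model.cutoffs)
    flags = binarize(profile, {m: scheme[m] for m in model.markers if m in profile})
    bits = []
    for m in model.markers:
        if m not in flags or flags[m] is None:
            raise BayesError(f"profile lacks required marker {m}")
        bits.append(int(flags[m]))
    return tuple(bits)


def posterior(
    model: Union[BernoulliNBModel, JointBayesModel],
    profile: MarkerProfile,
    cutoffs: Optional[CutoffScheme] = None,
) -> float:
    """Posterior probability of GCB for one profile, by Bayes' rule on the
    binarized pattern (log-space accumulation)."""
    bits = _pattern(model, profile, cutoffs)
    logs = {}
    with np.errstate(divide="ignore"):
        for c in CLASSES:
            lp = np.log(model.priors[c])
            if isinstance(model, BernoulliNBModel):
                for m, b in zip(model.markers, bits):
                    th = model.theta[c][m]
                    lp += np.log(th) if b else np.log1p(-th)
            else:
                lp += np.log(model.tables[c][bits])
            logs[c] = lp
    values = np.array([logs[GCB], logs[NON_GCB]])
    if np.all(np.isinf(values) & (values < 0)):
        if isinstance(model, JointBayesModel) and model.prior_fallback:
            warnings.warn(
                f"pattern {bits} unseen in both classes; falling back to priors",
                stacklevel=2,
            )
            return model.priors[GCB]
        raise BayesError(f"pattern {bits} has zero probability in both classes")
    return float(np.exp(values[0] - logsumexp(values)))


def classify_bayes(
    model: Union[BernoulliNBModel, JointBayesModel],
    profile: MarkerProfile,
    cutoffs: Optional[CutoffScheme] = None,
) -> str:
    """GCB iff the posterior exceeds 1/2; an exact 1/2 goes to non-GCB."""
    return GCB if posterior(model, profile, cutoffs) > 0.5 else NON_GCB


@dataclass(frozen=True)
class BayesSpec:
    """Untrained specification of one Bayes-family classifier."""

    variant: str
    combination: tuple[int, ...]
    name: str = ""


def pv_preset() -> BayesSpec:
    """The PV algorithm: Bayesian simple (independence, unsmoothed with
    failover) over CD10, FOXP1, GCET1 and MUM1 — BCL6 excluded."""
    return BayesSpec(variant="BS", combination=(1, 3, 4, 5), name="PV")
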