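"""A uniform classifier interface over trees, LDFs, Bayes models and
external plug-ins, plus the train/evaluate comparison harness.

Every classifier exposes a name, the antibody tags it needs, whether it is
trainable, ``fit(cohort)`` and per-profile prediction. Cases lacking any
required marker are excluded from that classifier's evaluation (mirroring
the complete-scores rule of the source protocols) and logged.

ANN and SVM structures are not implemented here; any scikit-learn
estimator can be wrapped as a plug-in over binarized marker features,
which is how the 5-structure comparison grid is assembled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

from . import bayes as _bayes
from . import lda as _lda
from .cohort import GCB, NON_GCB, Cohort
from .evaluation import MetricSet, confusion, metrics
from .panel import DEFAULT_CUTOFFS, MarkerProfile, is_missing, tags_to_markers
from .splits import SplitPlan, split_cohort
from .trees import BUILTIN_NAMES, TreeSpec, builtin_tree, classify_tree


@runtime_checkable
class Classifier(Protocol):
    name: str
    combination: tuple[int, ...]
    trainable: bool

    def fit(self, cohort: Cohort) -> "Classifier": ...
    def predict_profile(self, profile: MarkerProfile) -> str: ...


def _required_markers(combination) -> tuple[str, ...]:
    return tags_to_markers(combination)


@dataclass
class TreeClassifier:
    """Fixed published decision tree; no training step."""

    spec: TreeSpec
    trainable: bool = False

    @property
    def name(self) -> str:
        return self.spec.name

    @property
    def combination(self) -> tuple[int, ...]:
        return self.spec.combination

    def fit(self, cohort: Cohort) -> "TreeClassifier":
        return self

    def predict_profile(self, profile: MarkerProfile) -> str:
        return classify_tree(profile, self.spec)


@dataclass
class LDAClassifier:
    """Linear discriminant functions, fitted or loaded from the published
    coefficient table."""

    combination: tuple[int, ...]
    config: _lda.LDAFitConfig = field(default_factory=_lda.LDAFitConfig)
    model: Optional[_lda.LDFModel] = None
    trainable: bool = True

    @property
    def name(self) -> str:
        tags = ",".join(map(str, self.combination))
        return f"LDA({tags})"

    @classmethod
    def from_paper(cls, combination) -> "LDAClassifier":
        model = _lda.load_paper_ldf(combination)
        return cls(combination=model.combination, model=model, trainable=False)

    def fit(self, cohort: Cohort) -> "LDAClassifier":
        if self.trainable:
            self.model = _lda.fit_lda(cohort, self.combination, self.config)
        return self

    def predict_profile(self, profile: MarkerProfile) -> str:
        if self.model is None:
            raise RuntimeError(f"{self.name} is not fitted")
        return _lda.classify_ldf(self.model, profile)


@dataclass
class BayesClassifier:
    """One of the B / BS / BN structures over a marker combination."""

    variant: str
    combination: tuple[int, ...]
    cutoffs: Optional[dict] = None
    model: object = None
    label: str = ""
    trainable: bool = True

    @property
    def name(self) -> str:
        if self.label:
            return self.label
        tags = ",".join(map(str, self.combination))
        return f"{self.variant}({tags})"

    @classmethod
    def pv(cls) -> "BayesClassifier":
        spec = _bayes.pv_preset()
        return cls(variant=spec.variant, combination=spec.combination, label=spec.name)

    def fit(self, cohort: Cohort) -> "BayesClassifier":
        self.model = _bayes.fit_bayes_variant(
            cohort, self.combination, self.variant, self.cutoffs
        )
        return self

    def predict_profile(self, profile: MarkerProfile) -> str:
        if self.model is None:
            raise RuntimeError(f"{self.name} is not fitted")
        return _bayes.classify_bayes(self.model, profile)


@dataclass
class SklearnClassifier:
    """Plug-in adapter: any scikit-learn estimator over binarized markers."""

    label: str
    combination: tuple[int, ...]
    estimator: object
    cutoffs: Optional[dict] = None
    trainable: bool = True

    @property
    def name(self) -> str:
        return self.label

    def _design(self, values: np.ndarray) -> np.ndarray:
        markers = _required_markers(self.combination)
        cutoffs = self.cutoffs or DEFAULT_CUTOFFS
        thresh = np.array([cutoffs[m] for m in markers])
        return (values >= thresh).astype(float)

    def fit(self, cohort: Cohort) -> "SklearnClassifier":
        markers = _required_markers(self.combination)
        mask = cohort.complete_for(markers) & cohort.truth.notna().to_numpy()
        X = self._design(cohort.df.loc[mask, list(markers)].to_numpy(float))
        y = (cohort.truth[mask] == GCB).to_numpy(int)
        self.estimator.fit(X, y)
        return self

    def predict_profile(self, profile: MarkerProfile) -> str:
        markers = _required_markers(self.combination)
        values = []
        for m in markers:
            if m not in profile or is_missing(profile[m]):
                raise KeyError(f"{self.name}: profile lacks required marker {m}")
            values.append(float(profile[m]))
        X = self._design(np.asarray([values]))
        return GCB if int(self.estimator.predict(X)[0]) == 1 else NON_GCB


def builtin_tree_classifiers() -> list[TreeClassifier]:
    return [TreeClassifier(builtin_tree(n)) for n in BUILTIN_NAMES]


def ml_grid(
    structures: Optional[dict[str, Callable[[tuple[int, ...]], Classifier]]] = None,
) -> list[Classifier]:
    """The comparison grid: one classifier per (structure, distinct
    combination of the eight built-in trees) pair — 7 combinations, so 5
    structures give 35 classifiers.

    ``structures`` maps a structure label to a factory taking a tag
    combination; the default supplies B, BS, BN natively and SVM / ANN
    through scikit-learn plug-ins (RBF support vector machine; a small
    multilayer perceptron with one 5-neuron hidden layer).
    """
    if structures is None:
        structures = default_structures()
    combos = sorted(
        {tuple(sorted(builtin_tree(n).combination)) for n in BUILTIN_NAMES}
    )
    grid: list[Classifier] = []
    for label, factory in structures.items():
        for combo in combos:
            grid.append(factory(combo))
    return grid


def default_structures() -> dict[str, Callable]:
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC

    def svm_factory(combo):
        tags = ",".join(map(str, combo))
        return SklearnClassifier(
            label=f"SVM({tags})", combination=combo,
            estimator=SVC(kernel="rbf", random_state=0),
        )

    def ann_factory(combo):
        tags = ",".join(map(str, combo))
        return SklearnClassifier(
            label=f"ANN({tags})", combination=combo,
            estimator=MLPClassifier(
                hidden_layer_sizes=(5,), max_iter=200, tol=1e-3, random_state=0
            ),
        )

    return {
        "B": lambda combo: BayesClassifier("B", combo),
        "BS": lambda combo: BayesClassifier("BS", combo),
        "BN": lambda combo: BayesClassifier("BN", combo),
        "SVM": svm_factory,
        "ANN": ann_factory,
    }


def predict_cohort(
    clf: Classifier, cohort: Cohort
) -> tuple[pd.Series, list[str]]:
    """Predict every case with complete markers; return (labels indexed like
    the cohort, with None where excluded) and the exclusion log."""
    markers = _required_markers(clf.combination)
    labels = []
    excluded = []
    for i in range(len(cohort)):
        profile = cohort.profile(i)
        if all(m in profile for m in markers):
            labels.append(clf.predict_profile(profile))
        else:
            missing = [m for m in markers if m not in profile]
            excluded.append(
                f"{clf.name}: case {cohort.case_ids[i]} excluded "
                f"(missing {', '.join(missing)})"
            )
            labels.append(None)
    return pd.Series(labels, index=cohort.df.index, dtype=object), excluded


@dataclass
class ComparisonResult:
    """Outputs of the train/evaluate harness."""

    predictions: pd.DataFrame          # case_id, truth, one column per classifier
    metric_sets: dict[str, MetricSet]
    excluded: list[str]
    eval_cohort: Cohort

    def labelings(self, include_truth: bool = True) -> dict[str, list]:
        """Per-classifier labels restricted to cases every classifier and
        the truth agree to cover (for agreement matrices)."""
        cols = [c for c in self.predictions.columns if c not in ("case_id",)]
        df = self.predictions[cols].dropna()
        out = {}
        for c in cols:
            if c == "truth" and not include_truth:
                continue
            out["GEP" if c == "truth" else c] = list(df[c])
        return out


def run_comparison(
    cohort: Cohort,
    classifiers: Sequence[Classifier],
    plan: Optional[SplitPlan] = None,
    resubstitution: bool = False,
) -> ComparisonResult:
    """Fit trainable classifiers on the training split and score everything
    on the merged test+validation remainder (the study protocol), or on the
    full cohort when ``resubstitution`` is set.
    """
    if not cohort.has_truth:
        raise ValueError("comparison requires a truth label for every case")
    if resubstitution:
        train_cohort = eval_cohort = cohort
    else:
        plan = plan or SplitPlan()
        train, test, validation = split_cohort(cohort, plan)
        merged = pd.concat([test.df, validation.df], ignore_index=True)
        train_cohort = train
        eval_cohort = Cohort(merged, provenance=f"{cohort.provenance}[eval]")

    preds = pd.DataFrame({"case_id": eval_cohort.case_ids,
                          "truth": eval_cohort.truth})
    metric_sets: dict[str, MetricSet] = {}
    excluded: list[str] = []
    truth = eval_cohort.truth
    for clf in classifiers:
        if clf.trainable:
            clf.fit(train_cohort)
        labels, log = predict_cohort(clf, eval_cohort)
        excluded.extend(log)
        preds[clf.name] = labels
        ok = labels.notna()
        metric_sets[clf.name] = metrics(
            confusion(truth[ok], labels[ok])
        )
    return ComparisonResult(
        predictions=preds,
        metric_sets=metric_sets,
        excluded=excluded,
        eval_cohort=eval_cohort,
    )
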