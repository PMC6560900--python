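"""Two-class linear discriminant analysis over antibody combinations.

Fisher/Gaussian LDA with a pooled within-class covariance yields one linear
discriminant function (LDF) per class,

    LDF_c(x) = ln pi_c - 1/2 mu_c' S^-1 mu_c + (S^-1 mu_c)' x,

and a case is assigned to the class with the larger score. The per-class
constants and per-antibody weights are exactly what clinical LDA tools
(e.g. Minitab) print, so fitted models and the published coefficient table
share one representation. By default marker inputs are positivity
indicators in {0, 1} (the published weight magnitudes, roughly 1-7, only
make sense on a unit scale); percent inputs divided by 100 are available
via ``scale="proportion"``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence, Union

import numpy as np

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


class LDAError(ValueError):
    pass


@dataclass(frozen=True)
class LDAFitConfig:
    """Options for :func:`fit_lda`.

    priors: "empirical" (class frequencies), "equal", or an explicit
        mapping class -> prior summing to 1.
    ridge: epsilon added to the pooled-covariance diagonal; stabilizes
        collinear binary markers.
    tie_break: class returned on an exact score tie (default non-GCB,
        mirroring the conservative merging of unclassified cases).
    """

    priors: Union[str, Mapping[str, float]] = "empirical"
    ridge: float = 1e-6
    tie_break: str = NON_GCB
    scale: str = "binary"  # "binary" | "proportion"
    cutoffs: Optional[CutoffScheme] = None

    def __post_init__(self):
        if self.ridge < 0:
            raise LDAError("ridge must be >= 0")
        if self.scale not in ("binary", "proportion"):
            raise LDAError("scale must be 'binary' or 'proportion'")
        if not isinstance(self.priors, str):
            total = sum(self.priors.values())
            if abs(total - 1.0) > 1e-9:
                raise LDAError(f"explicit priors must sum to 1, got {total}")
        elif self.priors not in ("empirical", "equal"):
            raise LDAError("priors must be 'empirical', 'equal' or a mapping")


@dataclass
class LDFModel:
    """Per-class linear discriminant functions over an antibody combination."""

    combination: tuple[int, ...]
    constants: dict[str, float]            # class -> constant term
    weights: dict[str, dict[str, float]]   # class -> marker -> weight
    scale: str = "binary"
    cutoffs: Optional[dict[str, float]] = None
    tie_break: str = NON_GCB
    label: str = ""

    @property
    def markers(self) -> tuple[str, ...]:
        return tags_to_markers(self.combination)

    def features(self, profile: MarkerProfile) -> np.ndarray:
        """Marker inputs on the model's declared scale."""
        x = []
        for m in self.markers:
            if m not in profile or is_missing(profile[m]):
                raise LDAError(f"profile lacks required marker {m}")
            x.append(float(profile[m]))
        x = np.asarray(x, dtype=float)
        if self.scale == "binary":
            cutoffs = self.cutoffs or DEFAULT_CUTOFFS
            flags = binarize(dict(zip(self.markers, x)), {m: cutoffs[m] for m in self.markers})
            x = np.array([1.0 if flags[m] else 0.0 for m in self.markers])
        else:
            x = x / 100.0
        return x

    def to_json(self) -> str:
        return json.dumps(
            {
                "combination": list(self.combination),
                "constants": self.constants,
                "weights": self.weights,
                "scale": self.scale,
                "cutoffs": self.cutoffs,
                "tie_break": self.tie_break,
                "label": self.label,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "LDFModel":
        d = json.loads(text)
        return cls(
            combination=tuple(d["combination"]),
            constants=d["constants"],
            weights=d["weights"],
            scale=d.get("scale", "binary"),
            cutoffs=d.get("cutoffs"),
            tie_break=d.get("tie_break", NON_GCB),
            label=d.get("label", ""),
        )


def fit_ldf_arrays(
    X: np.ndarray,
    y: Sequence[str],
    feature_names: Sequence[str],
    config: LDAFitConfig = LDAFitConfig(),
    classes: Sequence[str] = CLASSES,
) -> tuple[dict[str, float], dict[str, dict[str, float]]]:
    """Low-level LDF fit on an arbitrary feature matrix.

    Returns (constants, weights) per class using the pooled within-class
    covariance (divisor n - g) ridge-stabilized by ``config.ridge * I``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    g = len(classes)
    pooled = np.zeros((p, p))
    means, counts = {}, {}
    for c in classes:
        Xc = X[y == c]
        if len(Xc) < 2:
            raise LDAError(f"class {c!r} has {len(Xc)} complete cases; need >= 2")
        mu = Xc.mean(axis=0)
        means[c] = mu
        counts[c] = len(Xc)
        d = Xc - mu
        pooled += d.T @ d
    pooled /= n - g
    pooled += config.ridge * np.eye(p)
    if config.priors == "empirical":
        priors = {c: counts[c] / n for c in classes}
    elif config.priors == "equal":
        priors = {c: 1.0 / g for c in classes}
    else:
        priors = dict(config.priors)
    try:
        sol = np.linalg.solve(pooled, np.column_stack([means[c] for c in classes]))
    except np.linalg.LinAlgError as e:
        raise LDAError(
            "pooled within-class covariance is singular; "
            "set a positive ridge in LDAFitConfig"
        ) from e
    constants, weights = {}, {}
    for j, c in enumerate(classes):
        w = sol[:, j]
        constants[c] = float(np.log(priors[c]) - 0.5 * means[c] @ w)
        weights[c] = {name: float(wj) for name, wj in zip(feature_names, w)}
    return constants, weights


def fit_lda(
    cohort: Cohort,
    combination: Sequence[int],
    config: LDAFitConfig = LDAFitConfig(),
) -> LDFModel:
    """Fit per-class LDFs on a cohort for one antibody combination.

    Cases missing any marker of the combination are excluded. Features are
    positivity indicators (``scale="binary"``, cut-offs from the config or
    the uniform 30% default) or staining proportions (``scale="proportion"``).
    """
    markers = tags_to_markers(combination)
    mask = cohort.complete_for(markers)
    truth = cohort.truth
    usable = mask & truth.notna().to_numpy()
    sub = cohort.df.loc[usable, list(markers)].to_numpy(float)
    y = truth[usable].to_numpy()
    if config.scale == "binary":
        cutoffs = dict(config.cutoffs or DEFAULT_CUTOFFS)
        X = (sub >= np.array([cutoffs[m] for m in markers])).astype(float)
    else:
        cutoffs = None
        X = sub / 100.0
    constants, weights = fit_ldf_arrays(X, y, markers, config)
    return LDFModel(
        combination=tuple(sorted(int(t) for t in combination)),
        constants=constants,
        weights=weights,
        scale=config.scale,
        cutoffs={m: cutoffs[m] for m in markers} if cutoffs else None,
        tie_break=config.tie_break,
        label="fitted",
    )


def ldf_scores(model: LDFModel, profile: MarkerProfile) -> dict[str, float]:
    """Evaluate both discriminant functions on one profile."""
    x = model.features(profile)
    scores = {}
    for c in CLASSES:
        w = np.array([model.weights[c][m] for m in model.markers])
        scores[c] = float(model.constants[c] + w @ x)
    return scores


def classify_ldf(model: LDFModel, profile: MarkerProfile) -> str:
    """Assign the class with the larger LDF score; exact ties go to the
    configured tie-break class (default non-GCB)."""
    s = ldf_scores(model, profile)
    if s[GCB] == s[NON_GCB]:
        return model.tie_break
    return GCB if s[GCB] > s[NON_GCB] else NON_GCB


def _published() -> dict:
    text = resources.files("lymphcoo.data").joinpath("ldf_published.json").read_text()
    data = json.loads(text)
    data.pop("_comment", None)
    return data


def published_combinations() -> list[tuple[int, ...]]:
    """Antibody combinations whose LDF coefficients are shipped as fixtures."""
    return [tuple(int(t) for t in key.split(",")) for key in _published()]


def load_paper_ldf(combination: Sequence[int]) -> LDFModel:
    """Load the published LDF coefficients for one antibody combination.

    These are the verbatim per-class constants and weights reported for the
    eight combinations used by the decision-tree algorithms (plus the
    unnamed (1,4,5) set), evaluated on positivity indicators.
    """
    key = ",".join(str(t) for t in sorted(int(t) for t in combination))
    data = _published()
    if key not in data:
        raise LDAError(
            f"no published LDF coefficients for combination ({key}); "
            f"available: {sorted(data)}"
        )
    row = data[key]
    constants = {c: float(row[c]["constant"]) for c in CLASSES}
    weights = {
        c: {m: float(v) for m, v in row[c].items() if m != "constant"}
        for c in CLASSES
    }
    markers = tags_to_markers(int(t) for t in key.split(","))
    return LDFModel(
        combination=tuple(int(t) for t in key.split(",")),
        constants=constants,
        weights=weights,
        scale="binary",
        cutoffs={m: DEFAULT_CUTOFFS[m] for m in markers},
        tie_break=NON_GCB,
        label=row.get("label", ""),
    )
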