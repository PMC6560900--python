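"""Dataset splitting: train/test/validation partitions and stratified k-fold.

The comparison protocol splits a cohort 75/20/5 into training, testing and
validation subsets, stratifying on the binary truth so each subset keeps the
cohort's GCB proportion, and evaluates trained classifiers on the merged
test+validation remainder. Fractional subset sizes are resolved by flooring
each target and handing remaining cases to the largest fractional parts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort

DEFAULT_FRACTIONS = (0.75, 0.20, 0.05)


class SplitError(ValueError):
    pass


@dataclass(frozen=True)
class SplitPlan:
    """Train/test/validation fractions plus seed and stratification flag."""

    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    seed: int = 0
    stratify: bool = True

    def __post_init__(self):
        fr = tuple(float(f) for f in self.fractions)
        object.__setattr__(self, "fractions", fr)
        if any(f < 0 for f in fr):
            raise SplitError("fractions must be non-negative")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise SplitError(f"fractions must sum to 1, got {sum(fr)}")


def allocate_counts(n: int, fractions) -> list[int]:
    """Largest-remainder apportionment of ``n`` items across fractions.

    Each target ``n * f`` is floored; leftover items go to the largest
    fractional parts (ties resolved toward earlier fractions).
    """
    targets = [n * f for f in fractions]
    counts = [int(np.floor(t)) for t in targets]
    leftover = n - sum(counts)
    order = sorted(
        range(len(fractions)), key=lambda i: (-(targets[i] - counts[i]), i)
    )
    for i in order[:leftover]:
        counts[i] += 1
    return counts


def split_cohort(cohort: Cohort, plan: SplitPlan = SplitPlan()) -> tuple[Cohort, ...]:
    """Partition a cohort into disjoint subsets per a :class:`SplitPlan`.

    Deterministic given the plan's seed. In stratified mode every case must
    carry a binary truth label and each subset's class proportions match the
    cohort's to within one case per class.
    """
    if len(cohort) == 0:
        raise SplitError("cannot split an empty cohort")
    rng = np.random.default_rng(plan.seed)
    k = len(plan.fractions)
    parts: list[list[int]] = [[] for _ in range(k)]
    if plan.stratify:
        truth = cohort.truth
        if truth.isna().any():
            raise SplitError(
                "stratified split requires a GEP-derived truth label for every case"
            )
        for label in sorted(truth.dropna().unique()):
            idx = np.flatnonzero((truth == label).to_numpy())
            rng.shuffle(idx)
            counts = allocate_counts(len(idx), plan.fractions)
            start = 0
            for j, c in enumerate(counts):
                parts[j].extend(idx[start : start + c].tolist())
                start += c
    else:
        idx = np.arange(len(cohort))
        rng.shuffle(idx)
        counts = allocate_counts(len(idx), plan.fractions)
        start = 0
        for j, c in enumerate(counts):
            parts[j].extend(idx[start : start + c].tolist())
            start += c
    names = ("train", "test", "validation") if k == 3 else tuple(
        f"part{j}" for j in range(k)
    )
    return tuple(
        cohort.subset(sorted(p), provenance=f"{cohort.provenance}[{names[j]}]")
        for j, p in enumerate(parts)
    )


def stratified_kfold(cohort: Cohort, k: int, seed: int = 0) -> np.ndarray:
    """Assign each case to one of ``k`` folds, balanced within each class.

    Returns an integer array of fold indices (length = cohort size). Per-fold
    class counts differ by at most one from perfect balance; deterministic
    given the seed.
    """
    if k < 2:
        raise SplitError("k must be at least 2")
    truth = cohort.truth
    if truth.isna().any():
        raise SplitError("stratified k-fold requires truth labels for every case")
    rng = np.random.default_rng(seed)
    folds = np.empty(len(cohort), dtype=int)
    for label in sorted(truth.dropna().unique()):
        idx = np.flatnonzero((truth == label).to_numpy())
        if k > len(idx):
            raise SplitError(
                f"k={k} exceeds the {label} class size ({len(idx)} cases)"
            )
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds
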