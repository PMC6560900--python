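"""Synthetic DLBCL cohorts with the structure of the public reference
database: two latent cell-of-origin classes at ~48.6% / 51.4% prevalence,
class-conditional marker positivity, staining percentages on the correct
side of each marker's cut-off, and class-dependent exponential survival
with independent uniform censoring.

The generator lets every classifier and the full evaluation harness run
without any download. Markers are conditionally independent given class by
default (the independence-Bayes family's own model, so parameter recovery
is exact in expectation); an optional pairwise-correlation knob introduces
shared latent noise to stress the joint-table classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import GCB, NON_GCB, Cohort
from .panel import MARKERS, STAINING_CUTOFFS

#: GCB prevalence of the reference database: 231 of 475 cases (48.6%).
DEFAULT_PREVALENCE = 0.486

#: class-conditional positivity probabilities: germinal-center markers
#: (CD10, BCL6, GCET1) enriched in GCB, FOXP1 and MUM1 in non-GCB.
DEFAULT_POSITIVITY = {
    GCB: {"CD10": 0.65, "BCL6": 0.85, "FOXP1": 0.35, "GCET1": 0.55, "MUM1": 0.15},
    NON_GCB: {"CD10": 0.10, "BCL6": 0.55, "FOXP1": 0.80, "GCET1": 0.15, "MUM1": 0.85},
}

#: median overall survival (months); GCB outcomes are better.
DEFAULT_MEDIAN_SURVIVAL = {GCB: 120.0, NON_GCB: 60.0}


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Generator parameters.

    n: cohort size (reference database: 475 cases).
    prevalence: P(GCB).
    positivity: class -> marker -> P(marker positive | class).
    pos_beta / neg_beta: Beta shape pairs for the staining percentage
        within positive (concentrated high, above the marker cut-off) and
        negative (concentrated low, below 30%) calls.
    median_survival: class -> median overall survival in months
        (exponential event times).
    censor_max_months: independent uniform censoring horizon.
    uc_fraction: fraction of non-GCB cases labelled UC rather than ABC
        (44 of 244 in the reference database).
    marker_correlation: optional shared-latent-noise weight in [0, 1)
        inducing positive pairwise dependence between markers within class.
    """

    n: int = 475
    prevalence: float = DEFAULT_PREVALENCE
    positivity: dict = field(default_factory=lambda: {
        c: dict(p) for c, p in DEFAULT_POSITIVITY.items()
    })
    pos_beta: tuple[float, float] = (4.0, 1.5)
    neg_beta: tuple[float, float] = (1.5, 4.0)
    cutoffs: dict = field(default_factory=lambda: dict(STAINING_CUTOFFS))
    median_survival: dict = field(default_factory=lambda: dict(DEFAULT_MEDIAN_SURVIVAL))
    censor_max_months: float = 120.0
    uc_fraction: float = 44.0 / 244.0
    marker_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.prevalence <= 1.0:
            raise SimulationError(f"prevalence {self.prevalence} outside [0, 1]")
        for c, probs in self.positivity.items():
            for m, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise SimulationError(f"positivity[{c}][{m}] = {p} outside [0, 1]")
        for c, med in self.median_survival.items():
            if med <= 0:
                raise SimulationError(f"median survival for {c} must be > 0")
        if self.censor_max_months <= 0:
            raise SimulationError("censoring horizon must be > 0")
        if not 0.0 <= self.marker_correlation < 1.0:
            raise SimulationError("marker_correlation must be in [0, 1)")
        if not 0.0 <= self.uc_fraction <= 1.0:
            raise SimulationError("uc_fraction outside [0, 1]")

    @property
    def hazards(self) -> dict[str, float]:
        """Exponential rates per class, ln 2 / median."""
        return {c: np.log(2.0) / m for c, m in self.median_survival.items()}

    def to_json(self) -> str:
        d = asdict(self)
        d["hazards"] = self.hazards
        return json.dumps(d, indent=2)


def default_config(**overrides) -> SimConfig:
    """The calibrated default study conditions (see class docstring)."""
    return SimConfig(**overrides)


def simulate_cohort(config: Optional[SimConfig] = None, **overrides) -> Cohort:
    """Draw one synthetic cohort; deterministic given ``config.seed``.

    Per case: class ~ Bernoulli(prevalence); each marker positive with the
    class-conditional probability, its percentage drawn on the correct side
    of the marker's cut-off (positives in [cutoff, 100], negatives in
    [0, 30)); survival exponential by class with uniform censoring; the GEP
    label records the truth (non-GCB cases split into ABC/UC).
    """
    if config is None:
        config = default_config(**overrides)
    elif overrides:
        raise SimulationError("pass either a SimConfig or keyword overrides")
    rng = np.random.default_rng(config.seed)
    n = config.n
    is_gcb = rng.random(n) < config.prevalence
    classes = np.where(is_gcb, GCB, NON_GCB)

    rho = config.marker_correlation
    shared = rng.random(n)
    data = {"case_id": [f"S{i+1:05d}" for i in range(n)]}
    for m in MARKERS:
        p = np.array([config.positivity[c][m] for c in classes])
        u = rng.random(n)
        if rho > 0:
            u = rho * shared + (1 - rho) * u
        flag = u < p
        cut = config.cutoffs[m]
        pos = cut + (100.0 - cut) * rng.beta(*config.pos_beta, size=n)
        neg = min(cut, 30.0) * rng.beta(*config.neg_beta, size=n)
        data[m] = np.where(flag, pos, neg)

    gep = np.where(
        is_gcb,
        "GCB",
        np.where(rng.random(n) < config.uc_fraction, "UC", "ABC"),
    )
    data["gep_label"] = gep

    rates = np.array([config.hazards[c] for c in classes])
    t_event = rng.exponential(1.0 / rates)
    t_censor = rng.uniform(0.0, config.censor_max_months, size=n)
    data["os_months"] = np.minimum(t_event, t_censor)
    data["os_event"] = (t_event <= t_censor).astype(int)

    return Cohort(pd.DataFrame(data), provenance=f"synthetic(seed={config.seed})")
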