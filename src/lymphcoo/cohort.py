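"""Cohort tables: one row per patient with marker percentages, the optional
gene-expression-profiling (GEP) label, and optional overall-survival columns.

The GEP three-way label (GCB / ABC / UC) is collapsed to the binary truth
used throughout: GCB vs non-GCB, where both ABC and UC count as non-GCB.
The original three-way label is retained for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .panel import MARKERS, MarkerProfile, is_missing

GCB = "GCB"
NON_GCB = "non-GCB"
GEP_LABELS = ("GCB", "ABC", "UC")

#: canonical column order for cohort CSV/TSV files
COLUMNS = ("case_id", *MARKERS, "gep_label", "os_months", "os_event")


class CohortFormatError(ValueError):
    """Raised when a cohort table violates the format contract."""


def truth_from_gep(gep_label: Optional[str]) -> Optional[str]:
    """Binary truth: GCB iff the GEP label is GCB; ABC and UC are non-GCB."""
    if gep_label is None or (isinstance(gep_label, float) and np.isnan(gep_label)):
        return None
    if gep_label == "GCB":
        return GCB
    if gep_label in ("ABC", "UC"):
        return NON_GCB
    raise CohortFormatError(f"unknown GEP label {gep_label!r}; expected GCB/ABC/UC")


@dataclass
class Case:
    """One patient: staining profile plus optional truth and survival."""

    case_id: str
    profile: dict
    gep_label: Optional[str] = None
    os_months: Optional[float] = None
    os_event: Optional[int] = None

    @property
    def truth(self) -> Optional[str]:
        return truth_from_gep(self.gep_label)


class Cohort:
    """A set of cases backed by a :class:`pandas.DataFrame`.

    Parameters
    ----------
    df : DataFrame with columns ``case_id``, the five markers, and optionally
        ``gep_label``, ``os_months``, ``os_event``.
    provenance : free-text origin label carried through splits.
    """

    def __init__(self, df: pd.DataFrame, provenance: str = ""):
        df = df.copy().reset_index(drop=True)
        if "case_id" not in df.columns:
            raise CohortFormatError("cohort table must have a case_id column")
        missing = [m for m in MARKERS if m not in df.columns]
        if missing:
            raise CohortFormatError(f"cohort table lacks marker columns: {missing}")
        df["case_id"] = df["case_id"].astype(str)
        dupes = df["case_id"][df["case_id"].duplicated()]
        if len(dupes):
            raise CohortFormatError(f"duplicate case ids: {sorted(set(dupes))}")
        for m in MARKERS:
            df[m] = pd.to_numeric(df[m], errors="raise").astype(float)
            bad = df.index[(df[m] < 0) | (df[m] > 100)]
            if len(bad):
                row = int(bad[0])
                raise CohortFormatError(
                    f"{m} value {df.loc[row, m]} outside [0, 100] "
                    f"(case {df.loc[row, 'case_id']!r}, row {row + 2})"
                )
        if "gep_label" in df.columns:
            labels = df["gep_label"].dropna()
            unknown = set(labels) - set(GEP_LABELS)
            if unknown:
                raise CohortFormatError(
                    f"unknown GEP labels {sorted(unknown)}; expected GCB/ABC/UC"
                )
        has_m = "os_months" in df.columns
        has_e = "os_event" in df.columns
        if has_m != has_e:
            raise CohortFormatError("os_months and os_event must be given together")
        if has_m:
            df["os_months"] = pd.to_numeric(df["os_months"], errors="raise").astype(float)
            df["os_event"] = pd.to_numeric(df["os_event"], errors="raise").astype(float)
            obs = df["os_months"].dropna()
            if (obs < 0).any():
                raise CohortFormatError("negative survival time")
            ev = df["os_event"].dropna()
            if not ev.isin([0.0, 1.0]).all():
                raise CohortFormatError("os_event must be 0 or 1")
        self.df = df
        self.provenance = provenance

    # -- basic container protocol -------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def case_ids(self) -> list[str]:
        return list(self.df["case_id"])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        src = f", provenance={self.provenance!r}" if self.provenance else ""
        return f"Cohort(n={len(self)}{src})"

    # -- labels --------------------------------------------------------------
    @property
    def gep_labels(self) -> pd.Series:
        if "gep_label" in self.df.columns:
            return self.df["gep_label"]
        return pd.Series([None] * len(self.df), index=self.df.index, dtype=object)

    @property
    def truth(self) -> pd.Series:
        """Binary truth per case (GCB / non-GCB), ``None`` where no GEP label."""
        return self.gep_labels.map(truth_from_gep, na_action=None)

    @property
    def has_truth(self) -> bool:
        return bool(self.truth.notna().all()) and len(self) > 0

    # -- survival -------------------------------------------------------------
    @property
    def has_survival(self) -> bool:
        return (
            "os_months" in self.df.columns
            and bool(self.df["os_months"].notna().all())
            and bool(self.df["os_event"].notna().all())
        )

    def survival_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.has_survival:
            raise CohortFormatError(
                "cohort has no complete survival columns (os_months, os_event)"
            )
        return (
            self.df["os_months"].to_numpy(float),
            self.df["os_event"].to_numpy(float).astype(int),
        )

    # -- profiles -------------------------------------------------------------
    def marker_matrix(self) -> pd.DataFrame:
        return self.df[list(MARKERS)]

    def profile(self, i: int) -> dict:
        row = self.df.iloc[i]
        return {m: float(row[m]) for m in MARKERS if not is_missing(row[m])}

    def iter_cases(self) -> Iterator[Case]:
        for i in range(len(self.df)):
            row = self.df.iloc[i]
            gep = row.get("gep_label")
            if isinstance(gep, float) and np.isnan(gep):
                gep = None
            yield Case(
                case_id=row["case_id"],
                profile=self.profile(i),
                gep_label=gep,
                os_months=row.get("os_months"),
                os_event=row.get("os_event"),
            )

    def complete_for(self, markers: Sequence[str]) -> np.ndarray:
        """Boolean mask of cases with readings for every requested marker."""
        mask = np.ones(len(self.df), dtype=bool)
        for m in markers:
            mask &= self.df[m].notna().to_numpy()
        return mask

    def subset(self, index, provenance: Optional[str] = None) -> "Cohort":
        sub = self.df.iloc[np.asarray(index)].reset_index(drop=True)
        return Cohort(sub, provenance if provenance is not None else self.provenance)

    # -- I/O -------------------------------------------------------------------
    def to_csv(self, path, sep: str = ",") -> None:
        cols = [c for c in COLUMNS if c in self.df.columns]
        self.df[cols].to_csv(path, sep=sep, index=False)


_HEADER_ALIASES = {m.lower(): m for m in MARKERS}
_HEADER_ALIASES.update(
    {"case_id": "case_id", "caseid": "case_id", "id": "case_id",
     "gep_label": "gep_label", "gep": "gep_label",
     "os_months": "os_months", "os_event": "os_event"}
)


def read_cohort(path, fmt: Optional[str] = None, provenance: Optional[str] = None) -> Cohort:
    """Read a cohort CSV/TSV file.

    The header must name the five antibodies (case-insensitive); a case id
    column, the GEP label and the survival columns are recognised by name.
    ``fmt`` may be ``"csv"`` or ``"tsv"``; by default it is inferred from the
    file suffix.
    """
    path = Path(path)
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in (".tsv", ".txt") else "csv"
    sep = {"csv": ",", "tsv": "\t"}[fmt]
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    rename = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in _HEADER_ALIASES:
            rename[col] = _HEADER_ALIASES[key]
    df = df.rename(columns=rename)
    missing = [m for m in MARKERS if m not in df.columns]
    if missing:
        raise CohortFormatError(
            f"{path.name}: header lacks marker columns {missing}"
        )
    if "case_id" not in df.columns:
        df.insert(0, "case_id", [f"case{i+1}" for i in range(len(df))])
    if "gep_label" in df.columns:
        df["gep_label"] = df["gep_label"].map(
            lambda v: v.strip().upper() if isinstance(v, str) else v
        )
        # GCB stays GCB; normalize case for ABC/UC too
    return Cohort(df, provenance=provenance or str(path))
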