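"""Shared domain types for treated-vs-control time-course expression studies.

A study consists of a sample design table (treatment arm, slaughter day,
batch), a probes x samples log-intensity matrix, and an optional
probe-to-gene annotation.  Regression is carried out on a log-transformed
time axis so that late sampling days (13, 27) do not dominate the fit.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TREATMENTS = ("control", "ba", "gh")
DEFAULT_DAY_GRID = (1.0, 3.0, 7.0, 13.0, 27.0)


class InputError(ValueError):
    """Raised when an input file or table violates a type invariant."""


def transform_times(days: Sequence[float] | np.ndarray) -> np.ndarray:
    """Natural-log time transform T_j = log(t_j).

    The transform compresses the spacing of the later sampling days so a
    polynomial fit weights early and late dynamics comparably.  Any
    positive scalar multiple (i.e. a different log base) rescales the axis
    without changing standardized downstream profiles.

    Parameters
    ----------
    days : sequence of positive numbers

    Returns
    -------
    numpy.ndarray of transformed times, strictly order-preserving.
    """
    arr = np.asarray(days, dtype=float)
    if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr <= 0)):
        bad = arr[~(np.isfinite(arr) & (arr > 0))]
        raise InputError(f"days must be positive and finite; offending values: {bad.tolist()}")
    return np.log(arr)


def normalize_treatment(label: str) -> str:
    """Trim whitespace and lower-case a treatment label; validate it."""
    norm = str(label).strip().lower()
    if norm not in TREATMENTS:
        raise InputError(f"unknown treatment label {label!r}; expected one of {TREATMENTS}")
    return norm


@dataclasses.dataclass(frozen=True)
class StudyDesign:
    """Sample-to-(treatment, day, batch) mapping with the transformed time scale.

    Attributes
    ----------
    frame : DataFrame with columns sample_id, treatment, day, batch,
        transformed_time; one row per sample.
    day_grid : the finite grid of sampling days.
    """

    frame: pd.DataFrame
    day_grid: tuple = DEFAULT_DAY_GRID

    def __post_init__(self):
        required = ["sample_id", "treatment", "day", "batch", "transformed_time"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise InputError(f"design frame missing columns: {missing}")
        dup = self.frame["sample_id"][self.frame["sample_id"].duplicated()]
        if len(dup):
            raise InputError(f"duplicated sample ids in design: {sorted(set(dup))}")
        bad = set(self.frame["treatment"]) - set(TREATMENTS)
        if bad:
            raise InputError(f"unknown treatment labels: {sorted(bad)}")
        if self.day_grid is not None:
            off = sorted(set(self.frame["day"]) - set(self.day_grid))
            if off:
                raise InputError(f"days outside the configured grid {self.day_grid}: {off}")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, day_grid=DEFAULT_DAY_GRID) -> "StudyDesign":
        """Build a design from a raw table, normalizing labels and filling T = log(day)."""
        f = frame.copy()
        f["sample_id"] = f["sample_id"].astype(str).str.strip()
        f["treatment"] = [normalize_treatment(t) for t in f["treatment"]]
        f["day"] = pd.to_numeric(f["day"], errors="raise").astype(float)
        f["batch"] = pd.to_numeric(f["batch"], errors="raise").astype(int)
        f["transformed_time"] = transform_times(f["day"].to_numpy())
        return cls(f.reset_index(drop=True), tuple(day_grid) if day_grid is not None else None)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def subset(self, treatments: Iterable[str]) -> "StudyDesign":
        keep = set(normalize_treatment(t) for t in treatments)
        sub = self.frame[self.frame["treatment"].isin(keep)].reset_index(drop=True)
        return StudyDesign(sub, self.day_grid)

    def samples_at(self, day: float, treatment: str) -> list[str]:
        f = self.frame
        mask = (f["day"] == float(day)) & (f["treatment"] == normalize_treatment(treatment))
        return list(f.loc[mask, "sample_id"])

    def days(self) -> np.ndarray:
        """Sorted distinct sampling days present in the design."""
        return np.sort(self.frame["day"].unique())


def read_design(path: str | Path, day_grid=DEFAULT_DAY_GRID) -> StudyDesign:
    """Read a tab-separated design table (sample_id, treatment, day, batch)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "treatment", "day", "batch"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise InputError(f"{path}: design file missing columns {missing}")
    try:
        return StudyDesign.from_frame(frame, day_grid=day_grid)
    except (ValueError, TypeError) as exc:
        raise InputError(f"{path}: {exc}") from exc


def write_design(design: StudyDesign, path: str | Path) -> None:
    cols = ["sample_id", "treatment", "day", "batch"]
    design.frame[cols].to_csv(path, sep="\t", index=False)


@dataclasses.dataclass
class ExpressionMatrix:
    """Probes x samples log-intensity matrix plus probe-to-gene annotation.

    values : DataFrame indexed by probe_id with sample ids as columns.
    annotation : Series mapping probe_id -> gene symbol ('' when unknown).
    """

    values: pd.DataFrame
    annotation: pd.Series = None

    def __post_init__(self):
        dup_p = self.values.index[self.values.index.duplicated()]
        if len(dup_p):
            raise InputError(f"duplicated probe ids: {sorted(set(dup_p))}")
        dup_s = self.values.columns[self.values.columns.duplicated()]
        if len(dup_s):
            raise InputError(f"duplicated sample ids: {sorted(set(dup_s))}")
        if self.annotation is None:
            self.annotation = pd.Series("", index=self.values.index, name="gene")
        else:
            self.annotation = self.annotation.reindex(self.values.index).fillna("")
            self.annotation.name = "gene"

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def gene_of(self, probe_id: str) -> str:
        return str(self.annotation.get(probe_id, ""))

    def drop_nonfinite(self, strict: bool = False) -> tuple["ExpressionMatrix", int]:
        """Drop probes containing non-finite values (or raise when strict).

        Returns the filtered matrix and the number of probes dropped.
        """
        finite = np.isfinite(self.values.to_numpy()).all(axis=1)
        n_bad = int((~finite).sum())
        if n_bad and strict:
            bad = list(self.values.index[~finite])[:10]
            raise InputError(f"{n_bad} probes contain non-finite values (first: {bad})")
        if n_bad == 0:
            return self, 0
        return ExpressionMatrix(self.values.loc[finite], self.annotation.loc[finite]), n_bad


def read_expression(path: str | Path, annotation_path: str | Path | None = None,
                    strict: bool = False) -> ExpressionMatrix:
    """Read a tab-separated expression matrix (first column probe id, header = sample ids).

    Probes containing non-finite values are dropped by default; ``strict=True``
    turns them into a hard error.  Parse problems are reported with the
    offending row/column.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.duplicated().any():
        dup = sorted(set(raw.index[raw.index.duplicated()]))
        raise InputError(f"{path}: duplicated probe ids {dup}")
    if raw.isna().any().any():
        r, c = np.argwhere(raw.isna().to_numpy())[0]
        raise InputError(f"{path}: ragged or missing cell at probe {raw.index[r]!r}, "
                         f"sample column {raw.columns[c]!r}")
    try:
        values = raw.astype(float)
    except ValueError:
        numeric = raw.apply(pd.to_numeric, errors="coerce")
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise InputError(f"{path}: non-numeric cell {raw.iat[r, c]!r} at probe "
                         f"{raw.index[r]!r}, sample column {raw.columns[c]!r}") from None
    annotation = None
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
        if ann.shape[1] < 2:
            raise InputError(f"{annotation_path}: expected two columns (probe_id, gene_symbol)")
        annotation = pd.Series(ann.iloc[:, 1].fillna("").values,
                               index=ann.iloc[:, 0].astype(str).values)
    em = ExpressionMatrix(values, annotation)
    em, _ = em.drop_nonfinite(strict=strict)
    return em


def write_expression(em: ExpressionMatrix, path: str | Path,
                     annotation_path: str | Path | None = None) -> None:
    """Write the matrix (and optionally the annotation) as TSV; round-trips exactly."""
    out = em.values.copy()
    out.index.name = "probe_id"
    # repr-based float formatting keeps the round-trip bit-exact
    out.to_csv(path, sep="\t", float_format=None)
    if annotation_path is not None:
        ann = em.annotation.rename("gene_symbol").to_frame()
        ann.index.name = "probe_id"
        ann.to_csv(annotation_path, sep="\t")
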