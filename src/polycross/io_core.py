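"""Dosage-matrix container, truth labels, and CSV input/output.

The central object is :class:`DosageMatrix`, the individuals x markers table
of SNP allele dosages (0..ploidy, ``NA`` for missing) with the two designated
parents of a biparental cross. Dosages are held as a float DataFrame with
``NaN`` encoding missing; every non-missing value is an integer in
``[0, ploidy]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DosageMatrix",
    "TruthLabels",
    "read_dosage_matrix",
    "write_dosage_matrix",
    "read_truth_labels",
    "write_truth_labels",
    "remove_high_missing_individuals",
]

#: Recognized truth-label categories (HS covers half-sibs of either foreign father).
LABELS = ("HP", "AC_P1", "AC_P2", "SP_P1", "SP_P2", "HS", "FC")


class DosageMatrixError(ValueError):
    """Raised when a dosage matrix violates its contract."""


@dataclass(frozen=True)
class DosageMatrix:
    """Individuals x markers allele-dosage table for a biparental cross.

    Parameters
    ----------
    data
        DataFrame indexed by individual id, columns are marker ids, values
        are float dosages in ``[0, ploidy]`` or ``NaN`` for missing.
    ploidy
        Even ploidy level (4 for tetraploids, 6 for hexaploids).
    parent1, parent2
        Row ids of the female (parent1) and male (parent2) parent.
    synthetic
        Ids of artificially injected rows (e.g. artificial clones added for
        PCA screening); excluded from genotypic analysis and reports.
    """

    data: pd.DataFrame
    ploidy: int
    parent1: str
    parent2: str
    synthetic: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.ploidy % 2 != 0 or self.ploidy < 2:
            raise DosageMatrixError(f"ploidy must be a positive even integer, got {self.ploidy}")
        idx = self.data.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise DosageMatrixError(f"duplicate individual ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise DosageMatrixError(f"duplicate marker ids: {dups}")
        if self.parent1 == self.parent2:
            raise DosageMatrixError("parent1 and parent2 must be distinct individuals")
        for p in (self.parent1, self.parent2):
            if p not in idx:
                raise DosageMatrixError(f"designated parent {p!r} not present in the matrix")
        if len(idx) < 3:
            raise DosageMatrixError("matrix needs two parents plus at least one progeny row")
        if self.data.shape[1] < 1:
            raise DosageMatrixError("matrix needs at least one marker")
        vals = self.data.to_numpy(dtype=float)
        obs = ~np.isnan(vals)
        bad = obs & ((vals < 0) | (vals > self.ploidy) | (vals != np.round(vals)))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise DosageMatrixError(
                f"invalid dosage {vals[r, c]!r} at individual {idx[r]!r}, "
                f"marker {self.data.columns[c]!r} (ploidy {self.ploidy})"
            )
        unknown = set(self.synthetic) - set(idx)
        if unknown:
            raise DosageMatrixError(f"synthetic ids not present in the matrix: {sorted(unknown)}")

    # -- convenience accessors -------------------------------------------------

    @property
    def individual_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_individuals(self) -> int:
        return self.data.shape[0]

    @property
    def n_markers(self) -> int:
        return self.data.shape[1]

    @property
    def progeny_ids(self) -> list[str]:
        """Non-parent, non-synthetic rows — the putative hybrids under test."""
        excl = {self.parent1, self.parent2, *self.synthetic}
        return [i for i in self.data.index if i not in excl]

    def parent_row(self, which: int) -> pd.Series:
        pid = self.parent1 if which == 1 else self.parent2
        return self.data.loc[pid]

    def with_data(self, data: pd.DataFrame) -> "DosageMatrix":
        return replace(self, data=data)


@dataclass(frozen=True)
class TruthLabels:
    """Ground-truth category per progeny individual (parents carry no label)."""

    labels: pd.Series  # individual id -> label
    origin: pd.Series | None = None  # optional cross-of-origin note

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - set(LABELS)
        if bad:
            raise ValueError(f"unknown truth labels: {sorted(bad)}; allowed: {LABELS}")

    def validate_against(self, matrix: DosageMatrix) -> None:
        missing = set(self.labels.index) - set(matrix.individual_ids)
        if missing:
            raise ValueError(f"labelled ids absent from the matrix: {sorted(missing)[:5]}")
        for p in (matrix.parent1, matrix.parent2):
            if p in self.labels.index:
                raise ValueError(f"parent {p!r} must not carry a truth label")


# -- CSV I/O ------------------------------------------------------------------


def read_dosage_matrix(path, ploidy: int, parent1: str, parent2: str) -> DosageMatrix:
    """Read a dosage CSV (first column ``id``, remaining columns marker ids).

    Missing dosages are encoded ``NA`` or an empty cell. Malformed cells
    raise :class:`DosageMatrixError` naming the offending row and column.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.columns[0] != "id":
        raise DosageMatrixError(f"{path}: first column must be 'id', got {df.columns[0]!r}")
    df = df.set_index("id")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        raw = df[col].str.strip()
        is_na = (raw == "NA") | (raw == "")
        try:
            vals = raw.where(~is_na, "0").astype(float)
        except ValueError:
            bad = raw[~is_na & ~raw.str.fullmatch(r"-?\d+")].index[0]
            raise DosageMatrixError(
                f"{path}: non-integer dosage at individual {bad!r}, marker {col!r}"
            ) from None
        out[col] = vals.where(~is_na, np.nan)
    return DosageMatrix(out, ploidy=ploidy, parent1=parent1, parent2=parent2)


def write_dosage_matrix(matrix: DosageMatrix, path) -> None:
    """Write a matrix to CSV; ``read_dosage_matrix`` round-trips it exactly."""
    df = matrix.data.astype("Int64")
    df.index.name = "id"
    try:
        df.to_csv(path, na_rep="NA")
    except OSError as exc:
        raise OSError(f"cannot write dosage matrix to {path}: {exc}") from exc


def read_truth_labels(path) -> TruthLabels:
    df = pd.read_csv(path, dtype=str)
    labels = pd.Series(df["label"].values, index=df["id"].values, name="label")
    origin = None
    if "origin" in df.columns:
        origin = pd.Series(df["origin"].values, index=df["id"].values, name="origin")
    return TruthLabels(labels, origin)


def write_truth_labels(truth: TruthLabels, path) -> None:
    df = pd.DataFrame({"id": truth.labels.index, "label": truth.labels.values})
    if truth.origin is not None:
        df["origin"] = truth.origin.reindex(truth.labels.index).values
    df.to_csv(path, index=False)


def remove_high_missing_individuals(
    matrix: DosageMatrix, threshold: float
) -> tuple[DosageMatrix, list[str]]:
    """Drop progeny rows whose missing-data fraction exceeds ``threshold``.

    Parents are never removed; a parent above the threshold triggers a
    warning instead. Returns the filtered matrix and the dropped ids.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    miss = matrix.data.isna().mean(axis=1)
    parents = {matrix.parent1, matrix.parent2}
    dropped = [i for i in matrix.individual_ids if miss[i] > threshold and i not in parents]
    for p in parents:
        if miss[p] > threshold:
            warnings.warn(
                f"parent {p!r} has {miss[p]:.1%} missing data (> {threshold:.0%}) "
                "but is retained as a designated parent",
                stacklevel=2,
            )
    if not dropped:
        return matrix, []
    kept = matrix.data.drop(index=dropped)
    syn = tuple(s for s in matrix.synthetic if s not in dropped)
    return DosageMatrix(kept, matrix.ploidy, matrix.parent1, matrix.parent2, syn), dropped
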