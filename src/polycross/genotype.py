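"""Mendelian genotypic-analysis (GA) scores for polyploid parentage screening.

Three per-individual scores quantify agreement between a putative hybrid and
its declared parents from allele dosages alone:

* ``GA-I``  — proportion of markers at which the individual's dosage equals a
  parent's dosage (clone detection: apomictic progeny match the mother
  everywhere, up to genotyping error).
* ``GA-II`` — proportion of the parent's *nulliplex* (dosage-0) markers at
  which the individual is also nulliplex (selfing detection: a selfed
  offspring cannot carry the alternate allele where its parent has none).
* ``GA-III`` — proportion of markers at which the individual's dosage is
  impossible under Mendelian segregation of the two declared parents
  (half-sib / unrelated-contaminant detection).

A marker contributes to a score only when every vector the score reads is
observed there; numerator and denominator shrink together, so all scores lie
in [0, 1]. A score whose denominator is empty is NaN (undefined).

Gamete dosages assume polysomic inheritance with bivalent pairing and no
double reduction: a parent of dosage ``d`` transmits between
``max(0, d - ploidy/2)`` and ``min(ploidy/2, d)`` alternate-allele copies,
and every dosage in that interval is attainable. The same rule serves
tetraploids and hexaploids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import DosageMatrix

__all__ = [
    "gamete_dosage_set",
    "expected_offspring_set",
    "ga1",
    "ga2",
    "ga3",
    "GAScoreTable",
    "compute_ga_table",
]

SCORE_COLUMNS = ("ga1_p1", "ga1_p2", "ga2_p1", "ga2_p2", "ga3")


def gamete_dosage_set(d: int, ploidy: int) -> set[int]:
    """Dosages transmissible in a gamete by a parent of dosage ``d``."""
    if ploidy % 2 != 0 or ploidy < 2:
        raise ValueError(f"ploidy must be a positive even integer, got {ploidy}")
    if not 0 <= d <= ploidy:
        raise ValueError(f"dosage {d} outside [0, {ploidy}]")
    half = ploidy // 2
    return set(range(max(0, d - half), min(half, d) + 1))


def expected_offspring_set(d1: int, d2: int, ploidy: int) -> set[int]:
    """Offspring dosages compatible with parents of dosages ``d1`` and ``d2``."""
    g1 = gamete_dosage_set(d1, ploidy)
    g2 = gamete_dosage_set(d2, ploidy)
    return {a + b for a in g1 for b in g2}


def _offspring_bounds(ploidy: int) -> tuple[np.ndarray, np.ndarray]:
    """(ploidy+1, ploidy+1) lower/upper offspring-dosage bounds per parent pair."""
    half = ploidy // 2
    d = np.arange(ploidy + 1)
    lo = np.maximum(0, d - half)
    hi = np.minimum(half, d)
    return lo[:, None] + lo[None, :], hi[:, None] + hi[None, :]


def _as_float(v) -> np.ndarray:
    return np.asarray(v, dtype=float)


def _check_lengths(*vecs: np.ndarray) -> None:
    lens = {v.shape[-1] for v in vecs}
    if len(lens) != 1:
        raise ValueError(f"marker-vector length mismatch: {sorted(lens)}")


def ga1(sample, parent) -> float:
    """Similarity of a sample to one parent over jointly observed markers."""
    s, p = _as_float(sample), _as_float(parent)
    _check_lengths(s, p)
    obs = ~np.isnan(s) & ~np.isnan(p)
    n = int(obs.sum())
    if n == 0:
        return float("nan")
    return float((s[obs] == p[obs]).sum() / n)


def ga2(sample, parent) -> float:
    """Nulliplex-restricted similarity: among markers where the parent is an
    observed nulliplex (and the sample observed), the fraction at which the
    sample is also nulliplex."""
    s, p = _as_float(sample), _as_float(parent)
    _check_lengths(s, p)
    obs = ~np.isnan(s) & ~np.isnan(p) & (p == 0)
    n = int(obs.sum())
    if n == 0:
        return float("nan")
    return float((s[obs] == 0).sum() / n)


def ga3(sample, parent1, parent2, ploidy: int) -> float:
    """Rate of Mendelian-unexpected dosages given both declared parents."""
    s, p1, p2 = _as_float(sample), _as_float(parent1), _as_float(parent2)
    _check_lengths(s, p1, p2)
    obs = ~np.isnan(s) & ~np.isnan(p1) & ~np.isnan(p2)
    n = int(obs.sum())
    if n == 0:
        return float("nan")
    lo, hi = _offspring_bounds(ploidy)
    i1 = p1[obs].astype(int)
    i2 = p2[obs].astype(int)
    sv = s[obs]
    unexpected = (sv < lo[i1, i2]) | (sv > hi[i1, i2])
    return float(unexpected.sum() / n)


@dataclass(frozen=True)
class GAScoreTable:
    """Per-progeny GA scores (five columns) plus informative-marker counts."""

    scores: pd.DataFrame  # index: progeny ids; columns: SCORE_COLUMNS
    counts: pd.DataFrame  # same shape; denominator size per score
    ploidy: int

    def __post_init__(self) -> None:
        if tuple(self.scores.columns) != SCORE_COLUMNS:
            raise ValueError(f"score columns must be {SCORE_COLUMNS}")

    @property
    def individual_ids(self) -> list[str]:
        return list(self.scores.index)

    def defined(self) -> pd.DataFrame:
        """Rows with all five scores defined (usable as clustering features)."""
        return self.scores.dropna()

    def undefined_ids(self) -> list[str]:
        return [i for i in self.scores.index if self.scores.loc[i].isna().any()]

    def to_csv(self, path) -> None:
        out = self.scores.join(self.counts.add_prefix("n_"))
        out.index.name = "id"
        out.to_csv(path)


def compute_ga_table(matrix: DosageMatrix) -> GAScoreTable:
    """Compute the five GA scores for every progeny row of the matrix.

    Synthetic rows (artificial clones injected for PCA screening) are
    excluded along with the parents.
    """
    p1 = matrix.parent_row(1).to_numpy(dtype=float)
    p2 = matrix.parent_row(2).to_numpy(dtype=float)
    if np.isnan(p1).all() or np.isnan(p2).all():
        raise ValueError("a designated parent row is entirely missing")
    prog_ids = matrix.progeny_ids
    S = matrix.data.loc[prog_ids].to_numpy(dtype=float)
    s_obs = ~np.isnan(S)

    def _sim(parent: np.ndarray, nulliplex_only: bool) -> tuple[np.ndarray, np.ndarray]:
        p_obs = ~np.isnan(parent)
        if nulliplex_only:
            p_obs = p_obs & (parent == 0)
        joint = s_obs & p_obs
        n = joint.sum(axis=1).astype(float)
        target = 0.0 if nulliplex_only else parent
        hits = ((S == target) & joint).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, hits / n, np.nan), n

    g1p1, n1p1 = _sim(p1, False)
    g1p2, n1p2 = _sim(p2, False)
    g2p1, n2p1 = _sim(p1, True)
    g2p2, n2p2 = _sim(p2, True)

    joint3 = s_obs & ~np.isnan(p1) & ~np.isnan(p2)
    n3 = joint3.sum(axis=1).astype(float)
    lo, hi = _offspring_bounds(matrix.ploidy)
    i1 = np.nan_to_num(p1).astype(int)
    i2 = np.nan_to_num(p2).astype(int)
    lo_m, hi_m = lo[i1, i2], hi[i1, i2]
    with np.errstate(invalid="ignore"):
        unexpected = ((S < lo_m) | (S > hi_m)) & joint3
    with np.errstate(invalid="ignore", divide="ignore"):
        g3 = np.where(n3 > 0, unexpected.sum(axis=1) / n3, np.nan)

    scores = pd.DataFrame(
        np.column_stack([g1p1, g1p2, g2p1, g2p2, g3]),
        index=prog_ids,
        columns=list(SCORE_COLUMNS),
    )
    counts = pd.DataFrame(
        np.column_stack([n1p1, n1p2, n2p1, n2p2, n3]).astype(int),
        index=prog_ids,
        columns=list(SCORE_COLUMNS),
    )
    return GAScoreTable(scores, counts, matrix.ploidy)
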