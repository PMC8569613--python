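"""Automatic contaminant classification from GA scores.

Pipeline: Euclidean distances on the five GA scores -> average-linkage
(UPGMA) hierarchical clustering -> cut the dendrogram at every k in a range
(default 2..15) -> each validity index votes for its optimal k -> schemes
ranked by vote count (majority rule, ties to the smaller k) -> sequential
cluster-classification rules:

1. a non-reference cluster whose median GA-I for a parent exceeds the
   threshold (default 0.75) is called apomictic clones (AC) of the parent
   with the larger median;
2. a remaining cluster whose median GA-II for a parent exceeds the threshold
   is called self-fertilization progeny (SP) of that parent;
3. a remaining cluster whose within-cluster minimum GA-III exceeds the
   maximum GA-III of the reference cluster is called half-sibs/full
   contaminants (HSFC).

The reference (true-hybrid) cluster is the one with the minimum median
GA-III; its members, and members of clusters matching no rule, are called HP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import pdist, squareform

from .genotype import GAScoreTable, SCORE_COLUMNS, compute_ga_table
from .io_core import DosageMatrix
from .indices import INDEX_BATTERY, index_value, sd_scat_dis

__all__ = [
    "ClusterScheme",
    "ContaminantReport",
    "ga_distance_matrix",
    "hierarchical_cluster",
    "rank_schemes",
    "classify_clusters",
    "detect_contaminants",
]

CALLS = ("HP", "AC_P1", "AC_P2", "SP_P1", "SP_P2", "HSFC")


@dataclass(frozen=True)
class ClusterScheme:
    """A dendrogram cut: cluster count, assignments and the votes behind it."""

    k: int
    assignment: pd.Series  # individual id -> cluster id (1..k)
    votes: dict  # index name -> k it voted for
    rank: int  # 1..3 among candidate schemes

    @property
    def n_votes(self) -> int:
        return sum(1 for v in self.votes.values() if v == self.k)


@dataclass(frozen=True)
class ContaminantReport:
    """Per-individual contaminant calls with the supporting cluster statistics."""

    calls: pd.Series  # individual id -> call in CALLS
    scheme: ClusterScheme
    cluster_medians: pd.DataFrame  # cluster id x five GA medians
    cluster_calls: dict  # cluster id -> call
    reference_cluster: int
    threshold: float

    def contaminant_ids(self) -> list[str]:
        return [i for i, c in self.calls.items() if c != "HP"]

    def to_csv(self, path) -> None:
        out = pd.DataFrame(
            {
                "id": self.calls.index,
                "call": self.calls.values,
                "cluster": self.scheme.assignment.reindex(self.calls.index).values,
                "scheme_rank": self.scheme.rank,
                "scheme_k": self.scheme.k,
            }
        )
        out.to_csv(path, index=False)


def ga_distance_matrix(table: GAScoreTable) -> pd.DataFrame:
    """Pairwise Euclidean distances between the 5-dimensional GA rows."""
    feats = table.defined()
    if len(feats) < 2:
        raise ValueError("need at least two individuals with defined GA scores")
    d = squareform(pdist(feats.to_numpy(), metric="euclidean"))
    return pd.DataFrame(d, index=feats.index, columns=feats.index)


def hierarchical_cluster(dist: pd.DataFrame) -> np.ndarray:
    """Average-linkage (UPGMA) merge tree from a square distance matrix."""
    d = dist.to_numpy()
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    return average(squareform(d, checks=False))


def rank_schemes(
    table: GAScoreTable,
    dist: pd.DataFrame,
    linkage: np.ndarray,
    k_range: range = range(2, 16),
    n_schemes: int = 3,
) -> list[ClusterScheme]:
    """Vote over dendrogram cuts and return the top-ranked schemes.

    Every validity index votes for the k at which it is optimal; candidate
    k values are ranked by vote count with ties broken toward smaller k.
    """
    ids = dist.index
    n = len(ids)
    ks = [k for k in k_range if k < n]
    if not ks:
        raise ValueError(f"not enough individuals (n={n}) for any k in {k_range}")
    X = table.defined().loc[ids].to_numpy()
    d = squareform(dist.to_numpy(), checks=False)
    cuts = {k: fcluster(linkage, t=k, criterion="maxclust") for k in ks}
    # a maxclust cut can return fewer distinct clusters than requested; such
    # duplicate partitions would double-count votes, keep first occurrence
    eff = {}
    for k in ks:
        actual = np.unique(cuts[k]).size
        if actual not in eff:
            eff[actual] = cuts[k]
    ks_eff = sorted(eff)
    values: dict[str, dict[int, float]] = {name: {} for name in INDEX_BATTERY}
    sd_parts = {}
    for k in ks_eff:
        labels = eff[k]
        for name in INDEX_BATTERY:
            values[name][k] = index_value(name, X, d, labels)
        sd_parts[k] = sd_scat_dis(X, labels)
    # SD index: alpha = Dis at the largest usable k
    alpha_k = max(k for k in ks_eff if np.isfinite(sd_parts[k][1])) if any(
        np.isfinite(sd_parts[k][1]) for k in ks_eff
    ) else None
    sd_vals = {}
    if alpha_k is not None:
        alpha = sd_parts[alpha_k][1]
        for k in ks_eff:
            scat, dis = sd_parts[k]
            sd_vals[k] = alpha * scat + dis if np.isfinite(scat) and np.isfinite(dis) else np.nan
    values["sd"] = sd_vals

    directions = {name: INDEX_BATTERY[name][1] for name in INDEX_BATTERY}
    directions["sd"] = "min"
    votes: dict[str, int] = {}
    for name, vals in values.items():
        finite = {k: v for k, v in vals.items() if np.isfinite(v)}
        if not finite:
            continue
        sign = 1 if directions[name] == "max" else -1
        votes[name] = min(finite, key=lambda k: (-sign * finite[k], k))
    tally = pd.Series(votes).value_counts()
    order = sorted(ks_eff, key=lambda k: (-int(tally.get(k, 0)), k))
    schemes = []
    for rank, k in enumerate(order[:n_schemes], start=1):
        assignment = pd.Series(eff[k], index=ids, name="cluster")
        schemes.append(ClusterScheme(k=int(np.unique(eff[k]).size), assignment=assignment,
                                     votes=dict(votes), rank=rank))
    return schemes


def classify_clusters(
    scheme: ClusterScheme, table: GAScoreTable, threshold: float = 0.75
) -> ContaminantReport:
    """Apply the sequential AC -> SP -> HSFC rules to a clustering scheme."""
    feats = table.defined().loc[scheme.assignment.index]
    if set(feats.index) != set(scheme.assignment.index):
        raise ValueError("scheme and GA table must cover the same individuals")
    lab = scheme.assignment
    clusters = sorted(lab.unique())
    med = feats.groupby(lab).median()
    sizes = lab.value_counts()
    # reference = hybrid cluster: minimum median GA-III; ties -> larger cluster
    ref = min(clusters, key=lambda c: (med.loc[c, "ga3"], -sizes[c], c))
    ref_max_ga3 = feats.loc[lab == ref, "ga3"].max()

    cluster_calls: dict[int, str] = {ref: "HP"}
    for c in clusters:
        if c == ref:
            continue
        m1p1, m1p2 = med.loc[c, "ga1_p1"], med.loc[c, "ga1_p2"]
        m2p1, m2p2 = med.loc[c, "ga2_p1"], med.loc[c, "ga2_p2"]
        if max(m1p1, m1p2) > threshold:  # rule 1: apomictic clones
            cluster_calls[c] = "AC_P1" if m1p1 >= m1p2 else "AC_P2"
        elif max(m2p1, m2p2) > threshold:  # rule 2: selfed progeny
            cluster_calls[c] = "SP_P1" if m2p1 >= m2p2 else "SP_P2"
        elif feats.loc[lab == c, "ga3"].min() > ref_max_ga3:  # rule 3
            cluster_calls[c] = "HSFC"
        else:
            cluster_calls[c] = "HP"
            warnings.warn(
                f"cluster {c} ({sizes[c]} individuals) separated from the "
                "reference cluster but matched no classification rule; "
                "calling HP",
                stacklevel=2,
            )
    calls = lab.map(cluster_calls)
    calls.name = "call"
    return ContaminantReport(
        calls=calls,
        scheme=scheme,
        cluster_medians=med,
        cluster_calls=cluster_calls,
        reference_cluster=ref,
        threshold=threshold,
    )


def detect_contaminants(
    matrix: DosageMatrix,
    threshold: float = 0.75,
    k_range: range = range(2, 16),
    n_schemes: int = 1,
) -> list[ContaminantReport]:
    """Full pipeline on a dosage matrix; returns reports for scheme ranks
    1..n_schemes (rank-1 first)."""
    table = compute_ga_table(matrix)
    undef = table.undefined_ids()
    if undef:
        warnings.warn(
            f"{len(undef)} individuals have undefined GA scores and are "
            f"excluded from clustering: {undef[:5]}...",
            stacklevel=2,
        )
    dist = ga_distance_matrix(table)
    linkage = hierarchical_cluster(dist)
    schemes = rank_schemes(table, dist, linkage, k_range=k_range,
                           n_schemes=max(n_schemes, 1))
    return [classify_clusters(s, table, threshold) for s in schemes[:n_schemes]]
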