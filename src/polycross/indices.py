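"""Cluster-validity indexes used to vote for the number of clusters.

Nine classical internal indexes, each with a documented optimization
direction. ``calinski_harabasz``, ``silhouette`` and ``davies_bouldin``
delegate to scikit-learn; the remainder are implemented here from their
standard definitions. Every function accepts the feature matrix ``X``
(n x p), the condensed pairwise distance vector ``d`` (as from
``scipy.spatial.distance.pdist``) and an integer label vector, and returns a
float or NaN when the index is undefined for that partition (e.g. no
within-cluster pairs).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn import metrics as _skm

__all__ = ["INDEX_BATTERY", "index_value"]


def _pair_masks(labels: np.ndarray) -> np.ndarray:
    """Condensed-form boolean mask of within-cluster pairs."""
    n = labels.size
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(n, k=1)
    return same[iu]


def _calinski_harabasz(X, d, labels):
    return _skm.calinski_harabasz_score(X, labels)


def _silhouette(X, d, labels):
    return _skm.silhouette_score(squareform(d), labels, metric="precomputed")


def _davies_bouldin(X, d, labels):
    return _skm.davies_bouldin_score(X, labels)


def _dunn(X, d, labels):
    """min inter-cluster distance / max intra-cluster diameter (maximize)."""
    within = _pair_masks(labels)
    if not within.any() or within.all():
        return np.nan
    diam = d[within].max()
    if diam == 0:
        return np.nan
    return d[~within].min() / diam


def _c_index(X, d, labels):
    """(Sw - Smin) / (Smax - Smin) over within-cluster pairs (minimize)."""
    within = _pair_masks(labels)
    nw = int(within.sum())
    if nw == 0:
        return np.nan
    ds = np.sort(d)
    smin, smax = ds[:nw].sum(), ds[-nw:].sum()
    if smax == smin:
        return np.nan
    return (d[within].sum() - smin) / (smax - smin)


def _mcclain_rao(X, d, labels):
    """mean within-cluster / mean between-cluster distance (minimize)."""
    within = _pair_masks(labels)
    if not within.any() or within.all():
        return np.nan
    mb = d[~within].mean()
    if mb == 0:
        return np.nan
    return d[within].mean() / mb


def _point_biserial(X, d, labels):
    """Point-biserial correlation between distances and the between-cluster
    indicator (maximize)."""
    within = _pair_masks(labels)
    nw, nb = int(within.sum()), int((~within).sum())
    if nw == 0 or nb == 0:
        return np.nan
    sd = d.std()
    if sd == 0:
        return np.nan
    nt = d.size
    return (d[~within].mean() - d[within].mean()) * np.sqrt(nw * nb / nt**2) / sd


def _gamma(X, d, labels):
    """Baker-Hubert gamma: (s+ - s-) / (s+ + s-) over (within, between)
    distance pairs (maximize). Computed by sorting, O(n^2 log n)."""
    within = _pair_masks(labels)
    w, b = d[within], np.sort(d[~within])
    if w.size == 0 or b.size == 0:
        return np.nan
    gt = b.size - np.searchsorted(b, w, side="right")  # b > w  -> concordant
    lt = np.searchsorted(b, w, side="left")  # b < w  -> discordant
    s_plus, s_minus = int(gt.sum()), int(lt.sum())
    if s_plus + s_minus == 0:
        return np.nan
    return (s_plus - s_minus) / (s_plus + s_minus)


def sd_scat_dis(X: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Scattering and total-separation terms of the SD index.

    ``SD(k) = alpha * Scat(k) + Dis(k)`` with ``alpha = Dis(k_max)``;
    the weighting across k is applied by the caller.
    """
    ks = np.unique(labels)
    tot_var = X.var(axis=0)
    tot_norm = np.linalg.norm(tot_var)
    if tot_norm == 0:
        return np.nan, np.nan
    scat = 0.0
    centroids = []
    for k in ks:
        sub = X[labels == k]
        scat += np.linalg.norm(sub.var(axis=0)) / tot_norm
        centroids.append(sub.mean(axis=0))
    scat /= ks.size
    C = np.asarray(centroids)
    cd = pdist(C)
    if cd.size == 0 or cd.min() == 0:
        return scat, np.nan
    dmax, dmin = cd.max(), cd.min()
    sq = squareform(cd)
    dis = (dmax / dmin) * np.sum(1.0 / sq.sum(axis=1))
    return scat, dis


#: name -> (function, direction); direction "max" means larger is better.
INDEX_BATTERY: dict[str, tuple] = {
    "calinski_harabasz": (_calinski_harabasz, "max"),
    "silhouette": (_silhouette, "max"),
    "dunn": (_dunn, "max"),
    "davies_bouldin": (_davies_bouldin, "min"),
    "c_index": (_c_index, "min"),
    "mcclain_rao": (_mcclain_rao, "min"),
    "point_biserial": (_point_biserial, "max"),
    "gamma": (_gamma, "max"),
    # "sd" is handled separately in detect.rank_schemes (needs k_max weighting)
}


def index_value(name: str, X: np.ndarray, d: np.ndarray, labels: np.ndarray) -> float:
    fn, _ = INDEX_BATTERY[name]
    try:
        return float(fn(X, d, labels))
    except ValueError:
        return float("nan")
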