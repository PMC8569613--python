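"""NIPALS principal component analysis with missing-value support.

NIPALS extracts components one at a time by alternating regressions of
scores on loadings and vice versa, skipping missing cells, then deflating.
On complete data it reproduces classical PCA. Columns are mean-centered over
their observed entries; no unit-variance scaling is applied (dosages share a
common scale). Component signs are fixed by forcing the largest-magnitude
loading positive so results are run-stable.

Also provides the artificial-clone trick: when contamination is too rare to
perturb the leading components, injecting simulated clones of one parent
(default 25% of the progeny count) shifts the dominant axis of variation and
pulls real clones/selfs of that parent away from the hybrid cloud in the
biplot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import DosageMatrix
from .simulate import inject_errors, inject_missing

__all__ = [
    "PCAResult",
    "nipals_pca",
    "variance_explained",
    "inject_artificial_clones",
    "export_biplot",
]


@dataclass(frozen=True)
class PCAResult:
    """Scores, loadings and per-component variance fractions from NIPALS."""

    scores: pd.DataFrame  # individuals x components
    loadings: pd.DataFrame  # markers x components
    r2: np.ndarray  # variance fraction per component
    iterations: tuple[int, ...]
    converged: tuple[bool, ...]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def nipals_pca(
    matrix: DosageMatrix,
    n_components: int = 2,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> PCAResult:
    """Iterative NIPALS decomposition of the (centered) dosage matrix."""
    X = matrix.data.to_numpy(dtype=float).copy()
    n, m = X.shape
    if n_components > min(n, m):
        raise ValueError(f"n_components={n_components} exceeds min(n, m)={min(n, m)}")
    col_obs = ~np.isnan(X)
    keep = col_obs.any(axis=0)
    if not keep.all():
        import warnings

        warnings.warn(f"dropping {int((~keep).sum())} all-missing marker columns", stacklevel=2)
        X = X[:, keep]
    marker_ids = [mid for mid, k in zip(matrix.marker_ids, keep) if k]
    obs = ~np.isnan(X)
    mu = np.nanmean(X, axis=0)
    Xc = np.where(obs, X - mu, 0.0)  # missing cells contribute 0 to regressions
    total_ss = float((Xc**2).sum())
    scores = np.zeros((n, n_components))
    loadings = np.zeros((Xc.shape[1], n_components))
    r2 = np.zeros(n_components)
    iters, conv = [], []
    for comp in range(n_components):
        t = Xc[:, int(np.argmax((Xc**2).sum(axis=0)))].copy()
        if not t.any():
            iters.append(0)
            conv.append(True)
            break
        it, ok = 0, False
        for it in range(1, max_iter + 1):
            # p_j = sum_i t_i x_ij / sum_{i: obs} t_i^2  (missing cells skipped)
            denom_p = (obs * (t**2)[:, None]).sum(axis=0)
            p = (Xc * t[:, None]).sum(axis=0) / np.where(denom_p > 0, denom_p, 1.0)
            p /= np.linalg.norm(p)
            denom_t = (obs * (p**2)[None, :]).sum(axis=1)
            t_new = (Xc * p[None, :]).sum(axis=1) / np.where(denom_t > 0, denom_t, 1.0)
            if np.linalg.norm(t_new - t) < tol * max(np.linalg.norm(t_new), 1e-30):
                t = t_new
                ok = True
                break
            t = t_new
        # sign convention: largest-|loading| positive
        j = int(np.argmax(np.abs(p)))
        if p[j] < 0:
            p, t = -p, -t
        approx = np.where(obs, np.outer(t, p), 0.0)
        r2[comp] = float((approx**2).sum()) / total_ss if total_ss > 0 else 0.0
        Xc = Xc - approx
        scores[:, comp] = t
        loadings[:, comp] = p
        iters.append(it)
        conv.append(ok)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.individual_ids, columns=cols),
        loadings=pd.DataFrame(loadings, index=marker_ids, columns=cols),
        r2=r2,
        iterations=tuple(iters),
        converged=tuple(conv),
    )


def variance_explained(result: PCAResult, k: int) -> float:
    """Fraction of total observed variance captured by the first k components."""
    if k < 0 or k > result.n_components:
        raise ValueError(f"k must be in [0, {result.n_components}], got {k}")
    return float(result.r2[:k].sum())


def inject_artificial_clones(
    matrix: DosageMatrix,
    parent: str,
    fraction: float = 0.25,
    rng: np.random.Generator | None = None,
    error_rate: float = 0.0,
    missing_range: tuple[float, float] | None = None,
) -> DosageMatrix:
    """Add ``ceil(fraction * n_progeny)`` duplicate rows of a parent.

    The added rows are tagged as synthetic, so genotypic analysis and
    contaminant reports ignore them; they only reshape the PCA dispersion.
    Optionally passes them through the simulator's error/missingness models.
    """
    if parent not in (matrix.parent1, matrix.parent2):
        raise ValueError(f"{parent!r} is not a designated parent of the matrix")
    if fraction <= 0:
        raise ValueError("fraction must be positive")
    n_add = int(np.ceil(fraction * len(matrix.progeny_ids)))
    row = matrix.data.loc[parent]
    add = pd.DataFrame(
        np.tile(row.to_numpy(dtype=float), (n_add, 1)),
        index=[f"synthclone_{parent}_{i + 1:03d}" for i in range(n_add)],
        columns=matrix.marker_ids,
    )
    out = DosageMatrix(
        pd.concat([matrix.data, add]),
        matrix.ploidy,
        matrix.parent1,
        matrix.parent2,
        synthetic=matrix.synthetic + tuple(add.index),
    )
    if error_rate > 0 or missing_range is not None:
        if rng is None:
            raise ValueError("rng required when applying error/missing models")
        if error_rate > 0:
            out = inject_errors(out, error_rate, rng)
        if missing_range is not None:
            out = inject_missing(out, missing_range, rng)
    return out


def export_biplot(result: PCAResult, labels: pd.Series | None = None, path=None):
    """Write PC1-PC2 coordinates to CSV and, if ``path`` ends in an image
    extension, a scatter plot; returns the coordinates DataFrame."""
    if result.n_components < 2:
        raise ValueError("biplot needs at least two components")
    coords = result.scores[["PC1", "PC2"]].copy()
    if labels is not None:
        coords["label"] = labels.reindex(coords.index).fillna("unlabelled")
    if path is not None:
        path = str(path)
        csv_path = path if path.endswith(".csv") else path.rsplit(".", 1)[0] + ".csv"
        coords.rename_axis("id").to_csv(csv_path)
        if path.endswith((".png", ".svg", ".pdf")):
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(6, 5))
            groups = coords.groupby("label") if "label" in coords else [("all", coords)]
            for name, sub in groups:
                ax.scatter(sub["PC1"], sub["PC2"], s=12, label=str(name))
            ax.set_xlabel(f"PC1 ({100 * result.r2[0]:.1f}%)")
            ax.set_ylabel(f"PC2 ({100 * result.r2[1]:.1f}%)")
            if "label" in coords:
                ax.legend(fontsize=7)
            fig.tight_layout()
            fig.savefig(path, dpi=150)
            plt.close(fig)
    return coords
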