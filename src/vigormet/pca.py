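"""Principal component analysis of log2 metabolite matrices.

Samples are observations (rows of the analysis matrix, e.g. 24 leaf samples)
and peaks are variables (columns, e.g. 188 peak areas). Peaks are
mean-centred by default; unit-variance autoscaling is optional. Scores,
loadings and the percent variance explained per component are returned with
a deterministic sign convention (the largest-magnitude loading of each
component is positive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from vigormet.preprocess import MetaboliteMatrix

__all__ = ["PCAResult", "run_pca", "group_separation_summary"]


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # peaks x components
    explained_pct: np.ndarray
    scaling: str  # "center" | "autoscale"

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def run_pca(
    matrix: MetaboliteMatrix, scaling: str = "center", n_components: int | None = None
) -> PCAResult:
    """Singular value decomposition of the centred samples x peaks matrix.

    ``explained_pct[k] = 100 * s_k^2 / sum(s^2)`` where ``s`` are the
    singular values of the centred (and optionally autoscaled) matrix. A
    constant matrix is an error; constant peaks are dropped with a warning
    under autoscaling (their variance cannot be rescaled to 1).
    """
    if scaling not in ("center", "autoscale"):
        raise ValueError(f"unknown scaling {scaling!r}")
    X = matrix.data.to_numpy(dtype=float).T  # samples x peaks
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 peaks")
    if np.isnan(X).any():
        raise ValueError("missing values present; impute upstream")

    peak_index = matrix.data.index
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("no variance: matrix is constant")
    if scaling == "autoscale":
        sd = X.std(axis=0, ddof=1)
        # a peak whose spread is at rounding level is constant, not signal
        constant = sd <= 1e-10 * np.maximum(np.abs(X).max(axis=0), 1.0)
        if constant.any():
            warnings.warn(
                f"dropped {int(constant.sum())} constant peak(s) under autoscaling",
                stacklevel=2,
            )
            Xc = Xc[:, ~constant]
            peak_index = peak_index[~constant]
            sd = sd[~constant]
        Xc = Xc / sd

    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(s.size):
        pivot = np.argmax(np.abs(Vt[k]))
        if Vt[k, pivot] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    explained = 100.0 * s**2 / np.sum(s**2)

    k = s.size if n_components is None else min(n_components, s.size)
    comps = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(U[:, :k] * s[:k], index=matrix.data.columns, columns=comps)
    scores.index.name = "sample"
    loadings = pd.DataFrame(Vt[:k].T, index=peak_index, columns=comps)
    return PCAResult(scores, loadings, explained[:k], scaling)


def group_separation_summary(
    result: PCAResult, sample_groups: dict[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group centroids in the PC1/PC2 plane and their pairwise distances.

    ``sample_groups`` maps each sample name to a group label (typically the
    line id). Returns (centroids, distances); the distance table is empty
    when there is a single group.
    """
    missing = set(result.scores.index) - set(sample_groups)
    if missing:
        raise ValueError(f"samples without a group: {sorted(missing)}")
    planes = result.scores[["PC1", "PC2"]] if result.n_components >= 2 else result.scores
    labels = pd.Series({s: sample_groups[s] for s in planes.index}, name="group")
    centroids = planes.groupby(labels).mean()
    centroids.index.name = "group"

    rows = []
    names = list(centroids.index)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            d = float(np.linalg.norm(centroids.loc[a] - centroids.loc[b]))
            rows.append({"group1": a, "group2": b, "distance": d})
    distances = pd.DataFrame(rows, columns=["group1", "group2", "distance"])
    return centroids, distances
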