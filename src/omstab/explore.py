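"""Exploratory structure analysis: PCA and hierarchical clustering.

Used to visualise how wastes, digestates and composts spread in the
34-variable space (the characteristic right-to-upper-left drift of treated
material: accessibility down, complexity up), to group raw wastes by origin,
and to flag multivariate outliers before modelling.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy

from .pls import ScalingSpec, _cv_groups

__all__ = ["PCAModel", "ClusterTree", "fit_pca", "hca_cluster", "flag_outliers"]


@dataclass
class PCAModel:
    """PCA on scaled variables with explained-variance and CV diagnostics."""

    n_components: int
    loadings: np.ndarray  # p x A, orthonormal columns
    scores: np.ndarray  # n x A
    r2: np.ndarray  # per component
    r2_cum: float
    q2_cum: float | None
    scaler: ScalingSpec
    singular_values: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_samples: int = 0

    def transform(self, X_new: np.ndarray) -> np.ndarray:
        Xs = self.scaler.transform(np.atleast_2d(X_new))
        return Xs @ self.loadings

    def hotelling_t2(self) -> np.ndarray:
        """Hotelling T² of each training sample over the fitted components.

        Degenerate components (zero score variance) contribute nothing.
        """
        score_var = self.scores.var(axis=0, ddof=1)
        safe = np.where(score_var > 0, score_var, np.inf)
        return np.sum(self.scores**2 / safe, axis=1)


def fit_pca(
    X: np.ndarray,
    n_components: int,
    scaling: ScalingSpec | None = None,
    cv_groups: int | None = 7,
) -> PCAModel:
    """Principal component analysis via SVD of the scaled data matrix.

    Components are ordered by decreasing explained variance; per-component
    R² is the squared singular value over the total sum of squares.  Q² is
    estimated with an element-wise grouped cross-validation: whole rows are
    left out, and each held-out cell is predicted from the *other* variables
    of its row through the loadings fitted without that row. Set
    ``cv_groups=None`` to skip the (more expensive) Q² computation.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not (1 <= n_components <= min(n - 1, p)):
        raise ValueError(
            f"n_components must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]"
        )
    scaler = (scaling or ScalingSpec()).clone_unfitted()
    Xs = scaler.fit_transform(X)
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    loadings = Vt[:n_components].T
    scores = U[:, :n_components] * s[:n_components]
    # deterministic sign: largest-magnitude loading entry positive
    for a in range(n_components):
        j = np.argmax(np.abs(loadings[:, a]))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            scores[:, a] *= -1
    total_ss = float(np.sum(Xs**2))
    r2 = (s[:n_components] ** 2) / total_ss if total_ss > 0 else np.zeros(n_components)

    q2_cum = None
    if cv_groups is not None and n >= cv_groups >= 2:
        q2_cum = _pca_q2(Xs, n_components, cv_groups, s)

    model = PCAModel(
        n_components=n_components,
        loadings=loadings,
        scores=scores,
        r2=r2,
        r2_cum=float(r2.sum()),
        q2_cum=q2_cum,
        scaler=scaler,
        singular_values=s[:n_components].copy(),
    )
    model.n_samples = n
    return model


def _pca_q2(Xs: np.ndarray, A: int, n_groups: int, s_full: np.ndarray) -> float:
    """Element-wise k-fold PCA cross-validation, multiplicative over components.

    For each held-out row and variable j, the scores are estimated by
    least squares from the row's other variables using the training-fold
    loadings truncated at a components, and cell (row, j) is reconstructed
    from those scores. PRESS_a over all held-out cells against SS_{a-1}
    (full-model residual before component a) gives the per-component ratio.
    """
    n, p = Xs.shape
    groups = _cv_groups(n, n_groups, "interleave", None)
    ss_seq = np.zeros(A + 1)
    ss_seq[0] = float(np.sum(Xs**2))
    for a in range(A):
        ss_seq[a + 1] = ss_seq[a] - s_full[a] ** 2
    press = np.zeros(A)
    for g in np.unique(groups):
        out = groups == g
        Xtr = Xs[~out]
        _, _, Vt = np.linalg.svd(Xtr - Xtr.mean(axis=0), full_matrices=False)
        for a in range(1, A + 1):
            P = Vt[:a].T  # p x a
            for row in Xs[out]:
                for j in range(p):
                    keep = np.arange(p) != j
                    t_hat, *_ = np.linalg.lstsq(P[keep], row[keep], rcond=None)
                    x_hat = P[j] @ t_hat
                    press[a - 1] += (row[j] - x_hat) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = press / ss_seq[:-1]
    return float(1.0 - np.prod(ratios))


@dataclass
class ClusterTree:
    """Agglomerative clustering result: merge history plus a flat partition."""

    linkage_matrix: np.ndarray  # scipy (n-1) x 4 format
    labels: np.ndarray  # flat assignment at the requested k
    k: int
    sample_ids: list[str] | None = None

    def cut(self, k: int) -> np.ndarray:
        """Flat assignment at another group count."""
        n = self.linkage_matrix.shape[0] + 1
        if not (1 <= k <= n):
            raise ValueError(f"k must be in [1, {n}]")
        return hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        """Nested-parentheses (Newick) text of the dendrogram, for plotting."""
        n = self.linkage_matrix.shape[0] + 1
        ids = self.sample_ids or [str(i) for i in range(n)]
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node) -> str:
            if node.is_leaf():
                return ids[node.id]
            left, right = walk(node.get_left()), walk(node.get_right())
            return f"({left},{right}):{node.dist:.6g}"

        return walk(tree) + ";"


def hca_cluster(
    X: np.ndarray,
    k: int = 5,
    scaling: ScalingSpec | None = None,
    method: str = "ward",
    sample_ids: list[str] | None = None,
) -> ClusterTree:
    """Hierarchical clustering of samples on scaled variables.

    Ward linkage on Euclidean distances of unit-variance-scaled variables is
    the default — the usual choice when variables live on very different
    scales (mg g⁻¹ carbon contents next to percentage compositions).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    if not (1 <= k <= n):
        raise ValueError(f"k={k} must be in [1, n={n}]")
    scaler = (scaling or ScalingSpec()).clone_unfitted()
    Xs = scaler.fit_transform(X)
    Z = hierarchy.linkage(Xs, method=method)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return ClusterTree(linkage_matrix=Z, labels=labels, k=k, sample_ids=sample_ids)


def flag_outliers(
    pca: PCAModel,
    confidence: float = 0.95,
    sample_ids: list[str] | None = None,
) -> list[int] | list[str]:
    """Samples outside the Hotelling-T² ellipse of the fitted PCA.

    The limit is ``A(n−1)/(n−A) · F_{A, n−A}(confidence)``.  Flags are
    advisory: nothing is removed automatically — exclusions are an explicit,
    recorded user decision in the run configuration.
    """
    if not (0.0 < confidence <= 1.0):
        raise ValueError("confidence must be in (0, 1]")
    n, A = pca.n_samples, pca.n_components
    if confidence == 1.0 or n <= A:
        return []
    t2 = pca.hotelling_t2()
    limit = A * (n - 1) / (n - A) * stats.f.ppf(confidence, A, n - A)
    idx = np.nonzero(t2 > limit)[0]
    if sample_ids is not None:
        return [sample_ids[i] for i in idx]
    return idx.tolist()
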