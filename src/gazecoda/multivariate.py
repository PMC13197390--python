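"""Compositional and classical PCA, biplot link lengths, and hierarchical
clustering of observations and of AOIs.

Compositional PCA is the singular value decomposition of the column-centred
clr matrix; its loadings are log-contrasts (each sums to zero) and the link
between two loading vertices in the covariance biplot estimates the variance
of the corresponding pairwise log-ratio. The classical track runs the same
machinery on the raw millisecond matrix. Clustering uses complete linkage
throughout, on the Aitchison metric (clr Euclidean), the raw Euclidean
metric, or — for AOIs — the variation matrix as the dissimilarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .coda import CompositionMatrix, VariationMatrix, clr_transform

__all__ = ["LinkageTree", "PcaResult", "biplot_links", "cluster_observations",
           "cluster_parts", "pca"]


@dataclass
class PcaResult:
    """SVD-derived scores (U D), loadings (columns of V) and spectrum.

    ``explained`` are variance shares lambda_k^2 / sum lambda_j^2; the
    singular-value shares lambda_k / sum lambda_j are kept in
    ``explained_singular`` for comparison with software that reports them.
    For ``mode='clr'`` the sum of lambda_k^2/(n-1) equals the total
    compositional variance of the input.
    """

    scores: np.ndarray
    loadings: np.ndarray  # (D, r), columns are loading vectors
    singular_values: np.ndarray
    explained: np.ndarray
    explained_singular: np.ndarray
    mode: str
    center: np.ndarray
    n: int
    parts: list[str]


def _center_and_mode(X: CompositionMatrix, mode: str) -> np.ndarray:
    if mode == "clr":
        return X.clr()
    if mode == "raw":
        return X.values.copy()
    raise ValueError(f"unknown PCA mode {mode!r}; use 'clr' or 'raw'")


def pca(X: CompositionMatrix, mode: str = "clr") -> PcaResult:
    """Principal components of the column-centred clr (or raw) matrix.

    The SVD sign ambiguity is fixed by flipping each loading so that its
    largest-magnitude entry is positive. Rejects degenerate input in which
    all rows are identical (rank 0 after centring).
    """
    if X.n < 2:
        raise ValueError("PCA needs at least 2 observations")
    Y = _center_and_mode(X, mode)
    center = Y.mean(axis=0)
    Yc = Y - center
    if np.allclose(Yc, 0.0, atol=1e-12):
        raise ValueError("all observations identical after centring; nothing to decompose")
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    # deterministic signs: largest-|.| entry of each loading positive
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    lam2 = s**2
    explained = lam2 / lam2.sum()
    explained_singular = s / s.sum()
    return PcaResult(
        scores=U * s,
        loadings=Vt.T,
        singular_values=s,
        explained=explained,
        explained_singular=explained_singular,
        mode=mode,
        center=center,
        n=X.n,
        parts=list(X.parts),
    )


def biplot_links(p: PcaResult, j: int, k: int, n_components: int | None = None) -> float:
    """Squared covariance-biplot link between the vertices of parts j and k.

    Vertex of part j lives at (lambda_l v_jl / sqrt(n-1))_l over the retained
    components; the squared link length estimates the variance t_jk of the
    log-ratio of parts j and k, exactly recovering it when every component
    is retained. Only defined for the clr biplot.
    """
    if p.mode != "clr":
        raise ValueError("biplot links are a clr-biplot construct; mode='raw' has none")
    r = len(p.singular_values) if n_components is None else int(n_components)
    lam = p.singular_values[:r]
    diff = p.loadings[j, :r] - p.loadings[k, :r]
    return float(np.sum((lam * diff) ** 2) / (p.n - 1))


@dataclass
class LinkageTree:
    """Complete-linkage merge tree with deterministic tie-breaking.

    ``merges`` is the SciPy linkage matrix (heights nondecreasing under
    complete linkage); ``labels`` names the leaves; ``metric`` records the
    dissimilarity used.
    """

    merges: np.ndarray
    labels: list[str]
    metric: str

    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def cut(self, n_clusters: int) -> np.ndarray:
        return hierarchy.fcluster(self.merges, t=n_clusters, criterion="maxclust")

    def to_newick(self) -> str:
        """Serialize as a Newick-style nested string with merge heights."""
        n = len(self.labels)
        nodes = {i: (self.labels[i], 0.0) for i in range(n)}
        for idx, (a, b, h, _) in enumerate(self.merges):
            sa, ha = nodes.pop(int(a))
            sb, hb = nodes.pop(int(b))
            rep = f"({sa}:{h - ha:.6g},{sb}:{h - hb:.6g})"
            nodes[n + idx] = (rep, h)
        (rep, _), = nodes.values()
        return rep + ";"


def _complete_linkage(dist: np.ndarray, labels: list[str], metric: str) -> LinkageTree:
    Z = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    return LinkageTree(Z, labels, metric)


def cluster_observations(X: CompositionMatrix, metric: str = "aitchison") -> LinkageTree:
    """Complete-linkage clustering of observations.

    ``metric='aitchison'`` works on clr coordinates (relative structure
    only — invariant to per-row rescaling); ``metric='euclidean-raw'`` on
    the raw millisecond vectors (dominated by total viewing time).
    """
    if X.n < 2:
        raise ValueError("clustering needs at least 2 observations")
    if metric == "aitchison":
        coords = X.clr()
    elif metric == "euclidean-raw":
        coords = X.values
    else:
        raise ValueError(f"unknown metric {metric!r}; use 'aitchison' or 'euclidean-raw'")
    if X.row_meta is not None and "participant" in X.row_meta.columns:
        labels = [f"{p}/{t}" for p, t in zip(X.row_meta["participant"], X.row_meta["task"])]
    else:
        labels = [str(i) for i in range(X.n)]
    dist = squareform(pdist(coords), checks=False)
    return _complete_linkage(dist, labels, metric)


def cluster_parts(V: VariationMatrix, sqrt_dissimilarity: bool = False) -> LinkageTree:
    """Complete-linkage clustering of AOIs on log-ratio variances.

    Proportional parts (t_jk ~ 0) merge first. The default dissimilarity is
    t_jk itself; set ``sqrt_dissimilarity`` to cluster on its square root
    (an actual metric, same merge order for complete linkage on monotone
    transforms of a dissimilarity).
    """
    t = np.sqrt(V.t) if sqrt_dissimilarity else V.t
    labels = V.parts or [str(j) for j in range(t.shape[0])]
    return _complete_linkage(t, list(labels), "variation")
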