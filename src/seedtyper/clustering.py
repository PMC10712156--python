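"""Peak-feature matrices, PCA and PCA-dendrograms of spectra or MSPs.

The "PCA dendrogram" of commercial biotyping suites is realized here as
average-linkage hierarchical clustering on Euclidean distances in the
space of the first ``k`` principal components (default 10) of the
peak-feature matrix.  Each sample contributes at most its 70 most intense
peaks; peaks are aligned across samples by the same greedy single-linkage
binning used for MSP construction.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .msp import bin_replicate_peaks
from .preprocessing import normalize
from .types import (
    DEFAULT_TOLERANCE,
    MainSpectrum,
    MassTolerance,
    Peak,
    PeakList,
)


def _as_peaklist(sample: Union[PeakList, MainSpectrum]) -> PeakList:
    if isinstance(sample, MainSpectrum):
        return sample.as_peaklist()
    return sample


def _label_of(sample: Union[PeakList, MainSpectrum], index: int) -> str:
    if isinstance(sample, MainSpectrum):
        return sample.label
    if sample.meta is not None:
        return sample.meta.reading_id
    return f"sample{index}"


def build_feature_matrix(
    samples: Sequence[Union[PeakList, MainSpectrum]],
    tolerance: MassTolerance = DEFAULT_TOLERANCE,
    top_n: int = 70,
    labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Align samples on consensus m/z bins; absent peaks are zeros.

    Rows are samples (labelled), columns are the intensity-weighted mean
    m/z of each consensus bin, strictly increasing.  Each sample is first
    base-peak normalized and truncated to its ``top_n`` most intense peaks.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    if labels is None:
        labels = [_label_of(s, i) for i, s in enumerate(samples)]
    if len(set(labels)) != len(labels):
        labels = [f"{lab}#{i}" for i, lab in enumerate(labels)]

    truncated: list[PeakList] = []
    for s in samples:
        pl = normalize(_as_peaklist(s), "base_peak")
        top = sorted(pl.peaks, key=lambda p: -p.intensity)[:top_n]
        truncated.append(PeakList(sorted(top, key=lambda p: p.mz)))

    bins = bin_replicate_peaks(truncated, tolerance)
    centers = np.array([b.mz for b in bins])

    matrix = np.zeros((len(samples), len(bins)))
    for i, pl in enumerate(truncated):
        for p in pl.peaks:
            j = int(np.argmin(np.abs(centers - p.mz)))
            matrix[i, j] = max(matrix[i, j], p.intensity)
    return pd.DataFrame(matrix, index=list(labels), columns=centers)


def pca(
    matrix: pd.DataFrame, n_components: int = 10
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of the (internally centered) feature matrix.

    Returns ``(coordinates, explained_variance_fractions)``.  Component
    signs are fixed by making the largest-magnitude loading positive, so
    coordinates are reproducible across runs.
    """
    X = np.asarray(matrix, dtype=float)
    k = min(n_components, X.shape[0], X.shape[1])
    model = PCA(n_components=k)
    coords = model.fit_transform(X)
    for j in range(k):
        i = int(np.argmax(np.abs(model.components_[j])))
        if model.components_[j, i] < 0:
            model.components_[j] *= -1
            coords[:, j] *= -1
    columns = [f"PC{j + 1}" for j in range(k)]
    return (
        pd.DataFrame(coords, index=matrix.index, columns=columns),
        model.explained_variance_ratio_,
    )


def _to_newick(node, labels: Sequence[str]) -> str:
    def escape(label: str) -> str:
        return label.replace(" ", "_").replace(",", "_").replace("(", "_").replace(")", "_")

    def recurse(n, parent_height: float) -> str:
        length = max(parent_height - (0.0 if n.is_leaf() else n.dist), 0.0)
        if n.is_leaf():
            length = max(parent_height, 0.0)
            return f"{escape(labels[n.id])}:{length:.6g}"
        left = recurse(n.get_left(), n.dist)
        right = recurse(n.get_right(), n.dist)
        return f"({left},{right}):{length:.6g}"

    root = node
    left = recurse(root.get_left(), root.dist)
    right = recurse(root.get_right(), root.dist)
    return f"({left},{right});"


def pca_dendrogram(
    matrix: pd.DataFrame,
    n_pcs: int = 10,
    linkage_method: str = "average",
) -> str:
    """Average-linkage tree in PC space, serialized as Newick text.

    Branch lengths derive from merge heights, so the tree is ultrametric
    (leaf depths equal the root height).
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    coords, _ = pca(matrix, n_components=n_pcs)
    Z = linkage(pdist(np.asarray(coords)), method=linkage_method)
    tree = to_tree(Z)
    return _to_newick(tree, list(matrix.index))


def linkage_matrix(
    matrix: pd.DataFrame, n_pcs: int = 10, linkage_method: str = "average"
) -> np.ndarray:
    """The scipy linkage matrix behind :func:`pca_dendrogram` (for cutting)."""
    coords, _ = pca(matrix, n_components=n_pcs)
    return linkage(pdist(np.asarray(coords)), method=linkage_method)
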