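"""Ordinations of species-mean shape data: PCA, Phy-PCA and PACA.

All three operate on the n x p matrix of flattened Procrustes coordinates
(species means). Conventional PCA eigen-decomposes the sample covariance.
The two phylogeny-aware variants first center the data at the generalized
least squares (GLS) mean implied by the Brownian covariance C of the tree:

* phylogenetic PCA (Phy-PCA) decomposes the evolutionary rate matrix
  Z' C^{-1} Z / (n - 1), so its leading components down-weight variation
  that is concentrated in closely related species;
* phylogenetically aligned component analysis (PACA) decomposes Z' C Z, so
  its leading components are the directions of shape space most aligned
  with phylogenetic signal, each scoring a share of that signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import Phylogeny
from .phylo_stats import phylo_cov
from .shape_core import ProcrustesSample

__all__ = ["Ordination", "pca", "phy_pca", "paca"]


@dataclass
class Ordination:
    method: str  # "PCA" | "PhyPCA" | "PACA"
    eigenvalues: np.ndarray  # (d,) non-increasing
    components: np.ndarray  # (p, d) loading vectors (columns)
    scores: np.ndarray  # (n, d)
    percent_explained: np.ndarray  # (d,)
    labels: list[str] = field(default_factory=list)
    percent_phylo_signal: np.ndarray | None = None  # PACA only


def _as_matrix(sample: ProcrustesSample | np.ndarray) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(sample, ProcrustesSample):
        Y = sample.coordinate_matrix()
        labels = [c.species_id for c in sample.configurations]
    else:
        Y = np.asarray(sample, dtype=float)
        labels = None  # bare arrays are taken to be in tree tip order
    if Y.ndim != 2:
        raise ValueError("expected a 2D data matrix")
    return Y, labels


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Orient each component so its largest-magnitude loading is positive."""
    flips = np.sign(components[np.argmax(np.abs(components), axis=0),
                               np.arange(components.shape[1])])
    flips[flips == 0] = 1.0
    return components * flips


def _eig_sorted(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh(0.5 * (M + M.T))
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def pca(sample: ProcrustesSample | np.ndarray) -> Ordination:
    """PCA of the covariance matrix of (flattened) shape coordinates."""
    Y, labels = _as_matrix(sample)
    n = Y.shape[0]
    if n < 2:
        raise ValueError("pca needs at least 2 observations")
    Z = Y - Y.mean(axis=0)
    cov = Z.T @ Z / (n - 1)
    vals, vecs = _eig_sorted(cov)
    d = min(n - 1, Y.shape[1])
    vals = np.clip(vals[:d], 0.0, None)
    vecs = _fix_signs(vecs[:, :d])
    total = np.sum(np.clip(np.linalg.eigvalsh(cov), 0.0, None))
    pct = 100.0 * vals / total if total > 0 else np.zeros(d)
    if labels is None:
        labels = [str(i) for i in range(n)]
    return Ordination("PCA", vals, vecs, Z @ vecs, pct, labels)


def _gls_centered(Y: np.ndarray, labels: list[str] | None, tree: Phylogeny):
    if labels is None:
        if Y.shape[0] != tree.tip_count:
            raise ValueError("row count does not match tree tip count")
        Yt = Y
    else:
        if sorted(labels) != sorted(tree.tip_labels):
            missing = set(tree.tip_labels) ^ set(labels)
            raise ValueError(f"species do not match tree tips: {sorted(missing)}")
        order = [labels.index(t) for t in tree.tip_labels]
        Yt = Y[order]
    C = phylo_cov(tree)
    Cinv = np.linalg.inv(C)
    ones = np.ones(len(Yt))
    denom = ones @ Cinv @ ones
    a = (ones @ Cinv @ Yt) / denom  # GLS mean (p,)
    Z = Yt - a
    return Z, C, Cinv, tree.tip_labels


def phy_pca(sample: ProcrustesSample | np.ndarray, tree: Phylogeny) -> Ordination:
    """Phylogenetic PCA: eigen-decomposition of the evolutionary rate matrix."""
    Y, labels = _as_matrix(sample)
    Z, _, Cinv, tip_labels = _gls_centered(Y, labels, tree)
    n = Z.shape[0]
    E = Z.T @ Cinv @ Z / (n - 1)
    vals, vecs = _eig_sorted(E)
    d = min(n - 1, Y.shape[1])
    vals = np.clip(vals[:d], 0.0, None)
    vecs = _fix_signs(vecs[:, :d])
    total = float(np.sum(np.clip(np.linalg.eigvalsh(E), 0.0, None)))
    pct = 100.0 * vals / total if total > 0 else np.zeros(d)
    return Ordination("PhyPCA", vals, vecs, Z @ vecs, pct, list(tip_labels))


def paca(sample: ProcrustesSample | np.ndarray, tree: Phylogeny) -> Ordination:
    """Phylogenetically aligned component analysis.

    Components are eigenvectors of Z' C Z (Z GLS-centered); the eigenvalue
    share of each component is reported as its percentage of phylogenetic
    signal.
    """
    Y, labels = _as_matrix(sample)
    Z, C, _, tip_labels = _gls_centered(Y, labels, tree)
    M = Z.T @ C @ Z
    vals, vecs = _eig_sorted(M)
    d = min(Z.shape[0] - 1, Y.shape[1])
    vals = np.clip(vals[:d], 0.0, None)
    vecs = _fix_signs(vecs[:, :d])
    trace = float(np.sum(np.clip(np.linalg.eigvalsh(M), 0.0, None)))
    signal = 100.0 * vals / trace if trace > 0 else np.zeros(d)
    scores = Z @ vecs
    # percent of total variance each aligned component explains
    var = np.var(scores, axis=0, ddof=1)
    tot_var = float(np.sum(np.var(Z, axis=0, ddof=1)))
    pct = 100.0 * var / tot_var if tot_var > 0 else np.zeros(d)
    return Ordination("PACA", vals, vecs, scores, pct, list(tip_labels),
                      percent_phylo_signal=signal)
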