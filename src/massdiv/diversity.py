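"""Dissimilarity, ordination and permutation vector fitting.

Molecular beta-diversity between extracts is measured with the
Bray-Curtis dissimilarity of normalized formula-intensity profiles,
embedded by principal coordinate analysis (PCoA: double-centering of
squared dissimilarities followed by eigendecomposition), and related to
external chemical/bioactivity variables by least-squares vector fitting
onto the leading ordination axes with a permutation test of r^2 — the
workflow of vegan's ``envfit``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .profiles import SampleProfile, profiles_to_matrix

__all__ = [
    "DissimilarityMatrix",
    "Ordination",
    "VectorFit",
    "bray_curtis",
    "pcoa",
    "fit_vectors",
]


@dataclass
class DissimilarityMatrix:
    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(self.data) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.data < 0) or np.any(self.data > 1 + 1e-12):
            raise ValueError("Bray-Curtis dissimilarities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g")

    def heatmap(self, path: str | Path) -> None:
        """Grayscale heatmap (black = identical, white = fully dissimilar)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(1.0 - self.data, cmap="gray", vmin=0, vmax=1)
        ax.set_xticks(range(len(self.ids)), self.ids, rotation=90, fontsize=6)
        ax.set_yticks(range(len(self.ids)), self.ids, fontsize=6)
        fig.colorbar(im, ax=ax, label="similarity (1 - Bray-Curtis)")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


@dataclass
class Ordination:
    """PCoA result: sample coordinates on positive-eigenvalue axes."""

    ids: list[str]
    coordinates: np.ndarray      # samples x retained axes
    eigenvalues: np.ndarray      # all eigenvalues, descending
    explained_pct: np.ndarray    # per retained axis, over the positive total

    @property
    def n_axes(self) -> int:
        return int(self.coordinates.shape[1])

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.n_axes)]
        return pd.DataFrame(self.coordinates, index=self.ids, columns=cols)

    def to_tsv(self, path: str | Path) -> None:
        self.scores_frame().to_csv(path, sep="\t", float_format="%.10g")


@dataclass
class VectorFit:
    """envfit-style fit of metadata vectors onto ordination axes."""

    table: pd.DataFrame          # index: vector name; columns: axis cosines, r2, p_value
    excluded: list[str]          # constant vectors, flagged and left out
    n_perm: int

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.10g")


def bray_curtis(profiles: Sequence[SampleProfile]) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarity over the profiles' common formula universe.

    d(x, y) = sum |x_i - y_i| / sum (x_i + y_i), with formulas missing
    from a profile counted as zero.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    mat = profiles_to_matrix(profiles).T.to_numpy()   # samples x formulas
    if np.any(mat.sum(axis=1) <= 0):
        raise ValueError("profile with all-zero intensities")
    d = squareform(pdist(mat, metric="braycurtis"))
    return DissimilarityMatrix([p.sample_id for p in profiles], d)


def pcoa(d: DissimilarityMatrix) -> Ordination:
    """Principal coordinate analysis of a dissimilarity matrix.

    Gower double-centering B = -1/2 J D^2 J followed by symmetric
    eigendecomposition.  Coordinates are eigenvectors scaled by the
    square root of their (positive) eigenvalues; axes with non-positive
    eigenvalues are dropped and the explained percentage is taken over
    the positive-eigenvalue total only (no Lingoes/Cailliez correction).
    """
    n = len(d.ids)
    if n < 2:
        raise ValueError("need at least two samples")
    d2 = d.data ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-12
    pos = eigval > tol
    lam = eigval[pos]
    coords = eigvec[:, pos] * np.sqrt(lam)
    explained = 100.0 * lam / lam.sum()
    return Ordination(list(d.ids), coords, eigval, explained)


def fit_vectors(
    o: Ordination,
    metadata: Mapping[str, Sequence[float]] | pd.DataFrame,
    k_axes: int = 2,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> VectorFit:
    """Fit external variables onto the first ``k_axes`` PCoA axes.

    Each (centered) metadata vector is regressed onto the axis scores;
    r^2 is the fraction of its variance explained and the direction
    cosines give the arrow orientation.  Significance comes from a
    permutation test shuffling the vector over samples:
    p = (#{r2_perm >= r2_obs} + 1) / (n_perm + 1).  Constant vectors
    are flagged and excluded.  A seeded generator makes the p-values
    reproducible; they are invariant to affine rescaling of the vector.
    """
    if isinstance(metadata, pd.DataFrame):
        meta_items = [(str(name), metadata[name].to_numpy(dtype=float))
                      for name in metadata.columns]
        if list(metadata.index) != list(o.ids) and set(metadata.index) == set(o.ids):
            metadata = metadata.loc[o.ids]
            meta_items = [(str(name), metadata[name].to_numpy(dtype=float))
                          for name in metadata.columns]
    else:
        meta_items = [(str(k), np.asarray(v, dtype=float)) for k, v in metadata.items()]
    if k_axes < 1 or k_axes > o.n_axes:
        raise ValueError(f"k_axes must be in [1, {o.n_axes}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(o.ids)
    x = o.coordinates[:, :k_axes]
    xc = x - x.mean(axis=0)
    # hat matrix of the centered axis scores (axes are orthogonal but
    # solve generally to be safe)
    hat = xc @ np.linalg.pinv(xc.T @ xc) @ xc.T

    rows = []
    excluded: list[str] = []
    for name, y in meta_items:
        y = np.asarray(y, dtype=float)
        if y.shape != (n,):
            raise ValueError(f"metadata vector {name!r} must have length {n}")
        yc = y - y.mean()
        ss_tot = float(yc @ yc)
        if ss_tot <= 0:
            excluded.append(name)
            continue
        fitted = hat @ yc
        r2 = float(fitted @ fitted) / ss_tot
        beta = np.linalg.pinv(xc.T @ xc) @ xc.T @ yc
        norm = np.linalg.norm(beta)
        cosines = beta / norm if norm > 0 else beta
        # vectorized permutation test
        perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
        yp = yc[perm_idx]                       # n_perm x n
        fitted_p = yp @ hat.T
        r2_perm = np.einsum("ij,ij->i", fitted_p, fitted_p) / np.einsum("ij,ij->i", yp, yp)
        p = (int(np.sum(r2_perm >= r2 - 1e-12)) + 1) / (n_perm + 1)
        rows.append((name, *cosines, r2, p))
    cols = ["vector", *[f"PCo{i + 1}" for i in range(k_axes)], "r2", "p_value"]
    table = pd.DataFrame(rows, columns=cols).set_index("vector")
    return VectorFit(table=table, excluded=excluded, n_perm=n_perm)
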