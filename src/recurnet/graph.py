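"""Sample-similarity graph and its un-normalized Laplacian.

Each node is a sample (labeled and unlabeled alike).  The edge weight
between two samples is the absolute Pearson correlation of their
expression vectors restricted to the informative gene set, kept only when
it strictly exceeds ``threshold_s``; absolute value is used because a
strong negative expression pattern is as informative a relationship as a
positive one, and Laplacian regularization requires non-negative weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import ExpressionDataset, UNLABELED
from .pairs import InformativePairSet, pearson

logger = logging.getLogger(__name__)


@dataclass
class SampleGraph:
    """Symmetric weighted graph over all samples, labeled nodes first.

    ``W`` is n × n, symmetric, zero-diagonal, entries in [0, 1] and either
    0 or strictly above ``threshold_s_used``.  ``y_labeled`` holds the ±1
    labels of the first ``n_labeled`` nodes (clamped during propagation).
    """

    sample_ids: list
    W: np.ndarray
    threshold_s_used: float
    n_labeled: int
    y_labeled: np.ndarray

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def unlabeled_ids(self) -> list:
        return self.sample_ids[self.n_labeled:]


@dataclass
class LaplacianPair:
    """Un-normalized graph Laplacian L = D − W with D = diag(row sums)."""

    L: np.ndarray
    D: np.ndarray


def sample_vector(ds: ExpressionDataset, sample, gene_set) -> np.ndarray:
    """Expression of one sample restricted to ``gene_set``.

    Genes are returned in the dataset's row order (canonical order), so two
    calls for the same sample are identical.
    """
    genes = list(gene_set)
    if len(genes) < 3:
        raise ValueError("gene_set must contain at least 3 genes for correlation")
    rows = sorted(ds.gene_row(g) for g in genes)
    col = ds.sample_ids.index(sample) if not isinstance(sample, (int, np.integer)) \
        else int(sample)
    return ds.matrix[rows, col]


def sample_weight(v_i, v_j, threshold_s: float) -> float:
    """|PCC| if strictly above ``threshold_s``, else 0."""
    if not 0 < threshold_s < 1:
        raise ValueError("threshold_s must lie in (0, 1)")
    w = abs(pearson(v_i, v_j))
    return w if w > threshold_s else 0.0


def _abs_corr_matrix(X: np.ndarray) -> np.ndarray:
    """Absolute column-column correlation; zero-variance columns give 0."""
    Xc = X - X.mean(axis=0, keepdims=True)
    ss = np.sqrt(np.einsum("ij,ij->j", Xc, Xc))
    ok = ss > 0
    denom = np.where(ok, ss, 1.0)
    Z = Xc / denom
    C = Z.T @ Z
    C[~ok, :] = 0.0
    C[:, ~ok] = 0.0
    np.clip(np.abs(C, out=C), 0.0, 1.0, out=C)
    return C


def weight_matrix(ds: ExpressionDataset, gene_rows: np.ndarray,
                  order: np.ndarray, threshold_s: float) -> np.ndarray:
    """Thresholded absolute-correlation weights for samples in ``order``."""
    A = _abs_corr_matrix(ds.matrix[np.ix_(gene_rows, order)])
    W = np.where(A > threshold_s, A, 0.0)
    np.fill_diagonal(W, 0.0)
    return W


def build_sample_graph(ds: ExpressionDataset, pairs: InformativePairSet,
                       threshold_s: float, labeled_mask=None) -> SampleGraph:
    """Build the full sample graph from an informative-pair gene set.

    Nodes are ordered labeled-first.  ``labeled_mask`` overrides which
    samples count as labeled (used by cross-validation to hide folds);
    default is the dataset's own labels.
    """
    if not 0 < threshold_s < 1:
        raise ValueError("threshold_s must lie in (0, 1)")
    if len(pairs.gene_set) == 0:
        raise ValueError("informative gene set is empty")
    if len(pairs.gene_set) < 3:
        raise ValueError("informative gene set must contain at least 3 genes")
    if labeled_mask is None:
        labeled_mask = ds.labels != UNLABELED
    labeled_mask = np.asarray(labeled_mask, dtype=bool)
    order = np.concatenate([np.flatnonzero(labeled_mask),
                            np.flatnonzero(~labeled_mask)])
    gene_rows = np.array(sorted(ds.gene_row(g) for g in pairs.gene_set), dtype=int)
    W = weight_matrix(ds, gene_rows, order, threshold_s)
    if not W.any():
        raise ValueError("all sample weights are zero; no graph to regularize")
    isolated = int((W.sum(axis=1) == 0).sum())
    if isolated:
        logger.info("sample graph has %d isolated node(s) at threshold_s=%.3g",
                    isolated, threshold_s)
    n_labeled = int(labeled_mask.sum())
    return SampleGraph(
        sample_ids=[ds.sample_ids[i] for i in order],
        W=W,
        threshold_s_used=float(threshold_s),
        n_labeled=n_labeled,
        y_labeled=ds.labels[order[:n_labeled]].astype(np.int8),
    )


def laplacian(g: SampleGraph) -> LaplacianPair:
    """L = D − W with D the diagonal degree matrix of W."""
    D = np.diag(g.W.sum(axis=1))
    return LaplacianPair(L=D - g.W, D=D)


def dump_graph(g: SampleGraph, path) -> None:
    """Write the non-zero edges as a TSV edge list."""
    with open(path, "w") as fh:
        fh.write("sample_i\tsample_j\tweight\n")
        for i in range(g.n):
            for j in range(i + 1, g.n):
                if g.W[i, j] > 0:
                    fh.write(f"{g.sample_ids[i]}\t{g.sample_ids[j]}\t{g.W[i, j]:.6f}\n")
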