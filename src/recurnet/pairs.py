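"""Differential co-expression scoring of PPI-connected gene pairs.

A gene pair is *informative* when its within-class co-expression changes
between the two labeled classes:

    Score(i, j) = | r(g_i^C1, g_j^C1) − r(g_i^C2, g_j^C2) |

where ``r`` is the Pearson correlation over the class's labeled samples.
Scores lie in [0, 2]; only PPI edges are scored, and only pairs with
``Score > threshold_g`` (strict) are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

from .io import ClassSplit, ExpressionDataset, PPINetwork

logger = logging.getLogger(__name__)


def pearson(x, y) -> float:
    """Product-moment correlation of two equal-length vectors.

    Degenerate (zero-variance) inputs yield 0 with a log message rather
    than NaN, so downstream thresholding stays well defined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson requires two 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError("pearson requires at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        logger.debug("zero-variance vector in pearson; returning 0")
        return 0.0
    return float((xc @ yc) / denom)


@dataclass(frozen=True, order=True)
class GenePairScore:
    """A scored gene pair; ``gene_i < gene_j`` lexicographically."""

    gene_i: str
    gene_j: str
    score: float

    def __post_init__(self):
        if self.gene_i == self.gene_j:
            raise ValueError("gene pair must join two distinct genes")

    @staticmethod
    def make(a, b, score) -> "GenePairScore":
        a, b = (a, b) if a < b else (b, a)
        return GenePairScore(a, b, float(score))


@dataclass
class InformativePairSet:
    """Informative pairs above ``threshold_g`` plus the induced gene set."""

    pairs: Tuple[GenePairScore, ...]
    threshold_g_used: float
    gene_set: tuple = field(init=False)

    def __post_init__(self):
        self.pairs = tuple(sorted(self.pairs))
        for p in self.pairs:
            if not p.score > self.threshold_g_used:
                raise ValueError(
                    f"pair {p.gene_i}-{p.gene_j} score {p.score} is not above "
                    f"threshold_g {self.threshold_g_used}"
                )
        genes = set()
        for p in self.pairs:
            genes.add(p.gene_i)
            genes.add(p.gene_j)
        self.gene_set = tuple(sorted(genes))

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def _check_split(ds: ExpressionDataset, split: ClassSplit) -> None:
    if len(split.class1_indices) < 3 or len(split.class2_indices) < 3:
        raise ValueError("each class needs at least 3 samples to score pairs")


def score_gene_pair(ds: ExpressionDataset, split: ClassSplit, gene_i, gene_j) -> float:
    """Score one pair as the absolute change of within-class correlation."""
    _check_split(ds, split)
    ri, rj = ds.gene_row(gene_i), ds.gene_row(gene_j)
    r1 = pearson(ds.matrix[ri, split.class1_indices],
                 ds.matrix[rj, split.class1_indices])
    r2 = pearson(ds.matrix[ri, split.class2_indices],
                 ds.matrix[rj, split.class2_indices])
    return abs(r1 - r2)


def _class_corr(matrix: np.ndarray, cols: np.ndarray,
                ri: np.ndarray, rj: np.ndarray) -> np.ndarray:
    """Within-class Pearson correlation for many (row_i, row_j) pairs at once.

    Zero-variance rows contribute correlation 0.
    """
    X = matrix[:, cols]
    Xc = X - X.mean(axis=1, keepdims=True)
    ss = np.sqrt(np.einsum("ij,ij->i", Xc, Xc))
    num = np.einsum("ij,ij->i", Xc[ri], Xc[rj])
    denom = ss[ri] * ss[rj]
    out = np.zeros(len(ri))
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    n_degenerate = int((~ok).sum())
    if n_degenerate:
        logger.debug("%d pair(s) with zero-variance gene set to correlation 0",
                     n_degenerate)
    return np.clip(out, -1.0, 1.0)


def score_edges(ds: ExpressionDataset, split: ClassSplit,
                ri: np.ndarray, rj: np.ndarray) -> np.ndarray:
    """Vectorised scores for edges given as parallel row-index arrays."""
    _check_split(ds, split)
    r1 = _class_corr(ds.matrix, split.class1_indices, ri, rj)
    r2 = _class_corr(ds.matrix, split.class2_indices, ri, rj)
    return np.abs(r1 - r2)


def mapped_edges(ds: ExpressionDataset, ppi: PPINetwork):
    """PPI edges whose both endpoints exist in the dataset.

    Returns (names, ri, rj) with names sorted for determinism.
    """
    names = [(a, b) for a, b in ppi.sorted_edges()
             if a in ds._gene_index and b in ds._gene_index]
    if not names:
        raise ValueError("no PPI edge maps into the expression data")
    ri = np.array([ds._gene_index[a] for a, _ in names], dtype=int)
    rj = np.array([ds._gene_index[b] for _, b in names], dtype=int)
    return names, ri, rj


def select_informative_pairs(ds: ExpressionDataset, ppi: PPINetwork,
                             split: ClassSplit, threshold_g: float
                             ) -> InformativePairSet:
    """Score every mapped PPI edge on the labeled classes and keep those
    with ``Score > threshold_g`` (strictly)."""
    if threshold_g < 0:
        raise ValueError("threshold_g must be non-negative")
    names, ri, rj = mapped_edges(ds, ppi)
    scores = score_edges(ds, split, ri, rj)
    keep = scores > threshold_g
    pairs = tuple(GenePairScore.make(a, b, s)
                  for (a, b), s, k in zip(names, scores, keep) if k)
    if not pairs:
        logger.warning("no informative pairs above threshold_g=%.3g", threshold_g)
    logger.info("selected %d/%d informative pairs at threshold_g=%.3g",
                len(pairs), len(names), threshold_g)
    return InformativePairSet(pairs=pairs, threshold_g_used=float(threshold_g))


def dump_scores(ds: ExpressionDataset, ppi: PPINetwork, split: ClassSplit,
                path) -> None:
    """Write all mapped-edge scores, sorted descending by score."""
    names, ri, rj = mapped_edges(ds, ppi)
    scores = score_edges(ds, split, ri, rj)
    order = np.argsort(-scores, kind="stable")
    with open(path, "w") as fh:
        fh.write("gene_i\tgene_j\tscore\n")
        for k in order:
            a, b = names[k]
            fh.write(f"{a}\t{b}\t{scores[k]:.6f}\n")
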