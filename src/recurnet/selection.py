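"""Threshold tuning by cross-validated grid search and self-training.

The classifier has two thresholds: ``threshold_g`` for informative-pair
selection and ``threshold_s`` for sample-graph sparsification.  They are
tuned by evaluating every grid cell with stratified k-fold cross-validation
on the labeled samples: inside each fold the fold's labels are hidden, the
pairs are re-selected on the remaining training labels only (no selection
leakage), the graph is built over *all* samples (training, hidden fold and
genuinely unlabeled), and the hidden fold is scored.

The self-training loop then alternates tuning and prediction: predicted
unlabeled samples are absorbed as newly labeled data for the next round of
tuning and pair selection, while the harmonic solve keeps clamping only the
original labels; the loop stops when the predicted labels stop changing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .graph import build_sample_graph, weight_matrix
from .io import ClassSplit, ExpressionDataset, PPINetwork, UNLABELED
from .pairs import (InformativePairSet, mapped_edges, score_edges,
                    select_informative_pairs)
from .propagation import Prediction, _harmonic, decide_cmn, decide_plain, encode

logger = logging.getLogger(__name__)

DEFAULT_G_RANGE = (0.15, 0.6, 0.05)
DEFAULT_S_RANGE = (0.72, 0.9, 0.02)


def _grid_values(lo: float, hi: float, step: float) -> np.ndarray:
    vals = np.round(np.arange(lo, hi + step / 2, step), 10)
    return vals[vals <= hi + 1e-12]


@dataclass
class ParameterGrid:
    """The two threshold grids; defaults are 0.15–0.6/0.05 × 0.72–0.9/0.02."""

    threshold_g_values: np.ndarray = field(
        default_factory=lambda: _grid_values(*DEFAULT_G_RANGE))
    threshold_s_values: np.ndarray = field(
        default_factory=lambda: _grid_values(*DEFAULT_S_RANGE))

    def __post_init__(self):
        self.threshold_g_values = np.asarray(self.threshold_g_values, dtype=float)
        self.threshold_s_values = np.asarray(self.threshold_s_values, dtype=float)
        for vals, name in ((self.threshold_g_values, "threshold_g"),
                           (self.threshold_s_values, "threshold_s")):
            if len(vals) == 0:
                raise ValueError(f"{name} grid is empty")
            if len(vals) > 1 and not (np.diff(vals) > 0).all():
                raise ValueError(f"{name} grid must be strictly increasing")

    @property
    def n_cells(self) -> int:
        return len(self.threshold_g_values) * len(self.threshold_s_values)


@dataclass
class CVResult:
    """Accuracy surface of the grid search with the winning cell."""

    grid: ParameterGrid
    mean_accuracy: np.ndarray          # (n_tg, n_ts)
    fold_accuracy: np.ndarray          # (k, n_tg, n_ts)
    best_cell: Tuple[float, float]
    k: int
    seed: int

    @property
    def best_accuracy(self) -> float:
        a = int(np.flatnonzero(self.grid.threshold_g_values == self.best_cell[0])[0])
        b = int(np.flatnonzero(self.grid.threshold_s_values == self.best_cell[1])[0])
        return float(self.mean_accuracy[a, b])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a, tg in enumerate(self.grid.threshold_g_values):
            for b, ts in enumerate(self.grid.threshold_s_values):
                rows.append((tg, ts, self.mean_accuracy[a, b]))
        return pd.DataFrame(rows, columns=["threshold_g", "threshold_s",
                                           "mean_accuracy"])


@dataclass
class SelfTrainState:
    """Snapshot of one self-training iteration."""

    iteration: int
    n_labeled: int
    best_cell: Tuple[float, float]
    cv_accuracy: float
    prediction: Prediction
    converged: bool
    pairs: Optional[InformativePairSet] = None


def stratified_folds(y, k: int, seed: int) -> List[np.ndarray]:
    """k disjoint, stratified, seeded test folds over ±1 labels ``y``.

    Returned arrays index into ``y``; they partition range(len(y)).
    """
    y = np.asarray(y)
    counts = [int((y == c).sum()) for c in (-1, 1)]
    if min(counts) < k:
        raise ValueError(
            f"smallest class has {min(counts)} samples; cannot build {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(y)), y)]


def _majority(y) -> int:
    """Majority ±1 label; ties break to −1 (non-recurrence)."""
    return 1 if (np.asarray(y) == 1).sum() > (np.asarray(y) == -1).sum() else -1


def _cv_surface(ds: ExpressionDataset, ppi: PPINetwork, grid: ParameterGrid,
                k: int, seed: int, rule: str = "cmn") -> np.ndarray:
    """Per-fold accuracy for every grid cell; shape (k, n_tg, n_ts)."""
    tg_vals = grid.threshold_g_values
    ts_vals = grid.threshold_s_values
    labeled_idx = ds.labeled_indices
    unlabeled_idx = ds.unlabeled_indices
    y_lab = ds.labels[labeled_idx]
    folds = stratified_folds(y_lab, k, seed)
    names, ri, rj = mapped_edges(ds, ppi)

    acc = np.zeros((k, len(tg_vals), len(ts_vals)))
    for f, test_pos in enumerate(folds):
        mask = np.ones(len(labeled_idx), dtype=bool)
        mask[test_pos] = False
        train_idx = labeled_idx[mask]
        test_idx = labeled_idx[test_pos]
        y_train = ds.labels[train_idx]
        y_test = ds.labels[test_idx]
        split = ClassSplit(class1_indices=train_idx[y_train == -1],
                           class2_indices=train_idx[y_train == 1])
        scores = score_edges(ds, split, ri, rj)
        majority_acc = float((y_test == _majority(y_train)).mean())
        q = float((y_train == 1).mean())
        f_l = encode(y_train)
        order = np.concatenate([train_idx, test_idx, unlabeled_idx])
        n_test = len(test_idx)
        l = len(train_idx)

        for a, tg in enumerate(tg_vals):
            keep = scores > tg
            gene_rows = np.unique(np.concatenate([ri[keep], rj[keep]])) \
                if keep.any() else np.empty(0, dtype=int)
            if len(gene_rows) < 3:
                # empty/degenerate selection: majority-class fallback
                logger.debug("fold %d threshold_g=%.3g: %d informative genes; "
                             "majority fallback", f, tg, len(gene_rows))
                acc[f, a, :] = majority_acc
                continue
            A = weight_matrix(ds, gene_rows, order, 0.0)  # |corr|, unthresholded
            for b, ts in enumerate(ts_vals):
                W = np.where(A > ts, A, 0.0)
                if not W.any():
                    acc[f, a, b] = majority_acc
                    continue
                f_u = _harmonic(W, f_l)
                pred = decide_cmn(f_u, q) if rule == "cmn" else decide_plain(f_u)
                acc[f, a, b] = float((pred[:n_test] == y_test).mean())
    return acc


def cv_cell_accuracy(ds: ExpressionDataset, ppi: PPINetwork,
                     cell: Tuple[float, float], k: int, seed: int,
                     rule: str = "cmn") -> float:
    """Mean k-fold accuracy of a single (threshold_g, threshold_s) cell."""
    grid = ParameterGrid(threshold_g_values=np.array([cell[0]]),
                         threshold_s_values=np.array([cell[1]]))
    acc = _cv_surface(ds, ppi, grid, k, seed, rule)
    return float(acc.mean(axis=0)[0, 0])


def grid_search(ds: ExpressionDataset, ppi: PPINetwork, grid: ParameterGrid,
                k: int, seed: int, rule: str = "cmn") -> CVResult:
    """Evaluate every grid cell; ties break to the smallest thresholds."""
    fold_acc = _cv_surface(ds, ppi, grid, k, seed, rule)
    mean_acc = fold_acc.mean(axis=0)
    best_val = -np.inf
    best_cell = None
    for a, tg in enumerate(grid.threshold_g_values):
        for b, ts in enumerate(grid.threshold_s_values):
            if mean_acc[a, b] > best_val:
                best_val = mean_acc[a, b]
                best_cell = (float(tg), float(ts))
    logger.info("grid search best cell threshold_g=%.3g threshold_s=%.3g "
                "(mean accuracy %.4f over %d folds)",
                best_cell[0], best_cell[1], best_val, k)
    return CVResult(grid=grid, mean_accuracy=mean_acc, fold_accuracy=fold_acc,
                    best_cell=best_cell, k=k, seed=seed)


def _predict_once(current: ExpressionDataset, orig_labeled_mask: np.ndarray,
                  ppi: PPINetwork, cell: Tuple[float, float], rule: str
                  ) -> Tuple[Prediction, Optional[InformativePairSet]]:
    """Predict the originally unlabeled samples at one threshold cell.

    Pair selection uses all *current* labels (original + absorbed); the
    harmonic solve clamps only the original labels, so absorbed samples
    remain free to change.
    """
    tg, ts = cell
    y_cur = current.labels
    split = ClassSplit(class1_indices=np.flatnonzero((y_cur == -1)),
                       class2_indices=np.flatnonzero((y_cur == 1)))
    pairs = select_informative_pairs(current, ppi, split, tg)
    unl_ids = [current.sample_ids[i] for i in np.flatnonzero(~orig_labeled_mask)]
    y_orig_lab = current.labels[orig_labeled_mask]
    q = float((y_orig_lab == 1).mean())
    if len(pairs.gene_set) < 3:
        maj = _majority(y_orig_lab)
        logger.warning("degenerate informative set at cell %s; predicting "
                       "majority class %+d", cell, maj)
        n_u = len(unl_ids)
        f = 1.0 if maj == 1 else 0.0
        return (Prediction(sample_ids=unl_ids, f_u=np.full(n_u, f),
                           labels_u=np.full(n_u, maj, dtype=np.int8),
                           decision_rule=rule), None)
    g = build_sample_graph(current, pairs, ts, labeled_mask=orig_labeled_mask)
    # y_labeled of the graph reflects current labels; re-clamp the originals
    f_u = _harmonic(g.W, encode(y_orig_lab))
    labels = decide_cmn(f_u, q) if rule == "cmn" else decide_plain(f_u)
    return (Prediction(sample_ids=list(g.unlabeled_ids), f_u=f_u,
                       labels_u=labels, decision_rule=rule), pairs)


def self_train(ds: ExpressionDataset, ppi: PPINetwork, grid: ParameterGrid,
               k: int, seed: int, max_iter: int = 10, rule: str = "cmn"
               ) -> Tuple[Prediction, List[SelfTrainState]]:
    """Iterate grid search and prediction, absorbing predicted labels.

    Converges when the predicted labels of the unlabeled samples repeat the
    previous iteration exactly; returns the final prediction and the full
    iteration history.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be at least 1")
    if len(ds.unlabeled_indices) == 0:
        raise ValueError("dataset contains no unlabeled samples to predict")
    orig_mask = ds.labeled_mask.copy()
    unl_idx = ds.unlabeled_indices
    current = ds.copy()
    history: List[SelfTrainState] = []
    prev_labels = None
    prediction = None
    for it in range(1, max_iter + 1):
        cv = grid_search(current, ppi, grid, k, seed, rule)
        prediction, pairs = _predict_once(current, orig_mask, ppi,
                                          cv.best_cell, rule)
        converged = (prev_labels is not None
                     and np.array_equal(prediction.labels_u, prev_labels))
        history.append(SelfTrainState(
            iteration=it, n_labeled=int((current.labels != UNLABELED).sum()),
            best_cell=cv.best_cell, cv_accuracy=cv.best_accuracy,
            prediction=prediction, converged=converged, pairs=pairs))
        logger.info("self-training iteration %d: cell=%s cv=%.4f converged=%s",
                    it, cv.best_cell, cv.best_accuracy, converged)
        if converged:
            break
        prev_labels = prediction.labels_u.copy()
        current.labels[unl_idx] = prediction.labels_u  # absorb
    return prediction, history


def balance_classes(ds: ExpressionDataset, seed: int) -> ExpressionDataset:
    """Randomly drop majority-class labeled samples until classes match.

    Unlabeled samples are untouched; a no-op (with a log message) when the
    classes are already balanced.
    """
    n1 = int((ds.labels == -1).sum())
    n2 = int((ds.labels == 1).sum())
    if n1 == n2:
        logger.info("classes already balanced (%d/%d); no samples removed", n1, n2)
        return ds.copy()
    majority = -1 if n1 > n2 else 1
    excess = abs(n1 - n2)
    rng = np.random.default_rng(seed)
    maj_idx = np.flatnonzero(ds.labels == majority)
    drop = set(rng.choice(maj_idx, size=excess, replace=False).tolist())
    keep = [i for i in range(ds.n_samples) if i not in drop]
    logger.info("balance: removed %d sample(s) from majority class %+d",
                excess, majority)
    return ds.subset_samples(keep)
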