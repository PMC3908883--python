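"""Harmonic label propagation with clamped labels and CMN decisions.

The estimated labels minimise the clamped quadratic cost

    J(ŷ) = Σ_{i≤l} (ŷ_i − y_i)²  +  ½ Σ_{ij} W_ij (ŷ_i − ŷ_j)²

with ŷ_l clamped to y_l, so the unlabeled block solves the harmonic system
L_uu ŷ_u = W_ul y_l.  Labels are encoded {0, 1} internally (−1 → 0,
+1 → 1) and decoded back to ±1 at the boundary.  Discrete labels come from
either the plain 0.5 rule or Class Mass Normalization (CMN), which rescales
the score mass by the labeled class proportions before comparing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .graph import LaplacianPair, SampleGraph, laplacian

logger = logging.getLogger(__name__)


@dataclass
class Prediction:
    """Continuous scores and discrete labels for the unlabeled samples."""

    sample_ids: list
    f_u: np.ndarray
    labels_u: np.ndarray
    decision_rule: str

    def __post_init__(self):
        if not (len(self.sample_ids) == len(self.f_u) == len(self.labels_u)):
            raise ValueError("prediction fields must have equal length")


def encode(y) -> np.ndarray:
    """±1 labels → {0, 1} solver space."""
    return (np.asarray(y, dtype=float) + 1.0) / 2.0


def decode(labels01) -> np.ndarray:
    return np.where(np.asarray(labels01) > 0, 1, -1).astype(np.int8)


def _harmonic(W: np.ndarray, f_l: np.ndarray) -> np.ndarray:
    """Solve the harmonic system on a labeled-first weight matrix.

    ``f_l`` are clamped values in [0, 1] for the first ``l`` nodes.
    Unlabeled nodes with no path to any labeled node receive the labeled
    prior mean.
    """
    n = W.shape[0]
    l = len(f_l)
    u = n - l
    if u == 0:
        return np.empty(0)
    # components with labeled mass
    _, comp = connected_components(csr_matrix(W > 0), directed=False)
    labeled_comps = set(comp[:l])
    unl = np.arange(l, n)
    reachable = np.array([comp[i] in labeled_comps for i in unl])
    f_u = np.full(u, float(f_l.mean()))
    n_cut = int((~reachable).sum())
    if n_cut:
        logger.debug(
            "%d unlabeled node(s) disconnected from labeled mass; "
            "assigned labeled prior mean %.3f", n_cut, f_l.mean())
    if reachable.any():
        ru = unl[reachable]
        deg = W.sum(axis=1)
        L_uu = np.diag(deg[ru]) - W[np.ix_(ru, ru)]
        b = W[np.ix_(ru, np.arange(l))] @ f_l
        try:
            f_u[reachable] = np.linalg.solve(L_uu, b)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular harmonic system after removing disconnected nodes; "
                "graph may contain zero-degree unlabeled nodes"
            ) from exc
    return f_u


def harmonic_solve(lap: LaplacianPair, y_l) -> np.ndarray:
    """Continuous scores ŷ_u for unlabeled nodes, given ±1 labels ``y_l``.

    Node order must be labeled-first; returns values in [0, 1] (up to
    solver tolerance).
    """
    y_l = np.asarray(y_l)
    if len(y_l) == 0:
        raise ValueError("no labeled samples")
    if not ((y_l == 1).any() and (y_l == -1).any()):
        raise ValueError("need at least one labeled sample of each class")
    W = lap.D - lap.L
    np.fill_diagonal(W, 0.0)
    return _harmonic(W, encode(y_l))


def decide_plain(f_u) -> np.ndarray:
    """+1 iff score strictly greater than 0.5, else −1."""
    f_u = np.asarray(f_u, dtype=float)
    return np.where(f_u > 0.5, 1, -1).astype(np.int8)


def decide_cmn(f_u, q: float) -> np.ndarray:
    """Class Mass Normalization decision.

    ``q`` is the proportion of +1 among the labeled samples.  Node i gets
    +1 iff  q·f_i/Σf  >  (1−q)·(1−f_i)/Σ(1−f)  (strict; ties → −1).
    Degenerate score mass falls back to the plain rule with a warning.
    """
    f_u = np.asarray(f_u, dtype=float)
    if not 0 < q < 1:
        raise ValueError("labeled class proportion q must lie in (0, 1)")
    pos_total = f_u.sum()
    neg_total = (1.0 - f_u).sum()
    if pos_total <= 0 or neg_total <= 0:
        logger.warning("degenerate score mass in CMN; falling back to plain rule")
        return decide_plain(f_u)
    pos = q * f_u / pos_total
    neg = (1.0 - q) * (1.0 - f_u) / neg_total
    return np.where(pos > neg, 1, -1).astype(np.int8)


def regularization_cost(g: SampleGraph, y, yhat) -> float:
    """Clamped regularization cost: fidelity + smoothness ŷᵀLŷ.

    ``y`` are encoded {0,1} targets for the first l nodes, ``yhat`` encoded
    estimates for all n nodes.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    l = len(y)
    fidelity = float(((yhat[:l] - y) ** 2).sum())
    L = laplacian(g).L
    smooth = float(yhat @ L @ yhat)
    return fidelity + smooth


def propagate(g: SampleGraph, rule: str = "cmn") -> Prediction:
    """Full propagation on a built sample graph: solve, then decide."""
    lap = laplacian(g)
    f_u = harmonic_solve(lap, g.y_labeled)
    if rule == "cmn":
        q = float((g.y_labeled == 1).mean())
        labels = decide_cmn(f_u, q)
    elif rule == "plain":
        labels = decide_plain(f_u)
    else:
        raise ValueError(f"unknown decision rule {rule!r}")
    return Prediction(sample_ids=list(g.unlabeled_ids), f_u=f_u,
                      labels_u=labels, decision_rule=rule)


def write_prediction(pred: Prediction, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tscore\tlabel\trule\n")
        for sid, f, lab in zip(pred.sample_ids, pred.f_u, pred.labels_u):
            fh.write(f"{sid}\t{f:.6f}\t{int(lab):+d}\t{pred.decision_rule}\n")
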