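"""Model/Results surface tying the pipeline together.

:class:`RecurrenceSSL` is built from an expression dataset and a PPI
network; :meth:`RecurrenceSSL.fit` runs the cross-validated threshold grid
search and the self-training loop, and returns a
:class:`RecurrenceSSLResults` carrying the chosen thresholds, the accuracy
surface, the predictions for the unlabeled samples, the selected gene
network and a ``summary()`` table.

Example
-------
>>> from recurnet import RecurrenceSSL, SimulationConfig, simulate
>>> ds, ppi, truth = simulate(SimulationConfig(seed=1))
>>> res = RecurrenceSSL(ds, ppi, k=10).fit(seed=1)
>>> print(res.summary())                        # doctest: +SKIP
>>> res.evaluate(truth).accuracy                # doctest: +SKIP
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import io, metrics
from .io import ExpressionDataset, PPINetwork
from .selection import (ParameterGrid, balance_classes, grid_search,
                        self_train)

logger = logging.getLogger(__name__)


class RecurrenceSSL:
    """Graph-regularized semi-supervised recurrence classifier.

    Parameters
    ----------
    dataset : ExpressionDataset
        Genes × samples matrix with ±1/U labels.
    ppi : PPINetwork
        Undirected gene-symbol interaction network used to restrict the
        candidate gene pairs.
    grid : ParameterGrid, optional
        Threshold grids; defaults to 0.15–0.6 (step 0.05) ×
        0.72–0.9 (step 0.02), i.e. 100 cells.
    k : int
        Cross-validation fold count (default 10).
    rule : {"cmn", "plain"}
        Decision rule for discretising propagation scores.
    balance : bool
        If true, randomly drop majority-class labeled samples to equalise
        the classes before fitting.
    max_iter : int
        Self-training iteration cap.
    """

    def __init__(self, dataset: ExpressionDataset, ppi: PPINetwork, *,
                 grid: Optional[ParameterGrid] = None, k: int = 10,
                 rule: str = "cmn", balance: bool = False, max_iter: int = 10):
        if rule not in ("cmn", "plain"):
            raise ValueError(f"unknown decision rule {rule!r}")
        self.dataset = dataset
        self.ppi = ppi
        self.grid = grid if grid is not None else ParameterGrid()
        self.k = int(k)
        self.rule = rule
        self.balance = bool(balance)
        self.max_iter = int(max_iter)

    @classmethod
    def from_files(cls, expression_path, label_path, ppi_path, **kwargs
                   ) -> "RecurrenceSSL":
        ds = io.load_expression(expression_path, label_path)
        ppi = io.load_ppi(ppi_path)
        return cls(ds, ppi, **kwargs)

    def tune(self, seed: int = 0):
        """Grid search only (no self-training); returns a CVResult."""
        ds = balance_classes(self.dataset, seed) if self.balance else self.dataset
        return grid_search(ds, self.ppi, self.grid, self.k, seed, self.rule)

    def fit(self, seed: int = 0) -> "RecurrenceSSLResults":
        """Run the full tuning + self-training pipeline."""
        ds = balance_classes(self.dataset, seed) if self.balance else self.dataset
        prediction, history = self_train(ds, self.ppi, self.grid, self.k,
                                         seed, self.max_iter, self.rule)
        return RecurrenceSSLResults(self, ds, prediction, history, seed)


class RecurrenceSSLResults:
    """Fit results: thresholds, CV surface, predictions, history."""

    def __init__(self, model: RecurrenceSSL, fitted_dataset: ExpressionDataset,
                 prediction, history, seed: int):
        self.model = model
        self.fitted_dataset = fitted_dataset
        self.prediction = prediction
        self.history = history
        self.seed = seed

    # -- estimates ------------------------------------------------------
    @property
    def params(self) -> pd.Series:
        """The tuned thresholds of the final iteration."""
        tg, ts = self.history[-1].best_cell
        return pd.Series({"threshold_g": tg, "threshold_s": ts})

    @property
    def cv_accuracy(self) -> float:
        return self.history[-1].cv_accuracy

    @property
    def converged(self) -> bool:
        return self.history[-1].converged

    @property
    def n_iter(self) -> int:
        return len(self.history)

    @property
    def informative_pairs(self):
        return self.history[-1].pairs

    @property
    def predictions(self) -> pd.DataFrame:
        p = self.prediction
        return pd.DataFrame({
            "sample_id": p.sample_ids,
            "score": p.f_u,
            "label": p.labels_u.astype(int),
            "rule": p.decision_rule,
        })

    # -- reporting ------------------------------------------------------
    def evaluate(self, truth: Mapping) -> metrics.ConfusionSummary:
        """Score the unlabeled predictions against known truth."""
        ids = self.prediction.sample_ids
        missing = [s for s in ids if s not in truth]
        if missing:
            raise ValueError(f"truth missing sample(s): {missing[:5]}")
        y = np.array([truth[s] for s in ids])
        return metrics.evaluate(self.prediction.labels_u, y,
                                scores=self.prediction.f_u)

    def export_network(self, path) -> None:
        pairs = self.informative_pairs
        if pairs is None:
            raise ValueError("final iteration selected no informative pairs")
        io.export_network(pairs, path)

    def plot_progress(self, ax=None):
        """Best mean CV accuracy across self-training iterations."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.iteration_frame()
        ax.plot(df["iteration"], df["cv_accuracy"], marker="o")
        ax.set_xlabel("self-training iteration")
        ax.set_ylabel("best mean CV accuracy")
        return ax

    def iteration_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": [s.iteration for s in self.history],
            "n_labeled": [s.n_labeled for s in self.history],
            "threshold_g": [s.best_cell[0] for s in self.history],
            "threshold_s": [s.best_cell[1] for s in self.history],
            "cv_accuracy": [s.cv_accuracy for s in self.history],
            "converged": [s.converged for s in self.history],
        })

    def summary(self) -> str:
        ds = self.fitted_dataset
        n1 = int((ds.labels == -1).sum())
        n2 = int((ds.labels == 1).sum())
        pairs = self.informative_pairs
        n_pairs = len(pairs) if pairs is not None else 0
        n_genes = len(pairs.gene_set) if pairs is not None else 0
        tg, ts = self.history[-1].best_cell
        width = 58
        lines = [
            "Graph-Regularized Semi-Supervised Recurrence Model".center(width),
            "=" * width,
            f"{'No. samples:':<24}{ds.n_samples:<10}{'No. labeled:':<16}{ds.n_labeled}",
            f"{'Class -1 / +1:':<24}{f'{n1}/{n2}':<10}{'No. unlabeled:':<16}"
            f"{ds.n_samples - ds.n_labeled}",
            f"{'PPI edges:':<24}{len(self.model.ppi):<10}{'k folds:':<16}{self.model.k}",
            f"{'Decision rule:':<24}{self.model.rule:<10}{'Balanced:':<16}"
            f"{'yes' if self.model.balance else 'no'}",
            "-" * width,
            f"{'threshold_g':<24}{tg:.2f}",
            f"{'threshold_s':<24}{ts:.2f}",
            f"{'CV accuracy':<24}{self.cv_accuracy:.3f}",
            f"{'Informative pairs':<24}{n_pairs:<10}{'genes:':<16}{n_genes}",
            f"{'Iterations':<24}{self.n_iter:<10}{'converged:':<16}"
            f"{'yes' if self.converged else 'no'}",
            "=" * width,
        ]
        return "\n".join(lines)
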