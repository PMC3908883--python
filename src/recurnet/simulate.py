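"""Synthetic two-class expression data with a PPI scaffold.

The generator reproduces the statistical structure the classifier relies
on, without any real downloads:

* *planted pairs* — gene pairs whose within-class co-expression flips sign
  between classes (+rho in class −1, −rho in class +1), so their expected
  differential-correlation score is ≈ 2·rho;
* *background genes* — independent noise, connected by uninformative PPI
  edges;
* *class profiles* — each class has its own fixed gene-profile offset
  (drawn once per class), so samples of the same class are strongly
  correlated with each other over the informative genes while samples of
  different classes are not.  This is the structure that makes the sample
  graph cluster by class.

Class labels carry no mean-shift signal usable by the pair score: the
profile offset is constant within a class and therefore does not affect
within-class correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .io import ExpressionDataset, PPINetwork, UNLABELED

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults: 200 genes of which 10 planted pairs (20 genes) carry the
    correlation-flip signal at magnitude rho = 0.8, with 100 uninformative
    background PPI edges, 50 labeled samples per class and 40 unlabeled
    samples split evenly between the classes.
    """

    n_genes: int = 200
    n_planted_pairs: int = 10
    n_labeled_per_class: int = 50
    n_unlabeled: int = 40
    rho: float = 0.8
    background_edges: int = 100
    noise_sd: float = 1.0
    class_factor_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if 2 * self.n_planted_pairs > self.n_genes:
            raise ValueError("planted pairs need 2*n_planted_pairs <= n_genes")
        if self.n_labeled_per_class < 3:
            raise ValueError("need at least 3 labeled samples per class")
        if self.noise_sd <= 0 or self.class_factor_sd < 0:
            raise ValueError("noise_sd must be positive, class_factor_sd >= 0")
        n_background_genes = self.n_genes - 2 * self.n_planted_pairs
        max_bg = n_background_genes * (n_background_genes - 1) // 2
        if self.background_edges > max_bg:
            raise ValueError(
                f"cannot place {self.background_edges} background edges among "
                f"{n_background_genes} background genes")


def _planted_block(rng, m: int, rho: float, sd: float) -> Tuple[np.ndarray, np.ndarray]:
    """m samples of a bivariate normal pair with correlation rho, sd scale."""
    z1 = rng.standard_normal(m)
    z2 = rng.standard_normal(m)
    x = z1
    y = rho * z1 + np.sqrt(1.0 - rho ** 2) * z2
    return sd * x, sd * y


def simulate(cfg: SimulationConfig
             ) -> Tuple[ExpressionDataset, PPINetwork, Dict[str, int]]:
    """Generate (dataset, PPI network, truth-for-unlabeled).

    Fully deterministic given ``cfg.seed``.  Labeled samples come first
    (all of class −1, then all of class +1), followed by unlabeled samples
    alternating −1, +1; the unlabeled truth is returned separately and the
    dataset's own labels mark them ``U``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_planted_genes = 2 * cfg.n_planted_pairs
    gene_ids = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]

    # sample bookkeeping: labeled-first, then unlabeled alternating classes
    classes = ([-1] * cfg.n_labeled_per_class + [1] * cfg.n_labeled_per_class
               + [(-1 if i % 2 == 0 else 1) for i in range(cfg.n_unlabeled)])
    classes = np.array(classes, dtype=np.int8)
    n_total = len(classes)
    sample_ids = [f"S{i + 1:04d}" for i in range(n_total)]
    labels = classes.copy()
    labels[2 * cfg.n_labeled_per_class:] = UNLABELED

    X = np.empty((cfg.n_genes, n_total))
    # class-specific gene profiles (the sample-similarity signal)
    profiles = {c: rng.normal(0.0, cfg.class_factor_sd, size=cfg.n_genes)
                for c in (-1, 1)}
    for c in (-1, 1):
        cols = np.flatnonzero(classes == c)
        m = len(cols)
        rho_c = cfg.rho if c == -1 else -cfg.rho
        noise = np.empty((cfg.n_genes, m))
        for p in range(cfg.n_planted_pairs):
            gi, gj = 2 * p, 2 * p + 1
            noise[gi], noise[gj] = _planted_block(rng, m, rho_c, cfg.noise_sd)
        noise[n_planted_genes:] = rng.normal(
            0.0, cfg.noise_sd, size=(cfg.n_genes - n_planted_genes, m))
        X[:, cols] = profiles[c][:, None] + noise

    edges = [(gene_ids[2 * p], gene_ids[2 * p + 1])
             for p in range(cfg.n_planted_pairs)]
    bg_pool = gene_ids[n_planted_genes:]
    seen = set()
    while len(seen) < cfg.background_edges:
        a, b = rng.choice(len(bg_pool), size=2, replace=False)
        e = (bg_pool[min(a, b)], bg_pool[max(a, b)])
        seen.add(e)
    edges.extend(sorted(seen))
    ppi = PPINetwork.from_pairs(edges)

    ds = ExpressionDataset(gene_ids=gene_ids, matrix=X,
                           sample_ids=sample_ids, labels=labels)
    truth = {sample_ids[i]: int(classes[i])
             for i in range(2 * cfg.n_labeled_per_class, n_total)}
    logger.info("simulated %d genes x %d samples, %d planted pairs, "
                "%d background edges (seed=%d)", cfg.n_genes, n_total,
                cfg.n_planted_pairs, cfg.background_edges, cfg.seed)
    return ds, ppi, truth


def planted_pairs(cfg: SimulationConfig) -> set:
    """The set of planted gene pairs for a config (sorted tuples)."""
    return {(f"G{2 * p + 1:04d}", f"G{2 * p + 2:04d}")
            for p in range(cfg.n_planted_pairs)}


# ---------------------------------------------------------------------------
# hand-checkable mini fixtures
# ---------------------------------------------------------------------------

def _affine_dataset(p1, a1, u1, p2, a2, u2, n_unl1, n_unl2, u_unl):
    """Samples of class c are p_c + u·a_c for scalar u; exact correlations.

    Within class c, gene g across samples is p_c[g] + a_c[g]·u, so the
    within-class correlation of two genes is exactly sign(a[i]·a[j]).
    """
    p1, a1, p2, a2 = map(np.asarray, (p1, a1, p2, a2))
    cols, labels = [], []
    for u in u1:
        cols.append(p1 + u * a1)
        labels.append(-1)
    for u in u2:
        cols.append(p2 + u * a2)
        labels.append(1)
    for i in range(n_unl1):
        cols.append(p1 + u_unl[i] * a1)
        labels.append(UNLABELED)
    for i in range(n_unl2):
        cols.append(p2 + u_unl[n_unl1 + i] * a2)
        labels.append(UNLABELED)
    X = np.column_stack(cols)
    return X, np.array(labels, dtype=np.int8)


def make_fixture(name: str):
    """Deterministic mini datasets for unit tests.

    Registry:

    ``tiny_separable``
        6 genes / 3 PPI pairs, 8 labeled (4 per class) + 4 unlabeled
        samples.  Every PPI pair scores exactly 2 (correlation +1 in class
        −1, −1 in class +1); same-class samples are near-perfectly
        correlated, cross-class samples weakly.  Truth for the unlabeled
        samples is returned.
    ``tiny_tied``
        Contains a pair whose score is exactly 0.5 (a grid value), for
        strict-inequality checks, plus a score-2 pair.
    ``tiny_disconnected``
        ``tiny_separable`` plus one unlabeled sample uncorrelated with
        both classes, isolated at threshold_s = 0.9.
    """
    if name == "tiny_separable":
        p1 = np.array([1.0, 2, 3, 4, 5, 6])
        a1 = np.ones(6)
        p2 = np.array([12.0, 2, 10, 4, 8, 6])
        a2 = np.array([1.0, -1, 1, -1, 1, -1])
        u_lab = [-1.5, -0.5, 0.5, 1.5]
        u_unl = [0.25, -0.25, 0.75, -0.75]
        X, labels = _affine_dataset(p1, a1, u_lab, p2, a2, u_lab, 2, 2, u_unl)
        genes = [f"g{i + 1}" for i in range(6)]
        samples = [f"s{i + 1}" for i in range(X.shape[1])]
        ds = ExpressionDataset(genes, X, samples, labels)
        ppi = PPINetwork.from_pairs([("g1", "g2"), ("g3", "g4"), ("g5", "g6")])
        truth = {"s9": -1, "s10": -1, "s11": 1, "s12": 1}
        return ds, ppi, truth
    if name == "tiny_tied":
        # pair (g1, g2): class1 corr 1, class2 corr 0.5 -> score exactly 0.5
        X = np.array([
            [1.0, 2, 3, 1, 2, 3],   # g1
            [1.0, 2, 3, 1, 3, 2],   # g2: corr 1 in class1, 0.5 in class2
            [1.0, 2, 3, 3, 2, 1],   # g3
            [1.0, 2, 3, 1, 2, 3],   # g4: corr 1 vs g3? see below
        ])
        # pair (g3, g4): class1 corr(g3,g4)=1, class2 corr((3,2,1),(1,2,3))=-1
        # -> score exactly 2
        labels = np.array([-1, -1, -1, 1, 1, 1], dtype=np.int8)
        genes = ["g1", "g2", "g3", "g4"]
        samples = [f"s{i + 1}" for i in range(6)]
        ds = ExpressionDataset(genes, X, samples, labels)
        ppi = PPINetwork.from_pairs([("g1", "g2"), ("g3", "g4")])
        return ds, ppi, {}
    if name == "tiny_disconnected":
        ds, ppi, truth = make_fixture("tiny_separable")
        # a direction orthogonal (after centering) to both class families:
        # every sample is p_c + u*a_c, so zero correlation with all of them
        p1 = np.array([1.0, 2, 3, 4, 5, 6])
        p2 = np.array([12.0, 2, 10, 4, 8, 6])
        a2 = np.array([1.0, -1, 1, -1, 1, -1])
        M = np.stack([np.ones(6), p1, p2, a2])
        stray = np.linalg.svd(M)[2][-1]
        X = np.column_stack([ds.matrix, stray])
        labels = np.append(ds.labels, UNLABELED).astype(np.int8)
        samples = ds.sample_ids + ["s_stray"]
        ds2 = ExpressionDataset(ds.gene_ids, X, samples, labels)
        return ds2, ppi, truth
    raise ValueError(f"unknown fixture name {name!r}")
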