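"""Differential co-expression scoring and informative-pair selection."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, strategies as st

from recurnet import (ExpressionDataset, PPINetwork, pearson, score_gene_pair,
                      select_informative_pairs)
from recurnet.pairs import GenePairScore, score_edges, mapped_edges


def pearson_oracle(x, y):
    """Textbook sum-of-products Pearson correlation (brute force)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x)
                    * sum((b - my) ** 2 for b in y))
    return num / den


class TestPearson:
    def test_identity(self):
        assert pearson([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_reflection(self):
        assert pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_brute_force_oracle(self):
        x, y = [1, 2, 3, 4], [2, 1, 4, 3]
        expected = pearson_oracle(x, y)
        assert expected == pytest.approx(0.6)  # frozen oracle value
        assert pearson(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_returns_zero(self):
        assert pearson([1, 1, 1], [1, 2, 3]) == 0.0

    def test_length_mismatch_fatal(self):
        with pytest.raises(ValueError):
            pearson([1, 2, 3], [1, 2])

    def test_too_short_fatal(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [3, 4])

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=20),
           st.integers(0, 2 ** 31 - 1))
    def test_agrees_with_numpy_on_random_vectors(self, x, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=len(x))
        x = np.asarray(x)
        if np.ptp(x) == 0:
            # constant input: zero up to centering rounding residue
            assert abs(pearson(x, y)) < 1e-8
        else:
            assume(np.std(x) > 1e-6)  # avoid catastrophic-cancellation regime
            assert pearson(x, y) == pytest.approx(
                float(np.corrcoef(x, y)[0, 1]), abs=1e-9)


def _dataset_from_class_vectors(gi_c1, gj_c1, gi_c2, gj_c2):
    X = np.array([list(gi_c1) + list(gi_c2), list(gj_c1) + list(gj_c2)],
                 dtype=float)
    n1, n2 = len(gi_c1), len(gi_c2)
    labels = np.array([-1] * n1 + [1] * n2)
    samples = [f"s{i}" for i in range(n1 + n2)]
    return ExpressionDataset(["gi", "gj"], X, samples, labels)


class TestScoreGenePair:
    def test_full_flip_scores_two(self):
        ds = _dataset_from_class_vectors([1, 2, 3, 4], [1, 2, 3, 4],
                                         [1, 2, 3, 4], [4, 3, 2, 1])
        assert score_gene_pair(ds, ds.class_split(), "gi", "gj") == \
            pytest.approx(2.0)

    def test_identical_classes_score_zero(self):
        ds = _dataset_from_class_vectors([1, 2, 3, 4], [2, 1, 4, 3],
                                         [1, 2, 3, 4], [2, 1, 4, 3])
        assert score_gene_pair(ds, ds.class_split(), "gi", "gj") == \
            pytest.approx(0.0)

    def test_matches_pcc_oracle(self):
        gi_c1, gj_c1 = [1, 2, 3, 4], [1, 2, 3, 5]
        gi_c2, gj_c2 = [1, 2, 3, 4], [4, 1, 3, 2]
        expected = abs(pearson_oracle(gi_c1, gj_c1)
                       - pearson_oracle(gi_c2, gj_c2))
        assert expected == pytest.approx(1.3827076, abs=1e-6)  # frozen
        ds = _dataset_from_class_vectors(gi_c1, gj_c1, gi_c2, gj_c2)
        assert score_gene_pair(ds, ds.class_split(), "gi", "gj") == \
            pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_bounds_random(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(6, 12))
        labels = np.array([-1] * 6 + [1] * 6)
        ds = ExpressionDataset([f"g{i}" for i in range(6)], X,
                               [f"s{i}" for i in range(12)], labels)
        split = ds.class_split()
        for i in range(6):
            for j in range(i + 1, 6):
                s_ij = score_gene_pair(ds, split, f"g{i}", f"g{j}")
                s_ji = score_gene_pair(ds, split, f"g{j}", f"g{i}")
                assert s_ij == pytest.approx(s_ji, abs=1e-12)
                assert 0.0 <= s_ij <= 2.0

    def test_absent_gene_fatal(self):
        ds = _dataset_from_class_vectors([1, 2, 3], [1, 2, 3],
                                         [1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            score_gene_pair(ds, ds.class_split(), "gi", "nope")

    def test_small_class_fatal(self):
        ds = _dataset_from_class_vectors([1, 2], [1, 2], [1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError, match="at least 3"):
            score_gene_pair(ds, ds.class_split(), "gi", "gj")


class TestSelectInformativePairs:
    def test_retains_above_threshold(self, tiny_separable):
        ds, ppi, _ = tiny_separable
        sel = select_informative_pairs(ds, ppi, ds.class_split(), 0.5)
        assert len(sel) == 3
        assert sel.gene_set == ("g1", "g2", "g3", "g4", "g5", "g6")

    def test_exact_threshold_excluded(self, tiny_tied):
        # pair (g1, g2) scores exactly 0.5 -> strict > drops it
        ds, ppi, _ = tiny_tied
        split = ds.class_split()
        assert score_gene_pair(ds, split, "g1", "g2") == pytest.approx(0.5)
        sel = select_informative_pairs(ds, ppi, split, 0.5)
        kept = {(p.gene_i, p.gene_j) for p in sel}
        assert kept == {("g3", "g4")}

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(5)
        n_genes = 30
        X = rng.normal(size=(n_genes, 24))
        labels = np.array([-1] * 12 + [1] * 12)
        genes = [f"g{i}" for i in range(n_genes)]
        ds = ExpressionDataset(genes, X, [f"s{i}" for i in range(24)], labels)
        edges = set()
        while len(edges) < 50:
            a, b = rng.integers(0, n_genes, 2)
            if a != b:
                edges.add((genes[min(a, b)], genes[max(a, b)]))
        ppi = PPINetwork.from_pairs(edges)
        split = ds.class_split()
        threshold = 0.6
        # brute-force: score every edge independently, apply the same rule
        expected = {tuple(sorted(e)) for e in edges
                    if score_gene_pair(ds, split, *e) > threshold}
        sel = select_informative_pairs(ds, ppi, split, threshold)
        assert {(p.gene_i, p.gene_j) for p in sel} == expected

    def test_monotone_in_threshold(self, tiny_separable):
        ds, ppi, _ = tiny_separable
        split = ds.class_split()
        sizes = [len(select_informative_pairs(ds, ppi, split, t))
                 for t in (0.0, 0.5, 1.0, 1.5, 1.99)]
        assert sizes == sorted(sizes, reverse=True)

    def test_no_mapped_edge_fatal(self, tiny_separable):
        ds, _, _ = tiny_separable
        foreign = PPINetwork.from_pairs([("x1", "x2")])
        with pytest.raises(ValueError, match="no PPI edge maps"):
            select_informative_pairs(ds, foreign, ds.class_split(), 0.5)

    def test_empty_selection_warns(self, tiny_separable, caplog):
        ds, ppi, _ = tiny_separable
        with caplog.at_level("WARNING"):
            sel = select_informative_pairs(ds, ppi, ds.class_split(), 2.0)
        assert len(sel) == 0 and sel.gene_set == ()

    def test_vectorised_scores_match_scalar_op(self, tiny_separable):
        ds, ppi, _ = tiny_separable
        split = ds.class_split()
        names, ri, rj = mapped_edges(ds, ppi)
        vec = score_edges(ds, split, ri, rj)
        for (a, b), s in zip(names, vec):
            assert s == pytest.approx(score_gene_pair(ds, split, a, b),
                                      abs=1e-12)


def test_gene_pair_score_rejects_self_pair():
    with pytest.raises(ValueError):
        GenePairScore.make("A", "A", 1.0)
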