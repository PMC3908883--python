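"""Core data containers and plain-text readers/writers.

Expression data are genes × samples tables (TSV, first column gene id,
header row of sample ids).  Labels live in a two-column table mapping every
sample id to one of ``-1`` (non-recurrence), ``+1`` (recurrence) or ``U``
(unlabeled).  Protein–protein interactions (PPIs) are a two-column edge
list of gene symbols; the network is undirected, deduplicated and free of
self-loops.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Internal code for an unlabeled sample.  External files use the token "U".
UNLABELED = 0

_LABEL_TOKENS = {"-1": -1, "+1": 1, "1": 1, "U": UNLABELED}

_PPI_HEADER_TOKENS = {
    "gene_a", "gene_b", "genea", "geneb", "gene1", "gene2",
    "source", "target", "protein_a", "protein_b",
}


@dataclass
class ExpressionDataset:
    """Gene-expression matrix with per-sample recurrence labels.

    Parameters
    ----------
    gene_ids : list of str
        Unique row identifiers.
    matrix : ndarray, shape (n_genes, n_samples)
        Real-valued expression, no missing entries.
    sample_ids : list of str
        Unique column identifiers.
    labels : ndarray of int8
        Per-sample label: ``-1`` non-recurrence, ``+1`` recurrence,
        ``0`` unlabeled (:data:`UNLABELED`).
    """

    gene_ids: list
    matrix: np.ndarray
    sample_ids: list
    labels: np.ndarray
    _gene_index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.matrix.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        if self.matrix.shape[0] != len(self.gene_ids):
            raise ValueError("row count does not match number of gene ids")
        if self.matrix.shape[1] != len(self.sample_ids):
            raise ValueError("column count does not match number of sample ids")
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("labels length does not match number of samples")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if self.matrix.size == 0:
            raise ValueError("empty expression matrix")
        if np.isnan(self.matrix).any():
            raise ValueError("expression matrix contains missing values")
        bad = set(np.unique(self.labels)) - {-1, 1, UNLABELED}
        if bad:
            raise ValueError(f"invalid label codes: {sorted(bad)}")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        """Total number of nodes n (labeled + unlabeled)."""
        return self.matrix.shape[1]

    @property
    def labeled_mask(self) -> np.ndarray:
        return self.labels != UNLABELED

    @property
    def labeled_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels != UNLABELED)

    @property
    def unlabeled_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels == UNLABELED)

    @property
    def n_labeled(self) -> int:
        """Number of labeled nodes l."""
        return int((self.labels != UNLABELED).sum())

    def gene_row(self, gene) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise ValueError(f"gene {gene!r} not present in dataset") from None

    def class_split(self) -> "ClassSplit":
        """Partition the labeled samples into the two classes."""
        return ClassSplit(
            class1_indices=np.flatnonzero(self.labels == -1),
            class2_indices=np.flatnonzero(self.labels == 1),
        )

    def subset_samples(self, indices: Sequence[int]) -> "ExpressionDataset":
        """New dataset restricted to the given sample positions (order kept)."""
        idx = np.asarray(indices, dtype=int)
        return ExpressionDataset(
            gene_ids=list(self.gene_ids),
            matrix=self.matrix[:, idx].copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=self.labels[idx].copy(),
        )

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            list(self.gene_ids), self.matrix.copy(),
            list(self.sample_ids), self.labels.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class ClassSplit:
    """Sample indices of the two labeled classes (class 1 = −1, class 2 = +1)."""

    class1_indices: np.ndarray
    class2_indices: np.ndarray

    def __post_init__(self):
        self.class1_indices = np.asarray(self.class1_indices, dtype=int)
        self.class2_indices = np.asarray(self.class2_indices, dtype=int)
        if len(self.class1_indices) == 0 or len(self.class2_indices) == 0:
            raise ValueError("both classes must be non-empty")
        if set(self.class1_indices) & set(self.class2_indices):
            raise ValueError("class index sets overlap")


@dataclass(frozen=True)
class PPINetwork:
    """Undirected, deduplicated protein–protein interaction network.

    Edges are stored as lexicographically sorted gene-symbol pairs.
    """

    edges: frozenset

    @classmethod
    def from_pairs(cls, pairs: Iterable) -> "PPINetwork":
        """Build a network from raw (possibly duplicated/self-loop) pairs."""
        edges = set()
        self_loops = 0
        raw = 0
        for a, b in pairs:
            raw += 1
            a, b = str(a), str(b)
            if a == b:
                self_loops += 1
                continue
            edges.add((a, b) if a < b else (b, a))
        removed = raw - self_loops - len(edges)
        if self_loops or removed:
            logger.info(
                "PPI normalisation removed %d self-loops and %d duplicate edges",
                self_loops, removed,
            )
        return cls(edges=frozenset(edges))

    @property
    def genes(self) -> set:
        out = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    def __len__(self) -> int:
        return len(self.edges)

    def sorted_edges(self) -> list:
        return sorted(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_edges_from(self.edges)
        return g


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _parse_label(token) -> int:
    tok = str(token).strip()
    if tok.upper() == "U":
        return UNLABELED
    if tok in _LABEL_TOKENS:
        return _LABEL_TOKENS[tok]
    raise ValueError(f"unknown label token {token!r}; expected -1, +1 or U")


def load_expression(path, label_path, sep: str = "\t") -> ExpressionDataset:
    """Read an expression table and its label file into a dataset.

    Rows containing missing cells are dropped (with a warning) and duplicate
    gene rows are collapsed by their mean, so the returned dataset always
    satisfies the :class:`ExpressionDataset` invariants.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    sample_header = header[1:]
    if len(set(sample_header)) != len(sample_header):
        raise ValueError("duplicated sample id in expression header")

    table = pd.read_csv(path, sep=sep, index_col=0)
    table.columns = sample_header  # undo any pandas dedup-mangling safeguards
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise ValueError("empty expression matrix")

    n_missing = int(table.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("dropping %d gene row(s) with missing values", n_missing)
        table = table.dropna(axis=0)
    if table.shape[0] == 0:
        raise ValueError("no complete gene rows left after dropping missing values")

    dup = table.index.duplicated(keep=False)
    if dup.any():
        logger.warning(
            "collapsing %d duplicated gene row(s) by mean", int(dup.sum())
        )
        table = table.groupby(level=0, sort=False).mean()

    labels = _read_labels(label_path, sep=sep)
    missing = [s for s in labels if s not in set(table.columns)]
    if missing:
        raise ValueError(f"label file references unknown sample ids: {missing[:5]}")
    unlabeled_cols = [c for c in table.columns if c not in labels]
    if unlabeled_cols:
        raise ValueError(
            f"samples missing from label file: {unlabeled_cols[:5]}"
        )
    y = np.array([labels[c] for c in table.columns], dtype=np.int8)

    ds = ExpressionDataset(
        gene_ids=list(table.index),
        matrix=table.to_numpy(dtype=float),
        sample_ids=list(table.columns),
        labels=y,
    )
    logger.info(
        "loaded expression: %d genes x %d samples (%d labeled, %d unlabeled)",
        ds.n_genes, ds.n_samples, ds.n_labeled, ds.n_samples - ds.n_labeled,
    )
    return ds


def _read_labels(path, sep: str = "\t") -> dict:
    out = {}
    with open(path) as fh:
        first = True
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split(sep)
            if len(fields) < 2:
                raise ValueError(f"malformed label line: {line!r}")
            sid, tok = fields[0].strip(), fields[1].strip()
            if first:
                first = False
                if sid.lower() in {"sample_id", "sample", "id"}:
                    continue  # header row
            if sid in out:
                raise ValueError(f"duplicate sample id in label file: {sid!r}")
            out[sid] = _parse_label(tok)
    if not out:
        raise ValueError("empty label file")
    return out


def load_ppi(path) -> PPINetwork:
    """Read a two-column gene-symbol edge list into a :class:`PPINetwork`.

    Malformed lines are skipped with a warning; lines with extra columns
    (e.g. a score column from :func:`export_network`) use the first two
    fields.  An optional header row is auto-detected.
    """
    pairs = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            fields = line.rstrip("\n").replace(",", "\t").split()
            if not fields:
                continue
            if len(fields) < 2:
                skipped += 1
                logger.warning("skipping malformed PPI line %d: %r", lineno + 1, line)
                continue
            if lineno == 0 and (
                fields[0].lower() in _PPI_HEADER_TOKENS
                or fields[1].lower() in _PPI_HEADER_TOKENS
            ):
                continue
            pairs.append((fields[0], fields[1]))
    if skipped:
        logger.warning("skipped %d malformed PPI line(s)", skipped)
    net = PPINetwork.from_pairs(pairs)
    if len(net) == 0:
        raise ValueError("PPI file yielded no usable edges")
    logger.info("loaded PPI network: %d edges over %d genes", len(net), len(net.genes))
    return net


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def export_network(pairs, path) -> None:
    """Write an informative-pair set as a scored, SIF-compatible edge list.

    Lines are ``gene_a <TAB> gene_b <TAB> score`` in lexicographic order so
    that re-exporting the same set is byte-identical.
    """
    records = sorted((p.gene_i, p.gene_j, p.score) for p in pairs.pairs)
    if not records:
        logger.warning("exporting empty informative-pair set (header-only file)")
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tscore\n")
        for a, b, s in records:
            fh.write(f"{a}\t{b}\t{s:.6f}\n")


def write_expression(ds: ExpressionDataset, path, float_format: str = "%.6f") -> None:
    ds.to_frame().to_csv(path, sep="\t", index_label="gene_id",
                         float_format=float_format)


def write_labels(ds: ExpressionDataset, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlabel\n")
        for sid, lab in zip(ds.sample_ids, ds.labels):
            tok = "U" if lab == UNLABELED else f"{int(lab):+d}"
            fh.write(f"{sid}\t{tok}\n")


def write_ppi(net: PPINetwork, path) -> None:
    with open(path, "w") as fh:
        for a, b in net.sorted_edges():
            fh.write(f"{a}\t{b}\n")


def write_truth(truth: Mapping, path) -> None:
    """Write ground-truth labels for unlabeled samples (simulation output)."""
    with open(path, "w") as fh:
        fh.write("sample_id\tlabel\n")
        for sid in truth:
            fh.write(f"{sid}\t{int(truth[sid]):+d}\n")


def read_truth(path) -> dict:
    labels = _read_labels(path)
    bad = [s for s, v in labels.items() if v == UNLABELED]
    if bad:
        raise ValueError(f"truth file contains unlabeled entries: {bad[:5]}")
    return labels
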