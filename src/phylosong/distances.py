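"""Labelled distance matrices: acoustic, sequence-based and tree-based.

The analysis compares species-by-species distance matrices from two sources:

* acoustic — per-feature matrices of absolute differences between species-mean
  feature values, min-max normalized and averaged into a mean acoustic
  distance matrix;
* genetic — uncorrected p-distances from an aligned marker gene, and
  cophenetic (patristic) distances from each tree of a bootstrap ensemble,
  averaged element-wise across the ensemble.

All matrices are represented by :class:`DistanceMatrix`, which enforces
symmetry, a zero diagonal and finiteness on construction, and aligns by
species label (never by position).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateMatrixError,
    InvalidTreeError,
    LabelAlignmentError,
    UndefinedDistanceError,
)

logger = logging.getLogger(__name__)

_SYM_ATOL = 1e-9


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric labelled distance matrix with zero diagonal.

    Parameters
    ----------
    labels : sequence of str
        Species identifiers, one per row/column, unique.
    values : (n, n) array_like
        Pairwise distances. Must be symmetric (within 1e-9), finite, with a
        zero diagonal. The stored matrix is exactly symmetrized.
    """

    labels: tuple
    values: np.ndarray = field(repr=False)

    def __init__(self, labels, values):
        labels = tuple(str(l) for l in labels)
        values = np.asarray(values, dtype=float)
        n = len(labels)
        if len(set(labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if values.shape != (n, n):
            raise ValueError(
                f"matrix shape {values.shape} does not match {n} labels"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite entries in distance matrix")
        if not np.allclose(values, values.T, atol=_SYM_ATOL, rtol=0.0):
            raise ValueError("distance matrix is not symmetric")
        if n and not np.allclose(np.diag(values), 0.0, atol=_SYM_ATOL):
            raise ValueError("distance matrix diagonal is not zero")
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)
        values.flags.writeable = False
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return len(self.labels)

    def reorder(self, labels) -> "DistanceMatrix":
        """Return a copy with rows/columns in the given label order."""
        labels = tuple(str(l) for l in labels)
        if set(labels) != set(self.labels) or len(labels) != self.n:
            missing = set(labels) - set(self.labels)
            extra = set(self.labels) - set(labels)
            raise LabelAlignmentError(
                f"label sets differ (missing: {sorted(missing)}, "
                f"extra: {sorted(extra)})",
                missing=sorted(missing),
                extra=sorted(extra),
            )
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)])

    def offdiag_upper(self) -> np.ndarray:
        """Upper-triangle off-diagonal entries as a flat vector."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="species_id")

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        # column order may differ from row order in hand-edited files
        df = df.loc[df.index, df.index]
        return cls(tuple(df.index), df.to_numpy())


def _require_same_labels(mats) -> tuple:
    labels = mats[0].labels
    for m in mats[1:]:
        if set(m.labels) != set(labels):
            missing = set(labels) - set(m.labels)
            raise LabelAlignmentError(
                f"distance matrices disagree on labels: {sorted(missing)} "
                "missing from one input",
                missing=sorted(missing),
            )
    return labels


# ---------------------------------------------------------------------------
# acoustic distances
# ---------------------------------------------------------------------------

def feature_distance_matrix(table, feature: str) -> DistanceMatrix:
    """Absolute-difference matrix of species-mean values for one feature.

    ``table`` is a :class:`~phylosong.features.SpeciesFeatureTable` (or any
    DataFrame indexed by species with the feature as a column).
    D_ij = |m_i - m_j| on the species means.
    """
    df = getattr(table, "data", table)
    if feature not in df.columns:
        raise ValueError(
            f"unknown feature {feature!r}; available: {list(df.columns)}"
        )
    m = df[feature].to_numpy(dtype=float)
    D = np.abs(m[:, None] - m[None, :])
    return DistanceMatrix(tuple(df.index.astype(str)), D)


def normalize_distance_matrix(D: DistanceMatrix, method: str = "minmax") -> DistanceMatrix:
    """Rescale off-diagonal entries to a common scale; diagonal stays zero.

    ``minmax`` (default) maps the off-diagonals onto [0, 1]; ``zscore``
    centres and scales them to unit sd. Off-diagonals only — the structural
    zero diagonal is not part of the distribution being scaled.
    """
    off = ~np.eye(D.n, dtype=bool)
    vals = D.values[off]
    V = D.values.copy()
    if method == "minmax":
        lo, hi = vals.min(), vals.max()
        if hi - lo <= 0:
            raise DegenerateMatrixError(
                "all off-diagonal distances equal; min-max normalization undefined"
            )
        V[off] = (vals - lo) / (hi - lo)
    elif method == "zscore":
        sd = vals.std(ddof=1)
        if sd <= 0:
            raise DegenerateMatrixError(
                "all off-diagonal distances equal; z-score normalization undefined"
            )
        V[off] = (vals - vals.mean()) / sd
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    np.fill_diagonal(V, 0.0)
    return DistanceMatrix(D.labels, V)


def mean_acoustic_distance(matrices) -> DistanceMatrix:
    """Element-wise mean of (normalized) per-feature distance matrices."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("need at least one distance matrix")
    labels = _require_same_labels(matrices)
    stack = np.stack([m.reorder(labels).values for m in matrices])
    return DistanceMatrix(labels, stack.mean(axis=0))


# ---------------------------------------------------------------------------
# genetic distances
# ---------------------------------------------------------------------------

_AMBIGUOUS = {"-", "N", "n", "?"}


def p_distance_matrix(alignment) -> DistanceMatrix:
    """Uncorrected pairwise p-distance from an aligned set of sequences.

    ``alignment`` maps species ID to an aligned sequence string (all equal
    length). For each pair, columns containing a gap or N in either sequence
    are excluded; the distance is mismatches / comparable sites.
    """
    items = list(alignment.items())
    if len(items) < 2:
        raise ValueError("need at least two sequences")
    labels = [str(k) for k, _ in items]
    seqs = [str(v).upper() for _, v in items]
    L = len(seqs[0])
    for lab, s in zip(labels, seqs):
        if len(s) != L:
            raise ValueError(
                f"sequence {lab!r} has length {len(s)}, expected {L}"
            )
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype="S1").reshape(
        len(seqs), L
    )
    ok = ~np.isin(arr, [b"-", b"N", b"?"])
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comp = ok[i] & ok[j]
            n_comp = int(comp.sum())
            if n_comp == 0:
                raise UndefinedDistanceError(
                    f"no comparable sites between {labels[i]!r} and {labels[j]!r}"
                )
            mism = int(np.sum(arr[i, comp] != arr[j, comp]))
            D[i, j] = D[j, i] = mism / n_comp
    return DistanceMatrix(labels, D)


def cophenetic_matrix(tree) -> DistanceMatrix:
    """Patristic (cophenetic) distances: branch-length path sums between tips."""
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise InvalidTreeError(
                f"missing branch length above node "
                f"{edge.head_node.taxon.label if edge.head_node.taxon else '<internal>'}"
            )
    pdm = tree.phylogenetic_distance_matrix()
    # shared taxon namespaces (ensembles) may hold taxa absent from this tree
    taxa = sorted(
        (leaf.taxon for leaf in tree.leaf_node_iter()), key=lambda t: t.label
    )
    labels = [t.label for t in taxa]
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            D[i, j] = D[j, i] = d
    return DistanceMatrix(labels, D)


def ensemble_mean_matrix(ensemble) -> DistanceMatrix:
    """Element-wise mean of per-tree cophenetic matrices, label-aligned.

    This is the ensemble 'back-estimate' of pairwise genetic distance: the
    cophenetic matrix of every tree in the bootstrap ensemble averaged
    entry by entry.
    """
    trees = list(ensemble)
    if not trees:
        raise ValueError("empty tree ensemble")
    mats = [cophenetic_matrix(t) for t in trees]
    labels = _require_same_labels(mats)
    stack = np.stack([m.reorder(labels).values for m in mats])
    return DistanceMatrix(labels, stack.mean(axis=0))
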