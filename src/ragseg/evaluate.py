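"""Segmentation comparison metrics from a shared sparse contingency table.

All metrics compare two integer label images A (automatic) and B (gold
standard) through the joint overlap counts n_ij = #pixels with label i in
A and label j in B, accumulated in one linear pass.  The central metric is
the variation of information

    VI(A, B) = H(A|B) + H(B|A)        (base-2 logarithms, i.e. bits)

where H(A|B) measures oversegmentation (false splits) and H(B|A)
undersegmentation (false merges).  The split-VI decomposition plotted over
merge thresholds traces the over/under tradeoff of an agglomeration: a
correct merge moves the (under, over) point downward, an incorrect merge
moves it rightward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

__all__ = [
    "ContingencyTable",
    "SplitVI",
    "ViCurve",
    "contingency_table",
    "split_vi",
    "vi",
    "rand_index",
    "adjusted_rand_index",
    "fowlkes_mallows",
    "edit_distance",
    "vi_curve",
    "entropy",
]


def entropy(p) -> float:
    """Shannon entropy in bits, with the 0·log 0 = 0 convention."""
    p = np.asarray(p, dtype=np.float64)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


@dataclass
class ContingencyTable:
    """Sparse joint label-overlap counts between two label images."""

    counts: sparse.csr_matrix  # n_ij, rows = labels of A, cols = labels of B
    row_labels: np.ndarray
    col_labels: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_sums(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    @property
    def col_sums(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()


def contingency_table(a, b, ignore_labels=(0,)) -> ContingencyTable:
    """Joint overlap counts between label images ``a`` and ``b``.

    Pixels whose label in either image is in ``ignore_labels`` are
    excluded (pass ``()`` to count everything, the default drops the
    conventional boundary label 0).
    """
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError("label images must have equal shapes")
    keep = np.ones(a.shape, dtype=bool)
    for lab in ignore_labels:
        keep &= (a != lab) & (b != lab)
    a, b = a[keep], b[keep]
    if a.size == 0:
        raise ValueError("no pixels left after applying ignore_labels")
    row_labels, ai = np.unique(a, return_inverse=True)
    col_labels, bi = np.unique(b, return_inverse=True)
    counts = sparse.coo_matrix(
        (np.ones(a.size), (ai, bi)),
        shape=(row_labels.size, col_labels.size),
    ).tocsr()
    return ContingencyTable(counts, row_labels, col_labels)


@dataclass
class SplitVI:
    """VI split into undersegmentation and oversegmentation components.

    ``under`` = H(B|A) in bits (false merges); ``over`` = H(A|B) in bits
    (false splits); their sum is VI(A, B).
    """

    under: float
    over: float

    @property
    def total(self) -> float:
        return self.under + self.over

    def __iter__(self):
        return iter((self.under, self.over))


def _split_vi_from_table(table: ContingencyTable) -> SplitVI:
    n = table.n
    coo = table.counts.tocoo()
    pij = coo.data / n
    pa = table.row_sums / n  # marginal of A
    pb = table.col_sums / n  # marginal of B
    # H(A|B) = -sum p_ij log2(p_ij / p_bj): oversegmentation / false splits
    over = float(-np.sum(pij * np.log2(pij / pb[coo.col])))
    # H(B|A): undersegmentation / false merges
    under = float(-np.sum(pij * np.log2(pij / pa[coo.row])))
    # conditional entropies are >= 0; drop floating-point negative zeros
    return SplitVI(under=max(0.0, under), over=max(0.0, over))


def split_vi(a, b, ignore_labels=(0,)) -> SplitVI:
    """Split variation of information between automatic ``a`` and gold ``b``.

    Returns the (under, over) = (H(B|A), H(A|B)) pair in bits, computed
    from the sparse contingency table in O(n_pixels) time.
    """
    return _split_vi_from_table(contingency_table(a, b, ignore_labels))


def vi(a, b, ignore_labels=(0,)) -> float:
    """Variation of information VI(A,B) = H(A|B) + H(B|A), in bits."""
    return split_vi(a, b, ignore_labels).total


def _pair_counts(table: ContingencyTable):
    """Closed-form co-assignment pair counts from the table.

    Returns (TP, pairs_a, pairs_b, total_pairs): pairs together in both,
    together in A, together in B, and all pixel pairs.
    """
    nij = table.counts.tocoo().data
    tp = float(np.sum(nij * (nij - 1) / 2))
    ai = table.row_sums
    bj = table.col_sums
    pa = float(np.sum(ai * (ai - 1) / 2))
    pb = float(np.sum(bj * (bj - 1) / 2))
    n = table.n
    return tp, pa, pb, n * (n - 1) / 2


def rand_index(a, b, ignore_labels=(0,)) -> float:
    """Fraction of pixel pairs classified consistently by both images."""
    tp, pa, pb, total = _pair_counts(contingency_table(a, b, ignore_labels))
    # agreements = together-in-both + apart-in-both
    return (total + 2 * tp - pa - pb) / total


def adjusted_rand_index(a, b, ignore_labels=(0,)) -> float:
    """Rand index corrected for chance under the permutation model."""
    tp, pa, pb, total = _pair_counts(contingency_table(a, b, ignore_labels))
    expected = pa * pb / total
    max_index = (pa + pb) / 2
    if max_index == expected:  # both partitions trivial
        return 1.0
    return (tp - expected) / (max_index - expected)


def fowlkes_mallows(a, b, ignore_labels=(0,)) -> float:
    """Geometric mean of pair precision and recall: TP/sqrt((TP+FP)(TP+FN))."""
    tp, pa, pb, _ = _pair_counts(contingency_table(a, b, ignore_labels))
    if pa == 0 or pb == 0:
        return 1.0 if pa == pb else 0.0
    return tp / np.sqrt(pa * pb)


def edit_distance(a, b, ignore_labels=(0,), tolerance_pixels: int = 1):
    """Counts of merge and split errors under plurality assignment.

    Each segment of ``a`` is assigned to the body of ``b`` it overlaps
    most.  A body of ``b`` claimed by k > 1 segments contributes k − 1
    false splits.  A segment of ``a`` overlapping two or more bodies by
    more than ``tolerance_pixels`` each counts as one false merge.

    Returns
    -------
    (n_false_merges, n_false_splits) : pair of int
    """
    table = contingency_table(a, b, ignore_labels)
    counts = table.counts
    assigned = np.asarray(counts.argmax(axis=1)).ravel()
    n_false_splits = 0
    claimed = np.bincount(assigned, minlength=counts.shape[1])
    n_false_splits = int(np.sum(np.maximum(claimed - 1, 0)))
    over_tol = counts > tolerance_pixels
    n_false_merges = int(np.sum(np.asarray(over_tol.sum(axis=1)).ravel() >= 2))
    return n_false_merges, n_false_splits


@dataclass
class ViCurve:
    """Split-VI tradeoff along a merge-tree threshold sweep."""

    thresholds: np.ndarray
    under: np.ndarray  # H(B|A) per threshold
    over: np.ndarray  # H(A|B) per threshold

    @property
    def total(self) -> np.ndarray:
        return self.under + self.over

    @property
    def best(self):
        """(threshold, under, over) at the minimum total VI."""
        i = int(np.argmin(self.total))
        return self.thresholds[i], self.under[i], self.over[i]

    def at(self, threshold: float):
        """(under, over) at the sweep point closest to ``threshold``."""
        i = int(np.argmin(np.abs(self.thresholds - threshold)))
        return self.under[i], self.over[i]

    def to_csv(self, path):
        arr = np.column_stack([self.thresholds, self.under, self.over])
        np.savetxt(
            path, arr, delimiter=",", header="threshold,under,over", comments=""
        )

    def plot(self, ax=None, **kwargs):
        """Split-VI plot: under (x, false merges) vs over (y, false splits)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.under, self.over, marker=".", **kwargs)
        t, u, o = self.best
        ax.plot([u], [o], marker="*", markersize=12, linestyle="none")
        u5, o5 = self.at(0.5)
        ax.plot([u5], [o5], marker="o", linestyle="none", fillstyle="none")
        ax.set_xlabel("undersegmentation H(B|A) [bits]")
        ax.set_ylabel("oversegmentation H(A|B) [bits]")
        return ax


def vi_curve(tree, superpixels, gold, thresholds, ignore_labels=(0,)) -> ViCurve:
    """Split VI of the tree cut at each threshold (strictly increasing)."""
    from .rag import cut_tree

    thresholds = np.asarray(sorted(thresholds), dtype=float)
    under, over = [], []
    for t in thresholds:
        seg = cut_tree(tree, t, superpixels)
        sv = split_vi(seg, gold, ignore_labels)
        under.append(sv.under)
        over.append(sv.over)
    return ViCurve(thresholds, np.array(under), np.array(over))
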