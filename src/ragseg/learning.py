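"""Learning merge policies from a gold-standard segmentation.

The training procedure agglomerates a region adjacency graph while
consulting the gold standard: at each step the best-priority edge is
popped, its feature vector and true label recorded, and the merge is
executed only if the gold standard agrees.  Each epoch's accumulated
samples refit a classifier whose "true boundary" probability prioritizes
the next epoch, so later epochs sample the feature distribution the final
policy will actually see at higher hierarchy levels.

Label convention: +1 = "do not merge" (true boundary), −1 = "should
merge".  A learned policy therefore outputs the probability that the
boundary is real; agglomerating to threshold 0.5 merges exactly while the
odds favor a true merge, assuming a well-calibrated classifier.
"""

from __future__ import annotations

import heapq
import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import FeatureManager, manager_from_config
from .rag import Rag

__all__ = [
    "TrainingSet",
    "edge_label",
    "learn_agglomerate",
    "flat_learning",
    "classifier_probability",
    "mean_boundary_policy",
    "median_boundary_policy",
    "default_classifier",
    "serialize_policy",
    "deserialize_policy",
]

_BUNDLE_VERSION = 1


@dataclass
class TrainingSet:
    """Accumulated (features, labels) samples from training agglomeration.

    ``labels`` are in {−1, +1} with +1 = true boundary ("do not merge");
    ``epochs`` records the training epoch of each sample and ``edges``
    the (u, v) node pair it came from.
    """

    features: np.ndarray = field(
        default_factory=lambda: np.empty((0, 0))
    )
    labels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    epochs: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    edges: list = field(default_factory=list)
    degenerate_gold: bool = False

    def __len__(self):
        return self.labels.size

    @classmethod
    def from_samples(cls, rows, labels, epochs, edges, degenerate=False):
        features = (
            np.array(rows) if rows else np.empty((0, 0))
        )
        return cls(
            features,
            np.array(labels, dtype=int),
            np.array(epochs, dtype=int),
            list(edges),
            degenerate,
        )

    def save(self, path):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("features", data=self.features)
            f.create_dataset("labels", data=self.labels)
            f.create_dataset("epochs", data=self.epochs)
            f.create_dataset("edges", data=np.array(self.edges, dtype=np.int64))

    @classmethod
    def load(cls, path):
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                f["features"][...],
                f["labels"][...],
                f["epochs"][...],
                [tuple(e) for e in f["edges"][...]],
            )


# ----------------------------------------------------------------------
# gold-standard supervision


class _GoldOverlap:
    """Per-node gold-body overlap histograms, additive under merges."""

    def __init__(self, rag: Rag, gold):
        gold = np.asarray(gold)
        if gold.shape != rag.shape:
            raise ValueError("gold segmentation shape must match the graph's")
        flat_gold = gold.ravel()
        self.counts = {}
        for n, pix in rag.node_pixels.items():
            if n in rag.graph:
                self.counts[n] = self._histogram(flat_gold[pix])

    @staticmethod
    def _histogram(values):
        labels, counts = np.unique(values, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def merged(self, u, v, w):
        cu, cv = self.counts[u], self.counts[v]
        out = dict(cu)
        for k, c in cv.items():
            out[k] = out.get(k, 0) + c
        self.counts[w] = out

    def assignment(self, n):
        """(best gold body, purity) for node n; gold label 0 is ignored."""
        counts = self.counts[n]
        total = sum(c for k, c in counts.items() if k != 0)
        if total == 0:
            return None, 0.0
        best, bc = max(
            ((k, c) for k, c in counts.items() if k != 0),
            key=lambda kv: (kv[1], -kv[0]),
        )
        return best, bc / total


def edge_label(rag: Rag, u, v, gold, purity_min: float = 0.75, _overlap=None):
    """True merge decision for edge (u, v) against the gold standard.

    Returns −1 ("should merge") when both nodes' plurality gold bodies
    agree, +1 ("should not merge") when they differ, and 0 (ambiguous,
    excluded from training) when either node's plurality overlap
    fraction is below ``purity_min`` or a node overlaps no nonzero gold
    body.
    """
    overlap = _overlap if _overlap is not None else _GoldOverlap(rag, gold)
    bu, pu = overlap.assignment(u)
    bv, pv = overlap.assignment(v)
    if bu is None or bv is None or pu < purity_min or pv < purity_min:
        return 0
    return -1 if bu == bv else 1


# ----------------------------------------------------------------------
# hand-crafted policies


class mean_boundary_policy:
    """Priority = mean boundary pixel probability (first channel).

    Equals the mean derived from an exact moments cache; invariant to
    how the boundary pixel set was split among pre-merge edges.
    """

    def __call__(self, rag: Rag, u, v) -> float:
        vals = rag.pixel_values(rag.boundary_pixels(u, v))[:, 0]
        return float(vals.mean())


class median_boundary_policy:
    """Priority = median boundary pixel probability (first channel).

    Estimated from an unnormalized histogram (the cache-combinable
    representation), interpolating the 50th percentile from the
    cumulative counts; accurate to one bin width of the exact median.
    """

    def __init__(self, n_bins: int = 25, value_range=(0.0, 1.0)):
        from .features import HistogramManager

        self._hist = HistogramManager(
            n_bins=n_bins, value_range=value_range, percentiles=(0.5,)
        )

    def __call__(self, rag: Rag, u, v) -> float:
        vals = rag.pixel_values(rag.boundary_pixels(u, v))[:, :1]
        counts = self._hist._cache_from_values(vals).reshape(-1)
        return float(self._hist._percentiles_from_hist(counts)[0])


def default_classifier(seed: int = 0, n_estimators: int = 100):
    """Seedable random-forest ensemble behind the fit/predict_proba contract."""
    from sklearn.ensemble import RandomForestClassifier

    return RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )


class classifier_probability:
    """Policy = fitted classifier's probability of a true boundary.

    Composes a feature manager with a classifier exposing
    ``predict_proba``; the output is the probability of class +1 ("do
    not merge"), in [0, 1], so agglomerating to threshold 0.5 merges
    while the odds favor a true merge.
    """

    def __init__(self, manager: FeatureManager, classifier):
        self.manager = manager
        self.classifier = classifier

    def _proba(self, X):
        clf = self.classifier
        if not hasattr(clf, "classes_"):
            raise RuntimeError("classifier must be fitted before use as a policy")
        proba = clf.predict_proba(X)
        classes = list(clf.classes_)
        if 1 in classes:
            return proba[:, classes.index(1)]
        return np.zeros(len(X))  # classifier never saw a true boundary

    def __call__(self, rag: Rag, u, v) -> float:
        return float(self._proba(self.manager.edge_vector(rag, u, v)[None, :])[0])

    def batch(self, rag: Rag, pairs):
        if not pairs:
            return []
        X = np.array([self.manager.edge_vector(rag, u, v) for u, v in pairs])
        return self._proba(X)


# ----------------------------------------------------------------------
# training agglomeration


def flat_learning(
    rag: Rag, gold, purity_min: float = 0.75
) -> TrainingSet:
    """Superpixel affinity learning: sample every initial edge once.

    No agglomeration is performed; each live edge of the initial graph
    contributes one (feature vector, label) sample unless its label is
    ambiguous.
    """
    overlap = _GoldOverlap(rag, gold)
    rows, labels, epochs, edges = [], [], [], []
    for u, v in sorted(tuple(sorted(e)) for e in rag.graph.edges):
        lab = edge_label(rag, u, v, gold, purity_min, _overlap=overlap)
        if lab == 0:
            continue
        rows.append(rag.edge_vector(u, v))
        labels.append(lab)
        epochs.append(0)
        edges.append((u, v))
    degenerate = bool(labels) and all(l == -1 for l in labels)
    return TrainingSet.from_samples(rows, labels, epochs, edges, degenerate)


def learn_agglomerate(
    rag: Rag,
    gold,
    n_epochs: int = 5,
    base_policy=None,
    classifier_factory=None,
    purity_min: float = 0.75,
    seed: int = 0,
) -> TrainingSet:
    """Training-set generation by gold-guided repeated agglomeration.

    Each epoch rebuilds the graph and agglomerates it to exhaustion:
    the best-priority edge is popped, its features and gold label
    recorded; true merges (−1) are executed, false merges (+1) are
    recorded but skipped (the edge goes inactive for the epoch), and
    ambiguous edges are skipped without recording.  Epoch 1 uses
    ``base_policy`` (default mean boundary); afterwards a fresh
    classifier fitted on all samples so far supplies the next epoch's
    priorities.

    Returns the accumulated :class:`TrainingSet`; its
    ``degenerate_gold`` flag is set when the gold standard contains a
    single body (every label −1).
    """
    if n_epochs < 1:
        raise ValueError(f"n_epochs must be >= 1, got {n_epochs}")
    if base_policy is None:
        base_policy = mean_boundary_policy()
    if classifier_factory is None:
        classifier_factory = lambda: default_classifier(seed)  # noqa: E731

    gold = np.asarray(gold)
    rows, labels, epochs, edges = [], [], [], []
    policy = base_policy
    for epoch in range(1, n_epochs + 1):
        g = rag.rebuild() if epoch > 1 else rag
        overlap = _GoldOverlap(g, gold)
        heap: list = []
        seq = 0
        pairs = sorted(tuple(sorted(e)) for e in g.graph.edges)
        prios = (
            policy.batch(g, pairs)
            if hasattr(policy, "batch")
            else [policy(g, u, v) for u, v in pairs]
        )
        for (u, v), p in zip(pairs, prios):
            g.graph.edges[u, v]["pseq"] = seq
            heapq.heappush(heap, (float(p), seq, u, v))
            seq += 1

        inactive = set()
        while heap:
            p, s, u, v = heapq.heappop(heap)
            if not g.graph.has_edge(u, v) or g.graph.edges[u, v]["pseq"] != s:
                continue
            if (u, v) in inactive:
                continue
            lab = edge_label(g, u, v, gold, purity_min, _overlap=overlap)
            if lab != 0:
                rows.append(g.edge_vector(u, v))
                labels.append(lab)
                epochs.append(epoch)
                edges.append((u, v))
            if lab == -1:
                w = g.merge_nodes(u, v, priority=p)
                overlap.merged(u, v, w)
                new_pairs = [tuple(sorted((w, x))) for x in sorted(g.graph[w])]
                new_prios = (
                    policy.batch(g, new_pairs)
                    if hasattr(policy, "batch")
                    else [policy(g, a, b) for a, b in new_pairs]
                )
                for (a, b), np_ in zip(new_pairs, new_prios):
                    g.graph.edges[a, b]["pseq"] = seq
                    heapq.heappush(heap, (float(np_), seq, a, b))
                    seq += 1
            else:
                inactive.add((u, v))

        if epoch < n_epochs:
            clf = classifier_factory()
            clf.fit(np.array(rows), np.array(labels))
            policy = classifier_probability(rag.manager, clf)

    degenerate = bool(labels) and all(l == -1 for l in labels)
    return TrainingSet.from_samples(rows, labels, epochs, edges, degenerate)


# ----------------------------------------------------------------------
# policy persistence


def serialize_policy(policy: classifier_probability, path):
    """Write a learned policy (manager config + classifier) to a directory."""
    if not str(path):
        raise ValueError("empty path")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "manager.json", "w") as f:
        json.dump(
            {"version": _BUNDLE_VERSION, "manager": policy.manager.to_config()},
            f,
        )
    with open(path / "classifier.pkl", "wb") as f:
        pickle.dump(policy.classifier, f)


def deserialize_policy(path) -> classifier_probability:
    """Load a policy bundle; priorities reproduce bit-identically."""
    path = Path(path)
    with open(path / "manager.json") as f:
        meta = json.load(f)
    if meta.get("version") != _BUNDLE_VERSION:
        raise ValueError(
            f"policy bundle version {meta.get('version')} not supported "
            f"(expected {_BUNDLE_VERSION})"
        )
    manager = manager_from_config(meta["manager"])
    with open(path / "classifier.pkl", "rb") as f:
        clf = pickle.load(f)
    return classifier_probability(manager, clf)
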