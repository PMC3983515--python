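"""Feature managers: cached region statistics combinable in constant time.

A feature manager defines (a) a per-node and per-edge *cache* of sufficient
statistics, (b) how two caches combine when regions or boundaries merge,
and (c) how to map a cache to a fixed-length feature vector.  Because
caches combine by summation (moments, histograms) or by hulling a vertex
union (convex hull), agglomeration never re-reads pixels, turning a
quadratic workload into a linear one.

The full per-edge vector handed to a classifier concatenates the edge
boundary features with the elementwise min and max of the two node
vectors, making learned policies invariant to edge orientation.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "FeatureManager",
    "MomentsManager",
    "HistogramManager",
    "ConvexHullManager",
    "CompositeManager",
    "default_manager",
    "manager_from_config",
]


class FeatureManager:
    """Contract: caches, constant-time combination, feature computation.

    Subclasses implement ``create_node_cache``, ``create_edge_cache``,
    ``combine_caches``, ``compute_node_features`` and
    ``compute_edge_features``; combination must be commutative and
    associative, and feature vectors must have fixed length independent
    of region size.
    """

    #: number of entries in a node feature vector (set by subclass)
    node_feature_length: int = 0
    #: number of entries in an edge (boundary) feature vector
    edge_feature_length: int = 0

    @property
    def feature_length(self) -> int:
        """Length of the full edge vector used for learning."""
        return self.edge_feature_length + 2 * self.node_feature_length

    def create_node_cache(self, rag, node):
        raise NotImplementedError

    def create_edge_cache(self, rag, u, v):
        raise NotImplementedError

    def combine_caches(self, c1, c2):
        raise NotImplementedError

    def compute_node_features(self, rag, node, cache) -> np.ndarray:
        raise NotImplementedError

    def compute_edge_features(self, rag, u, v, cache) -> np.ndarray:
        raise NotImplementedError

    def edge_vector(self, rag, u, v) -> np.ndarray:
        """Orientation-invariant classifier input for edge (u, v)."""
        ef = self.compute_edge_features(rag, u, v, rag.edge_cache(u, v))
        nu = self.compute_node_features(rag, u, rag.node_cache(u))
        nv = self.compute_node_features(rag, v, rag.node_cache(v))
        return np.concatenate(
            [ef, np.minimum(nu, nv), np.maximum(nu, nv)]
        )

    def to_config(self) -> dict:
        raise NotImplementedError


class MomentsManager(FeatureManager):
    """Raw-moment caches: count and power sums per channel.

    Cache layout per channel: (count, Σx, Σx², …, Σx^n_moments); caches
    are purely additive.  Features per channel: count, mean, standard
    deviation, then standardized central moments of order 3..n_moments
    (zero for degenerate variance).
    """

    def __init__(self, n_moments: int = 4, channels=None):
        if n_moments < 2:
            raise ValueError(f"n_moments must be >= 2, got {n_moments}")
        self.n_moments = n_moments
        self.channels = None if channels is None else list(channels)

    def _select(self, values):
        # values: (n_pixels, n_channels)
        if self.channels is not None:
            values = values[:, self.channels]
        return values

    def _cache_from_values(self, values):
        values = self._select(values)
        n_px, n_ch = values.shape
        cache = np.empty((n_ch, self.n_moments + 1))
        cache[:, 0] = n_px
        for k in range(1, self.n_moments + 1):
            cache[:, k] = np.sum(values**k, axis=0)
        return cache.ravel()

    def create_node_cache(self, rag, node):
        return self._cache_from_values(rag.pixel_values(rag.node_pixels[node]))

    def create_edge_cache(self, rag, u, v):
        return self._cache_from_values(
            rag.pixel_values(rag.boundary_pixels(u, v))
        )

    def combine_caches(self, c1, c2):
        return c1 + c2

    def _features(self, cache) -> np.ndarray:
        cache = cache.reshape(-1, self.n_moments + 1)
        feats = []
        for row in cache:
            n = row[0]
            raw = row[1:] / max(n, 1)  # raw moments E[x^k]
            mean = raw[0]
            var = raw[1] - mean**2
            # raw-moment cancellation leaves O(eps) residuals for constant
            # regions; snap those to an exact zero so standardized moments
            # stay finite and degenerate variance reports as 0
            scale = max(raw[1], mean * mean, 1e-300)
            var = 0.0 if var < 1e-12 * scale else var
            std = np.sqrt(var)
            f = [n, mean, std]
            # standardized central moments via binomial expansion
            for k in range(3, self.n_moments + 1):
                central = sum(
                    _binom(k, j) * raw[j - 1] * (-mean) ** (k - j)
                    for j in range(1, k + 1)
                ) + (-mean) ** k
                f.append(central / std**k if std > 0 else 0.0)
            feats.append(f)
        return np.array(feats).ravel()

    def compute_node_features(self, rag, node, cache):
        return self._features(cache)

    def compute_edge_features(self, rag, u, v, cache):
        return self._features(cache)

    def to_config(self):
        return {
            "name": "moments",
            "n_moments": self.n_moments,
            "channels": self.channels,
        }


def _binom(n, k):
    from math import comb

    return comb(n, k)


# MomentsManager feature length depends on channel count, which is a
# property of the data, not the manager.  Managers therefore finalize
# their lengths when bound to a graph via ``bind``.


class HistogramManager(FeatureManager):
    """Unnormalized-histogram caches, summed bin-wise under merges.

    Features: the normalized histogram plus percentile estimates
    linearly interpolated from the cumulative histogram.  Values outside
    ``value_range`` are clipped into the edge bins.
    """

    def __init__(
        self,
        n_bins: int = 25,
        value_range: tuple[float, float] = (0.0, 1.0),
        percentiles=(0.1, 0.5, 0.9),
        channels=None,
    ):
        if n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        lo, hi = value_range
        if not lo < hi:
            raise ValueError("value_range must satisfy lo < hi")
        self.n_bins = n_bins
        self.value_range = (float(lo), float(hi))
        self.percentiles = list(percentiles)
        self.channels = None if channels is None else list(channels)

    def _cache_from_values(self, values):
        if self.channels is not None:
            values = values[:, self.channels]
        lo, hi = self.value_range
        n_ch = values.shape[1]
        cache = np.empty((n_ch, self.n_bins))
        clipped = np.clip(values, lo, hi)
        for c in range(n_ch):
            cache[c], _ = np.histogram(
                clipped[:, c], bins=self.n_bins, range=(lo, hi)
            )
        return cache.ravel()

    def create_node_cache(self, rag, node):
        return self._cache_from_values(rag.pixel_values(rag.node_pixels[node]))

    def create_edge_cache(self, rag, u, v):
        return self._cache_from_values(
            rag.pixel_values(rag.boundary_pixels(u, v))
        )

    def combine_caches(self, c1, c2):
        return c1 + c2

    def _percentiles_from_hist(self, counts):
        lo, hi = self.value_range
        width = (hi - lo) / self.n_bins
        total = counts.sum()
        if total == 0:
            return np.full(len(self.percentiles), (lo + hi) / 2)
        cdf = np.concatenate([[0.0], np.cumsum(counts)])
        out = []
        for q in self.percentiles:
            target = q * total
            idx = int(np.searchsorted(cdf, target, side="left"))
            idx = min(max(idx, 1), self.n_bins)
            binc = counts[idx - 1]
            frac = (target - cdf[idx - 1]) / binc if binc > 0 else 0.5
            out.append(lo + width * (idx - 1 + frac))
        return np.array(out)

    def _features(self, cache):
        cache = cache.reshape(-1, self.n_bins)
        feats = []
        for counts in cache:
            total = counts.sum()
            norm = counts / total if total > 0 else counts
            feats.append(np.concatenate([norm, self._percentiles_from_hist(counts)]))
        return np.concatenate(feats)

    def compute_node_features(self, rag, node, cache):
        return self._features(cache)

    def compute_edge_features(self, rag, u, v, cache):
        return self._features(cache)

    def to_config(self):
        return {
            "name": "histogram",
            "n_bins": self.n_bins,
            "value_range": list(self.value_range),
            "percentiles": self.percentiles,
            "channels": self.channels,
        }


class ConvexHullManager(FeatureManager):
    """Convex-hull caches for 2D and 3D regions.

    The cache of a region is the vertex set of the convex hull of its
    pixels' unit cells (each pixel contributes its 2^ndim cell corners,
    so even a single pixel spans a full-dimensional polytope and Qhull
    never sees a degenerate input).  Merging hulls the hull of the union
    of the two vertex sets, which equals the hull of the union of the
    regions — pixels are never revisited.

    Node features: hull volume and convexity (region volume / hull
    volume, <= 1).  Edge features describe the hypothetical merged node:
    merged hull volume and merged convexity, which a classifier can use
    to penalize merges that create implausibly non-convex shapes.
    """

    #: fallback thickness regularizer, used only if Qhull still fails
    _EPS = 1e-9

    def __init__(self):
        pass

    @staticmethod
    def _cell_corners(coords):
        # coords: (n, d) integer pixel coordinates -> (n * 2^d, d) corners
        d = coords.shape[1]
        corners = np.array(
            np.meshgrid(*([[0, 1]] * d), indexing="ij")
        ).reshape(d, -1).T
        pts = (coords[:, None, :] + corners[None, :, :]).reshape(-1, d)
        return np.unique(pts, axis=0).astype(float)

    @classmethod
    def _hull_vertices(cls, points):
        try:
            hull = ConvexHull(points)
            return points[hull.vertices]
        except QhullError:
            return np.unique(points, axis=0)

    @classmethod
    def _hull_volume(cls, vertices):
        try:
            return ConvexHull(vertices).volume
        except QhullError:
            return cls._EPS

    def create_node_cache(self, rag, node):
        coords = rag.pixel_coords(rag.node_pixels[node])
        if coords.shape[1] not in (2, 3):
            raise ValueError("convex hull features require 2D or 3D images")
        return self._hull_vertices(self._cell_corners(coords))

    def create_edge_cache(self, rag, u, v):
        coords = rag.pixel_coords(rag.boundary_pixels(u, v))
        return self._hull_vertices(self._cell_corners(coords))

    def combine_caches(self, c1, c2):
        return self._hull_vertices(np.vstack([c1, c2]))

    def compute_node_features(self, rag, node, cache):
        vol = max(self._hull_volume(cache), self._EPS)
        size = float(rag.node_size(node))
        return np.array([vol, min(size / vol, 1.0)])

    def compute_edge_features(self, rag, u, v, cache):
        merged = self.combine_caches(rag.node_cache(u), rag.node_cache(v))
        vol = max(self._hull_volume(merged), self._EPS)
        size = float(rag.node_size(u) + rag.node_size(v))
        bvol = max(self._hull_volume(cache), self._EPS)
        return np.array([bvol, vol, min(size / vol, 1.0)])

    node_feature_length = 2
    edge_feature_length = 3

    def to_config(self):
        return {"name": "convex_hull"}


class CompositeManager(FeatureManager):
    """Concatenation of child managers; caches are tuples of child caches."""

    def __init__(self, managers):
        managers = list(managers)
        if not managers:
            raise ValueError("composite requires at least one child manager")
        self.managers = managers

    def create_node_cache(self, rag, node):
        return tuple(m.create_node_cache(rag, node) for m in self.managers)

    def create_edge_cache(self, rag, u, v):
        return tuple(m.create_edge_cache(rag, u, v) for m in self.managers)

    def combine_caches(self, c1, c2):
        return tuple(
            m.combine_caches(a, b) for m, a, b in zip(self.managers, c1, c2)
        )

    def compute_node_features(self, rag, node, cache):
        return np.concatenate(
            [
                m.compute_node_features(rag, node, c)
                for m, c in zip(self.managers, cache)
            ]
        )

    def compute_edge_features(self, rag, u, v, cache):
        return np.concatenate(
            [
                m.compute_edge_features(rag, u, v, c)
                for m, c in zip(self.managers, cache)
            ]
        )

    @property
    def node_feature_length(self):  # type: ignore[override]
        return sum(m.node_feature_length for m in self.managers)

    @property
    def edge_feature_length(self):  # type: ignore[override]
        return sum(m.edge_feature_length for m in self.managers)

    def to_config(self):
        return {
            "name": "composite",
            "managers": [m.to_config() for m in self.managers],
        }


def _moments_lengths(mgr: MomentsManager, n_channels: int):
    per = 1 + mgr.n_moments  # count, mean, std, standardized 3..n
    n_ch = n_channels if mgr.channels is None else len(mgr.channels)
    return per * n_ch


def _histogram_lengths(mgr: HistogramManager, n_channels: int):
    per = mgr.n_bins + len(mgr.percentiles)
    n_ch = n_channels if mgr.channels is None else len(mgr.channels)
    return per * n_ch


def bind_feature_lengths(manager: FeatureManager, n_channels: int) -> None:
    """Finalize channel-dependent feature lengths for a data source.

    Moments and histogram features scale with the channel count of the
    intensity map; hull features do not.  Called by the graph builder.
    """
    if isinstance(manager, CompositeManager):
        for m in manager.managers:
            bind_feature_lengths(m, n_channels)
    elif isinstance(manager, MomentsManager):
        n = _moments_lengths(manager, n_channels)
        manager.__dict__["node_feature_length"] = n
        manager.__dict__["edge_feature_length"] = n
    elif isinstance(manager, HistogramManager):
        n = _histogram_lengths(manager, n_channels)
        manager.__dict__["node_feature_length"] = n
        manager.__dict__["edge_feature_length"] = n


def default_manager() -> CompositeManager:
    """Default feature set: 4 moments + 25-bin histogram with
    10/50/90 percentiles, concatenated."""
    return CompositeManager(
        [
            MomentsManager(n_moments=4),
            HistogramManager(
                n_bins=25, value_range=(0.0, 1.0), percentiles=(0.1, 0.5, 0.9)
            ),
        ]
    )


_REGISTRY = {
    "moments": lambda cfg: MomentsManager(cfg["n_moments"], cfg["channels"]),
    "histogram": lambda cfg: HistogramManager(
        cfg["n_bins"], tuple(cfg["value_range"]), cfg["percentiles"], cfg["channels"]
    ),
    "convex_hull": lambda cfg: ConvexHullManager(),
    "composite": lambda cfg: CompositeManager(
        [manager_from_config(c) for c in cfg["managers"]]
    ),
}


def manager_from_config(config: dict) -> FeatureManager:
    """Rebuild a manager from its JSON-serializable configuration."""
    try:
        factory = _REGISTRY[config["name"]]
    except KeyError as e:
        raise ValueError(f"unknown feature manager {config.get('name')!r}") from e
    return factory(config)
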