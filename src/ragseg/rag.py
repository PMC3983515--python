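"""Region adjacency graph with feature caches and hierarchical merging.

The :class:`Rag` is the package's central mutable structure: one node per
superpixel, one edge per pair of touching superpixels, per-node and
per-edge feature caches maintained by a feature manager, a lazy merge
priority queue, and a :class:`MergeTree` recording every executed merge so
any intermediate segmentation can be recovered by cutting the tree at a
threshold.

Because agglomeration is hierarchical, the number of node ids ever created
is bounded by twice the initial node count (and likewise for edges), so
cache storage is preallocated as flat tables of ``2 * n_initial`` rows
addressed by an incremental id scheme, rather than allocated per node.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .features import FeatureManager, bind_feature_lengths, default_manager
from .geometry import Connectivity

__all__ = ["Rag", "MergeTree", "build_rag", "cut_tree"]


@dataclass
class MergeTree:
    """Ordered record of merges: (parent_id, child_u, child_v, priority).

    Leaf ids are the initial superpixel labels; each id appears as a
    child at most once.  The executed order is preserved, so cutting the
    tree replays agglomeration exactly.
    """

    records: list = field(default_factory=list)

    def append(self, parent, u, v, priority):
        self.records.append((int(parent), int(u), int(v), priority))

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_json(self, path):
        with open(path, "w") as f:
            json.dump(
                [
                    {"parent": p, "u": u, "v": v, "priority": pr}
                    for p, u, v, pr in self.records
                ],
                f,
            )

    @classmethod
    def from_json(cls, path):
        with open(path) as f:
            raw = json.load(f)
        tree = cls()
        for r in raw:
            tree.append(r["parent"], r["u"], r["v"], r["priority"])
        return tree


def _normalize_probabilities(probabilities, spatial_shape):
    probabilities = np.asarray(probabilities, dtype=np.float64)
    if probabilities.shape == tuple(spatial_shape):
        probabilities = probabilities[..., np.newaxis]
    elif probabilities.shape[:-1] == tuple(spatial_shape):
        pass
    else:
        raise ValueError(
            f"probability map shape {probabilities.shape} does not match "
            f"label image shape {tuple(spatial_shape)}"
        )
    if not np.all(np.isfinite(probabilities)):
        raise ValueError("probability map contains non-finite values")
    return probabilities


class Rag:
    """Region adjacency graph over a superpixel map and an intensity map.

    Parameters
    ----------
    superpixels : ndarray of int
        Initial fine-grained segmentation; nonzero labels become nodes.
    probabilities : ndarray
        Pixel-level evidence, shape equal to ``superpixels`` with an
        optional trailing channel axis; probability channels in [0, 1].
    connectivity : Connectivity, optional
        Adjacency used both for edges and boundary pixel sets; defaults
        to face connectivity.
    manager : FeatureManager, optional
        Defaults to moments + histogram composite.
    zero_is_boundary : bool
        If True, label-0 pixels are ridge lines: they belong to no
        region and mediate adjacency between the regions around them.
    """

    def __init__(
        self,
        superpixels,
        probabilities,
        connectivity: Connectivity | None = None,
        manager: FeatureManager | None = None,
        zero_is_boundary: bool = False,
    ):
        superpixels = np.asarray(superpixels)
        if superpixels.size == 0:
            raise ValueError("empty label image")
        if np.any(superpixels < 0):
            raise ValueError("label image must be non-negative")
        if connectivity is None:
            connectivity = Connectivity(superpixels.ndim, 1)
        if connectivity.ndim != superpixels.ndim:
            raise ValueError("connectivity ndim does not match image")
        if manager is None:
            manager = default_manager()

        self.superpixels = superpixels
        self.shape = superpixels.shape
        self.connectivity = connectivity
        self.manager = manager
        self.zero_is_boundary = zero_is_boundary
        self.probabilities = _normalize_probabilities(probabilities, self.shape)
        self._flat_probabilities = self.probabilities.reshape(
            -1, self.probabilities.shape[-1]
        )
        bind_feature_lengths(manager, self.probabilities.shape[-1])

        flat = superpixels.ravel()
        labels = np.unique(flat)
        labels = labels[labels > 0]
        if labels.size == 0:
            raise ValueError("label image has no nonzero labels")

        # node extents: group flat pixel indices by label in one sort
        order = np.argsort(flat, kind="stable")
        sorted_labels = flat[order]
        starts = np.searchsorted(sorted_labels, labels, side="left")
        stops = np.searchsorted(sorted_labels, labels, side="right")
        self.node_pixels = {
            int(l): order[a:b] for l, a, b in zip(labels, starts, stops)
        }

        self.graph = nx.Graph()
        self.graph.add_nodes_from(int(l) for l in labels)
        self.tree = MergeTree()
        self.n_initial_nodes = len(labels)
        self._next_node_id = int(labels.max()) + 1

        boundaries = self._find_adjacencies(flat)
        self.n_initial_edges = len(boundaries)

        # §-style preallocation: flat tables of 2x the initial counts,
        # addressed by incremental row ids (object dtype so structured
        # caches such as hull vertex sets fit alongside float vectors).
        self._node_caches = np.empty(2 * self.n_initial_nodes, dtype=object)
        self._edge_caches = np.empty(max(2 * self.n_initial_edges, 1), dtype=object)
        self._edge_boundary = np.empty(max(2 * self.n_initial_edges, 1), dtype=object)
        self._node_rows = {}
        self._node_sizes = {}
        self.nodes_created = 0
        self.edges_created = 0

        for l in labels:
            l = int(l)
            self._node_rows[l] = self.nodes_created
            self.nodes_created += 1
            self._node_sizes[l] = self.node_pixels[l].size
            self._node_caches[self._node_rows[l]] = manager.create_node_cache(
                self, l
            )

        for (u, v), pix in boundaries.items():
            row = self.edges_created
            self.edges_created += 1
            self._edge_boundary[row] = pix
            self.graph.add_edge(u, v, row=row, priority=None, pseq=None)
            self._edge_caches[row] = manager.create_edge_cache(self, u, v)

    # ------------------------------------------------------------------
    # construction helpers

    def _find_adjacencies(self, flat):
        """Map (u, v) -> sorted unique flat boundary pixel indices."""
        shape = self.shape
        labels = flat.reshape(shape)
        idx_grid = np.arange(flat.size).reshape(shape)
        offsets = self.connectivity.offsets()
        # enumerate each unordered pixel pair once: keep offsets whose
        # first nonzero component is positive
        half = [o for o in offsets if o[np.flatnonzero(o)[0]] > 0]

        pair_u, pair_v, pix = [], [], []
        for off in half:
            sl_p = tuple(
                slice(max(0, -o), s - max(0, o)) for o, s in zip(off, shape)
            )
            sl_q = tuple(
                slice(max(0, o), s - max(0, -o)) for o, s in zip(off, shape)
            )
            la, lb = labels[sl_p].ravel(), labels[sl_q].ravel()
            ia, ib = idx_grid[sl_p].ravel(), idx_grid[sl_q].ravel()
            mask = (la != lb) & (la > 0) & (lb > 0)
            if not mask.any():
                continue
            u = np.minimum(la[mask], lb[mask])
            v = np.maximum(la[mask], lb[mask])
            # "thick" boundary: both sides belong to the boundary set
            pair_u.append(np.concatenate([u, u]))
            pair_v.append(np.concatenate([v, v]))
            pix.append(np.concatenate([ia[mask], ib[mask]]))

        boundaries: dict = {}
        if pair_u:
            pu = np.concatenate(pair_u)
            pv = np.concatenate(pair_v)
            px = np.concatenate(pix)
            code = pu * (self._next_node_id) + pv
            order = np.argsort(code, kind="stable")
            code, pu, pv, px = code[order], pu[order], pv[order], px[order]
            uniq, starts = np.unique(code, return_index=True)
            stops = np.append(starts[1:], code.size)
            for a, b in zip(starts, stops):
                key = (int(pu[a]), int(pv[a]))
                boundaries[key] = np.unique(px[a:b])

        if self.zero_is_boundary:
            self._add_ridge_adjacencies(labels, boundaries)
        return boundaries

    def _add_ridge_adjacencies(self, labels, boundaries):
        """Connect regions separated by zero-labeled ridge pixels."""
        from .geometry import get_neighbor_idxs

        zero_coords = np.argwhere(labels == 0)
        if zero_coords.size == 0:
            return
        strides = np.array(
            [int(np.prod(self.shape[i + 1:])) for i in range(len(self.shape))]
        )
        nbr_lists = get_neighbor_idxs(zero_coords, self.shape, self.connectivity)
        extra: dict = {}
        for c, nbrs in zip(zero_coords, nbr_lists):
            vals = np.unique(labels[tuple(nbrs.T)])
            vals = vals[vals > 0]
            if vals.size < 2:
                continue
            p = int(c @ strides)
            for i in range(vals.size):
                for j in range(i + 1, vals.size):
                    extra.setdefault((int(vals[i]), int(vals[j])), []).append(p)
        for key, pixlist in extra.items():
            prev = boundaries.get(key, np.empty(0, dtype=np.intp))
            boundaries[key] = np.unique(np.concatenate([prev, pixlist]))

    # ------------------------------------------------------------------
    # accessors used by feature managers

    def pixel_values(self, flat_idxs) -> np.ndarray:
        """(n_pixels, n_channels) intensity values at flat indices."""
        return self._flat_probabilities[flat_idxs]

    def pixel_coords(self, flat_idxs) -> np.ndarray:
        """(n_pixels, ndim) coordinates of flat indices."""
        return np.array(np.unravel_index(flat_idxs, self.shape)).T

    def node_cache(self, n):
        return self._node_caches[self._node_rows[n]]

    def edge_cache(self, u, v):
        return self._edge_caches[self.graph.edges[u, v]["row"]]

    def boundary_pixels(self, u, v) -> np.ndarray:
        return self._edge_boundary[self.graph.edges[u, v]["row"]]

    def node_size(self, n) -> int:
        return self._node_sizes[n]

    def live_nodes(self):
        return sorted(self.graph.nodes)

    def edge_vector(self, u, v) -> np.ndarray:
        return self.manager.edge_vector(self, u, v)

    def rebuild(self) -> "Rag":
        """Fresh graph from the same inputs (used per training epoch)."""
        return Rag(
            self.superpixels,
            self.probabilities,
            self.connectivity,
            self.manager,
            self.zero_is_boundary,
        )

    # ------------------------------------------------------------------
    # merging

    def merge_nodes(self, u, v, priority=None) -> int:
        """Merge adjacent live nodes u, v; return the fresh parent id.

        Node and edge caches are combined by the manager in constant
        time; boundary pixel sets of edges to common neighbors are
        unioned.  Edges to exclusive neighbors keep their edge id.
        """
        if not self.graph.has_edge(u, v):
            raise ValueError(f"nodes {u} and {v} are not joined by a live edge")
        w = self._next_node_id
        self._next_node_id += 1
        row = self.nodes_created
        if row >= self._node_caches.size:
            raise RuntimeError("node id budget exceeded (hierarchy bound violated)")
        self.nodes_created += 1
        self._node_rows[w] = row
        self._node_caches[row] = self.manager.combine_caches(
            self.node_cache(u), self.node_cache(v)
        )
        self._node_sizes[w] = self._node_sizes[u] + self._node_sizes[v]
        self.node_pixels[w] = np.concatenate(
            [self.node_pixels[u], self.node_pixels[v]]
        )

        self.graph.add_node(w)
        neighbors = (set(self.graph[u]) | set(self.graph[v])) - {u, v}
        new_edges = []
        for x in sorted(neighbors):
            has_u = self.graph.has_edge(u, x)
            has_v = self.graph.has_edge(v, x)
            if has_u and has_v:
                erow = self.edges_created
                if erow >= self._edge_caches.size:
                    raise RuntimeError(
                        "edge id budget exceeded (hierarchy bound violated)"
                    )
                self.edges_created += 1
                self._edge_caches[erow] = self.manager.combine_caches(
                    self.edge_cache(u, x), self.edge_cache(v, x)
                )
                self._edge_boundary[erow] = np.unique(
                    np.concatenate(
                        [self.boundary_pixels(u, x), self.boundary_pixels(v, x)]
                    )
                )
            else:
                a = u if has_u else v
                erow = self.graph.edges[a, x]["row"]
            self.graph.add_edge(w, x, row=erow, priority=None, pseq=None)
            new_edges.append((w, x))

        self.graph.remove_node(u)
        self.graph.remove_node(v)
        self.tree.append(w, u, v, priority)
        return w

    # ------------------------------------------------------------------
    # agglomeration

    def _push(self, heap, seq, u, v, priority):
        self.graph.edges[u, v]["priority"] = priority
        self.graph.edges[u, v]["pseq"] = seq
        heapq.heappush(heap, (priority, seq, u, v))

    def _edge_priorities(self, policy, pairs):
        batch = getattr(policy, "batch", None)
        if batch is not None:
            return batch(self, pairs)
        return [policy(self, u, v) for u, v in pairs]

    def agglomerate(
        self, policy, threshold: float, continue_past_threshold: bool = False
    ) -> np.ndarray:
        """Merge lowest-priority edges while priority < threshold.

        Uses a lazily invalidated priority queue: entries carry the
        priority at push time and are discarded on pop if either
        endpoint died or the edge was re-prioritized since.  Ties are
        broken first-in-first-out by insertion sequence.

        With ``continue_past_threshold`` the graph is merged to
        exhaustion (recording every priority in the merge tree, for
        threshold sweeps) and the returned segmentation is the tree cut
        at ``threshold``.
        """
        if self.graph.number_of_nodes() == 0:
            raise ValueError("empty graph")
        heap: list = []
        seq = 0
        pairs = sorted(tuple(sorted(e)) for e in self.graph.edges)
        for (u, v), p in zip(pairs, self._edge_priorities(policy, pairs)):
            self._push(heap, seq, u, v, float(p))
            seq += 1

        while heap:
            p, s, u, v = heapq.heappop(heap)
            if (
                not self.graph.has_edge(u, v)
                or self.graph.edges[u, v]["pseq"] != s
            ):
                continue  # stale entry
            if p >= threshold and not continue_past_threshold:
                break
            w = self.merge_nodes(u, v, priority=p)
            new_pairs = [(w, x) for x in sorted(self.graph[w])]
            for (a, b), np_ in zip(
                new_pairs, self._edge_priorities(policy, new_pairs)
            ):
                self._push(heap, seq, a, b, float(np_))
                seq += 1

        if continue_past_threshold:
            return cut_tree(self.tree, threshold, self.superpixels)
        return self.current_segmentation()

    def current_segmentation(self) -> np.ndarray:
        """Label image of the live nodes, relabeled consecutively from 1."""
        ancestor = {}
        for parent, u, v, _ in self.tree:
            ancestor[u] = parent
            ancestor[v] = parent

        def resolve(n):
            while n in ancestor:
                n = ancestor[n]
            return n

        live = {n: i + 1 for i, n in enumerate(self.live_nodes())}
        max_label = int(self.superpixels.max())
        lut = np.zeros(max_label + 1, dtype=np.uint64)
        for leaf in np.unique(self.superpixels):
            if leaf == 0:
                continue
            lut[leaf] = live[resolve(int(leaf))]
        return lut[self.superpixels]


def build_rag(
    superpixels,
    probabilities,
    connectivity: Connectivity | None = None,
    manager: FeatureManager | None = None,
    zero_is_boundary: bool = False,
) -> Rag:
    """Construct a region adjacency graph (see :class:`Rag`)."""
    return Rag(superpixels, probabilities, connectivity, manager, zero_is_boundary)


def cut_tree(tree: MergeTree, threshold: float, superpixels) -> np.ndarray:
    """Segmentation from the merge prefix executed below a threshold.

    Applies recorded merges in order until the first whose priority is
    >= threshold, which is exactly the sequence a threshold-stopped
    agglomeration executes; returns the corresponding relabeling of the
    superpixels (labels consecutive from 1, 0 preserved).
    """
    superpixels = np.asarray(superpixels)
    ancestor = {}
    for parent, u, v, priority in tree:
        if priority is not None and priority >= threshold:
            break
        ancestor[u] = parent
        ancestor[v] = parent

    def resolve(n):
        while n in ancestor:
            n = ancestor[n]
        return n

    leaves = [int(l) for l in np.unique(superpixels) if l != 0]
    roots = {}
    next_out = 1
    max_label = int(superpixels.max())
    lut = np.zeros(max_label + 1, dtype=np.uint64)
    for leaf in leaves:
        root = resolve(leaf)
        if root not in roots:
            roots[root] = next_out
            next_out += 1
        lut[leaf] = roots[root]
    return lut[superpixels]
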