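"""Dimension-agnostic pixel adjacency and watershed oversegmentation.

Everything downstream (graph construction, boundary extraction, regional
minima) is parameterized by a single :class:`Connectivity` object, so the
same code segments 2D micrographs and 3D volumes.  Connectivity ``order``
follows the scipy/scikit-image convention: a neighbor may differ from the
center pixel by at most ``order`` orthogonal steps, so order 1 gives the
2·ndim face neighbors and order ndim gives all 3^ndim − 1 surrounding
pixels.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi


@dataclass(frozen=True)
class Connectivity:
    """Neighborhood definition for an ``ndim``-dimensional image.

    Parameters
    ----------
    ndim : int
        Number of spatial dimensions (>= 1).
    order : int
        Between 1 (face neighbors only) and ``ndim`` (include all
        diagonal neighbors).
    """

    ndim: int
    order: int = 1

    def __post_init__(self):
        if self.ndim < 1:
            raise ValueError(f"ndim must be >= 1, got {self.ndim}")
        if not 1 <= self.order <= self.ndim:
            raise ValueError(
                f"order must be in [1, {self.ndim}], got {self.order}"
            )

    def offsets(self) -> np.ndarray:
        """All neighbor offsets, each component in {-1, 0, 1}.

        Returns an array of shape (n_neighbors, ndim); excludes the zero
        offset.  Row order is fixed (lexicographic over the product), so
        iteration is deterministic.
        """
        offs = [
            o
            for o in itertools.product((-1, 0, 1), repeat=self.ndim)
            if 0 < sum(c != 0 for c in o) <= self.order
        ]
        return np.array(offs, dtype=np.intp)

    def structure(self) -> np.ndarray:
        """Binary footprint for scipy.ndimage (center included)."""
        return ndi.generate_binary_structure(self.ndim, self.order)


def get_neighbor_idxs(coords, shape, connectivity: Connectivity):
    """In-bounds neighbors of each coordinate under a connectivity.

    Parameters
    ----------
    coords : sequence of coordinate tuples, or (n, ndim) array
    shape : tuple of int
        Image shape; every input coordinate must lie inside it.
    connectivity : Connectivity

    Returns
    -------
    list of (k_i, ndim) integer arrays, one per input coordinate, holding
    the in-bounds neighbors.  Out-of-bounds candidates are dropped, never
    clamped, so the neighbor relation is symmetric.
    """
    shape = tuple(shape)
    if connectivity.ndim != len(shape):
        raise ValueError(
            f"connectivity ndim {connectivity.ndim} != image ndim {len(shape)}"
        )
    coords = np.atleast_2d(np.asarray(coords, dtype=np.intp))
    if coords.shape[1] != len(shape):
        raise ValueError("coordinate dimensionality does not match shape")
    upper = np.array(shape, dtype=np.intp)
    if np.any(coords < 0) or np.any(coords >= upper):
        raise ValueError("coordinate outside image shape")
    offs = connectivity.offsets()
    out = []
    for c in coords:
        nbrs = c[np.newaxis, :] + offs
        keep = np.all((nbrs >= 0) & (nbrs < upper), axis=1)
        out.append(nbrs[keep])
    return out


def _flat_neighbors(shape, connectivity: Connectivity):
    """Flat-index offsets and a validity test for neighbor stepping.

    Returns (offsets_nd, strides) so callers can step in raveled index
    space while checking bounds in coordinate space.
    """
    offs = connectivity.offsets()
    strides = np.array(
        [int(np.prod(shape[i + 1:], dtype=np.intp)) for i in range(len(shape))],
        dtype=np.intp,
    )
    return offs, offs @ strides


def regional_minima(landscape: np.ndarray, connectivity: Connectivity) -> np.ndarray:
    """Label connected plateaus with no lower neighbor, in raster order."""
    from skimage.morphology import local_minima

    minima = local_minima(landscape, connectivity=connectivity.order)
    markers, _ = ndi.label(minima, structure=connectivity.structure())
    return markers


def watershed(
    landscape: np.ndarray,
    seeds: np.ndarray | None = None,
    connectivity: Connectivity | None = None,
) -> np.ndarray:
    """Marker-based priority-flood watershed with a fixed tie policy.

    Pixels are flooded in increasing landscape value; markers are enqueued
    in raster order and ties in value are broken first-in-first-out, so the
    output is fully deterministic and plateaus are divided geodesically
    from the basins that reach them first.

    Parameters
    ----------
    landscape : ndarray
        Single-channel image; basins form around its minima.
    seeds : ndarray of int, optional
        Nonzero pixels are markers.  When absent, regional minima under
        the same connectivity become the markers.
    connectivity : Connectivity, optional
        Defaults to face connectivity (order 1).

    Returns
    -------
    ndarray of uint64
        Label image partitioning every pixel among the markers.
    """
    landscape = np.asarray(landscape)
    if connectivity is None:
        connectivity = Connectivity(landscape.ndim, 1)
    if connectivity.ndim != landscape.ndim:
        raise ValueError("landscape must be single-channel (spatial axes only)")
    if seeds is None:
        seeds = regional_minima(landscape, connectivity)
    else:
        seeds = np.asarray(seeds)
        if seeds.shape != landscape.shape:
            raise ValueError("seeds shape must match landscape shape")

    shape = landscape.shape
    flat_land = landscape.ravel()
    flat_seeds = seeds.ravel()
    labels = np.zeros(flat_land.shape, dtype=np.uint64)
    offs, flat_offs = _flat_neighbors(shape, connectivity)
    upper = np.array(shape, dtype=np.intp)

    heap: list = []
    seq = 0
    for p in np.flatnonzero(flat_seeds):  # raster order
        heapq.heappush(heap, (flat_land[p], seq, int(p), int(flat_seeds[p])))
        seq += 1

    coords_cache = np.array(np.unravel_index(np.arange(flat_land.size), shape)).T

    while heap:
        _, _, p, lab = heapq.heappop(heap)
        if labels[p]:
            continue
        labels[p] = lab
        c = coords_cache[p]
        nb = c + offs
        ok = np.all((nb >= 0) & (nb < upper), axis=1)
        for q in (p + flat_offs[ok]):
            if not labels[q]:
                heapq.heappush(heap, (flat_land[q], seq, int(q), lab))
                seq += 1

    return labels.reshape(shape)
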