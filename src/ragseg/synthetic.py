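"""Synthetic gold standards, boundary-probability maps, and superpixels.

Generates everything the pipeline needs — a ground-truth partition, a
noisy boundary-probability map emulating a pixel classifier's output, and
a valid oversegmentation — so training, segmentation and evaluation are
fully testable without any external data.

Gold bodies are Voronoi cells of random seed points (always connected);
the probability map is the blurred body-boundary indicator plus truncated
Gaussian noise; superpixels come from a seeded watershed on that map,
intersected with the gold standard so they provably never cross true
boundaries (undersegmentation VI is exactly 0 by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage as ndi

from .geometry import Connectivity, watershed

__all__ = ["FixtureSpec", "make_gold", "make_probability", "make_superpixels",
           "make_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic segmentation fixture.

    shape : image shape, 2D or 3D
    n_bodies : number of true segments
    boundary_blur : Gaussian sigma smearing the boundary indicator
    noise_sigma : scale of additive truncated-Gaussian pixel noise
    oversegmentation_factor : superpixel seeds per true body (>= 1)
    min_fragment : fragments smaller than this are absorbed into a
        same-body neighbor after the gold intersection
    seed : RNG seed; every output is deterministic given the spec
    """

    shape: tuple = (64, 64)
    n_bodies: int = 8
    boundary_blur: float = 1.0
    noise_sigma: float = 0.1
    oversegmentation_factor: int = 4
    min_fragment: int = 4
    seed: int = 0

    def __post_init__(self):
        if len(self.shape) not in (2, 3):
            raise ValueError("fixtures are 2D or 3D")
        if self.n_bodies < 1:
            raise ValueError("n_bodies must be >= 1")
        if self.oversegmentation_factor < 1:
            raise ValueError("oversegmentation_factor must be >= 1")
        if self.boundary_blur < 0 or self.noise_sigma < 0:
            raise ValueError("blur and noise scales must be nonnegative")

    def to_json(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)
        return d

    @classmethod
    def from_json(cls, d: dict) -> "FixtureSpec":
        d = dict(d)
        d["shape"] = tuple(d["shape"])
        return cls(**d)


def _rng(spec: FixtureSpec, salt: int) -> np.random.Generator:
    return np.random.default_rng((spec.seed, salt))


def make_gold(spec: FixtureSpec) -> np.ndarray:
    """Voronoi partition of the volume around n_bodies random seed points.

    Each body is the set of pixels nearest (Euclidean) to its seed, so
    bodies are convex, connected and nonempty; labels are 1..n_bodies.
    """
    rng = _rng(spec, 1)
    shape = np.array(spec.shape)
    # rejection-free distinct seeds: sample flat indices without replacement
    n_px = int(np.prod(shape))
    flat_seeds = rng.choice(n_px, size=spec.n_bodies, replace=False)
    seeds = np.array(np.unravel_index(flat_seeds, spec.shape)).T  # (k, d)
    grids = np.indices(spec.shape).reshape(len(spec.shape), -1).T
    d2 = ((grids[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1) + 1
    return labels.reshape(spec.shape).astype(np.uint64)


def _boundary_indicator(gold: np.ndarray) -> np.ndarray:
    """1.0 at pixels with a face neighbor of a different label."""
    ind = np.zeros(gold.shape, dtype=np.float64)
    for axis in range(gold.ndim):
        a = [slice(None)] * gold.ndim
        b = [slice(None)] * gold.ndim
        a[axis] = slice(0, -1)
        b[axis] = slice(1, None)
        diff = gold[tuple(a)] != gold[tuple(b)]
        ind[tuple(a)][diff] = 1.0
        ind[tuple(b)][diff] = 1.0
    return ind


def make_probability(gold: np.ndarray, spec: FixtureSpec) -> np.ndarray:
    """Noisy boundary-probability map for a gold standard.

    The body-boundary indicator is blurred with a Gaussian of sigma
    ``boundary_blur`` (rescaled so the ridge peaks stay at 1), then
    zero-mean Gaussian noise of scale ``noise_sigma`` is added and the
    result clipped to [0, 1].  With zero noise, values on and near true
    boundaries strictly exceed interior values.
    """
    prob = _boundary_indicator(np.asarray(gold))
    if spec.boundary_blur > 0:
        prob = ndi.gaussian_filter(prob, spec.boundary_blur)
        peak = prob.max()
        if peak > 0:
            prob = prob / peak
    if spec.noise_sigma > 0:
        rng = _rng(spec, 2)
        prob = prob + rng.normal(0.0, spec.noise_sigma, size=prob.shape)
    return np.clip(prob, 0.0, 1.0)


def _absorb_small_fragments(labels, gold, min_size, connectivity):
    """Merge fragments smaller than min_size into a same-body neighbor."""
    labels = labels.copy()
    structure = connectivity.structure()
    changed = True
    while changed:
        changed = False
        ids, counts = np.unique(labels, return_counts=True)
        small = ids[(counts < min_size) & (ids > 0)]
        for sid in small:
            mask = labels == sid
            body = gold[mask].ravel()[0]
            dil = ndi.binary_dilation(mask, structure=structure) & ~mask
            cand = labels[dil & (gold == body)]
            cand = cand[cand != sid]
            if cand.size == 0:
                continue  # whole body smaller than min_size; keep
            vals, vc = np.unique(cand, return_counts=True)
            labels[mask] = vals[np.argmax(vc)]
            changed = True
    return labels


def make_superpixels(
    gold: np.ndarray, probability: np.ndarray, spec: FixtureSpec
) -> np.ndarray:
    """Guaranteed-valid oversegmentation of a gold standard.

    Seeds a watershed of the probability map with
    ``oversegmentation_factor`` random interior points per gold body,
    then splits every watershed region along gold boundaries so no
    superpixel ever crosses a true boundary: the undersegmentation
    component of split VI against gold is exactly 0.  Fragments below
    ``min_fragment`` pixels (slivers at basin junctions) are absorbed
    into a neighboring superpixel of the same body.
    """
    gold = np.asarray(gold)
    rng = _rng(spec, 3)
    conn = Connectivity(gold.ndim, 1)

    seeds = np.zeros(gold.shape, dtype=np.uint64)
    next_label = 1
    for body in np.unique(gold):
        if body == 0:
            continue
        flat = np.flatnonzero(gold.ravel() == body)
        k = min(spec.oversegmentation_factor, flat.size)
        chosen = rng.choice(flat, size=k, replace=False)
        for p in np.sort(chosen):
            seeds.ravel()[p] = next_label
            next_label += 1

    ws = watershed(np.asarray(probability, dtype=float), seeds, conn)

    # split watershed regions along gold boundaries, then re-extract
    # connected components so each label is a single connected region
    combo = ws.astype(np.int64) * (int(gold.max()) + 1) + gold.astype(np.int64)
    _, combo = np.unique(combo, return_inverse=True)
    combo = combo.reshape(gold.shape) + 1
    out = np.zeros(gold.shape, dtype=np.int64)
    next_label = 1
    for cid in np.unique(combo):
        comp, n = ndi.label(combo == cid, structure=conn.structure())
        for i in range(1, n + 1):
            out[comp == i] = next_label
            next_label += 1
    out = _absorb_small_fragments(out, gold, spec.min_fragment, conn)
    _, relab = np.unique(out, return_inverse=True)
    return (relab.reshape(gold.shape) + 1).astype(np.uint64)


def make_fixture(spec: FixtureSpec):
    """(gold, probability, superpixels) triple for a spec."""
    gold = make_gold(spec)
    prob = make_probability(gold, spec)
    sp = make_superpixels(gold, prob, spec)
    return gold, prob, sp
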