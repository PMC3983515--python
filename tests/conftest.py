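"""Shared fixtures: small synthetic volumes and from-scratch oracles."""

import numpy as np
import pytest

from ragseg import FixtureSpec, Rag, make_fixture
from ragseg.features import manager_from_config


@pytest.fixture(scope="session")
def noiseless_2d():
    """Noiseless 2D fixture: gold, probability map, valid superpixels."""
    spec = FixtureSpec(
        shape=(40, 40),
        n_bodies=6,
        boundary_blur=1.0,
        noise_sigma=0.0,
        oversegmentation_factor=3,
        seed=11,
    )
    return spec, *make_fixture(spec)


@pytest.fixture(scope="session")
def noisy_2d():
    """Moderately noisy 2D fixture."""
    spec = FixtureSpec(
        shape=(40, 40),
        n_bodies=6,
        boundary_blur=1.0,
        noise_sigma=0.15,
        oversegmentation_factor=3,
        seed=12,
    )
    return spec, *make_fixture(spec)


@pytest.fixture(scope="session")
def noisy_3d():
    """Small 3D fixture."""
    spec = FixtureSpec(
        shape=(12, 12, 12),
        n_bodies=4,
        boundary_blur=0.8,
        noise_sigma=0.1,
        oversegmentation_factor=2,
        seed=13,
    )
    return spec, *make_fixture(spec)


def rebuild_fresh(g: Rag) -> tuple[Rag, dict]:
    """From-scratch oracle: rebuild a graph from the current segmentation.

    Returns a fresh Rag built by plain pixel iteration over the merged
    label image, plus a mapping from live node ids of ``g`` to labels of
    the fresh graph, so cached features can be compared against features
    computed without any cache combination.
    """
    seg = g.current_segmentation()
    manager = manager_from_config(g.manager.to_config())
    fresh = Rag(seg, g.probabilities, g.connectivity, manager, g.zero_is_boundary)
    mapping = {}
    flat = seg.ravel()
    for n in g.live_nodes():
        mapping[n] = int(flat[g.node_pixels[n][0]])
    return fresh, mapping


def random_merge_walk(g: Rag, n_merges: int, seed: int) -> None:
    """Execute ``n_merges`` uniformly random valid merges in place."""
    rng = np.random.default_rng(seed)
    for _ in range(n_merges):
        edges = sorted(tuple(sorted(e)) for e in g.graph.edges)
        if not edges:
            break
        u, v = edges[rng.integers(len(edges))]
        g.merge_nodes(u, v)
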