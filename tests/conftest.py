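"""Shared fixtures: small swarms, rendered stacks and random graphs."""

from __future__ import annotations

import numpy as np
import pytest

from swarmdim.isomap import NeighborGraph
from swarmdim.render import RenderSpec, render_frames
from swarmdim.swarm import SwarmParams, SwarmTrajectory, simulate_swarm


@pytest.fixture(scope="session")
def small_trajectory() -> SwarmTrajectory:
    params = SwarmParams(n_agents=8, domain_size=10.0, speed=0.1,
                         noise_eta=0.5, interaction_radius=2.0,
                         boundary="reflective", seed=42)
    return simulate_swarm(params, n_steps=30)


@pytest.fixture(scope="session")
def small_stack(small_trajectory):
    return render_frames(small_trajectory, RenderSpec(width=64, height=48,
                                                      agent_radius=3))


def random_geometric_graph(n: int, nu: int, seed: int) -> NeighborGraph:
    """A knn graph over random planar points: a convenient random weighted
    graph whose weights satisfy the triangle inequality."""
    from swarmdim.isomap import build_knn_graph

    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 1, size=(n, 2))
    return build_knn_graph(pts, nu=nu)


def enumerate_shortest_paths(graph: NeighborGraph) -> np.ndarray:
    """Exhaustive simple-path enumeration oracle (exponential; tiny graphs
    only).  Independent of any shortest-path library routine."""
    w = graph.weights
    n = graph.n_vertices
    best = np.full((n, n), np.inf)
    np.fill_diagonal(best, 0.0)
    adj = [np.flatnonzero(np.isfinite(w[i]) & (np.arange(n) != i)) for i in range(n)]

    def dfs(start: int, current: int, visited: set[int], length: float) -> None:
        for nxt in adj[current]:
            if nxt in visited:
                continue
            new_len = length + w[current, nxt]
            if new_len < best[start, nxt]:
                best[start, nxt] = new_len
            # prune: extending a path longer than the incumbent cannot win
            if new_len <= best[start, nxt]:
                dfs(start, int(nxt), visited | {int(nxt)}, new_len)

    for s in range(n):
        dfs(s, s, {s}, 0.0)
    return best
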