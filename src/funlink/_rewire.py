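"""Degree-preserving double-edge-swap kernel.

Works on integer edge arrays plus a dense boolean adjacency matrix, which
keeps edge-existence checks O(1) and lets numba compile the inner loop.
If numba is unavailable the same function runs as plain Python (identical
results, just slower).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=True)
def _swap_kernel(u, v, adj, e1s, e2s):  # pragma: no cover - jit-compiled
    """Attempt one double-edge swap per (e1, e2) proposal, in place.

    Edges (a,b) and (c,d) become (a,c) and (b,d) unless that would create
    a self-loop or a duplicate edge, in which case the attempt is skipped.
    Every node keeps its exact degree.
    """
    n_attempts = e1s.shape[0]
    accepted = 0
    for t in range(n_attempts):
        e1 = e1s[t]
        e2 = e2s[t]
        if e1 == e2:
            continue
        a = u[e1]
        b = v[e1]
        c = u[e2]
        d = v[e2]
        if a == c or b == d:  # would create a self-loop
            continue
        if adj[a, c] or adj[b, d]:  # would create a duplicate edge
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, c] = True
        adj[c, a] = True
        adj[b, d] = True
        adj[d, b] = True
        u[e1] = a
        v[e1] = c
        u[e2] = b
        v[e2] = d
        accepted += 1
    return accepted


def build_adjacency(u: np.ndarray, v: np.ndarray, n_nodes: int) -> np.ndarray:
    adj = np.zeros((n_nodes, n_nodes), dtype=np.bool_)
    adj[u, v] = True
    adj[v, u] = True
    return adj


def rewire_arrays(
    u: np.ndarray,
    v: np.ndarray,
    n_nodes: int,
    swaps_per_edge: int,
    rng: np.random.Generator,
    adj: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Return rewired copies of (u, v) after ``swaps_per_edge * n_edges``
    swap attempts; also returns the number of accepted swaps."""
    m = u.shape[0]
    if m < 2:
        return u.copy(), v.copy(), 0
    uu = u.copy()
    vv = v.copy()
    a = build_adjacency(uu, vv, n_nodes) if adj is None else adj
    n_attempts = int(swaps_per_edge) * m
    e1s = rng.integers(0, m, size=n_attempts)
    e2s = rng.integers(0, m, size=n_attempts)
    accepted = _swap_kernel(uu, vv, a, e1s, e2s)
    return uu, vv, int(accepted)
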