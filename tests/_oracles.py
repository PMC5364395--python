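"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive and self-contained: hand-rolled BFS,
exhaustive geodesic enumeration, and direct kernel-sum convolution.  None of
it calls networkx or the package's own fast paths.
"""

from collections import deque
from fractions import Fraction


def adjacency_from_dual(dual) -> dict[str, set[str]]:
    return {s: set(dual.neighbors(s)) for s in dual.nodes()}


def bfs_distances(adj: dict[str, set[str]], source: str) -> dict[str, int]:
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in sorted(adj[u]):
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def brute_degree(adj, s) -> int:
    return len(adj[s])


def brute_closeness(adj, s) -> Fraction:
    d = bfs_distances(adj, s)
    assert len(d) == len(adj), "graph disconnected"
    return Fraction(1, sum(d.values()))


def enumerate_geodesics(adj, a, b) -> list[tuple[str, ...]]:
    """All shortest paths from a to b by depth-limited DFS."""
    target_len = bfs_distances(adj, a)[b]
    dist_to_b = bfs_distances(adj, b)
    paths = []

    def extend(path):
        u = path[-1]
        if u == b:
            paths.append(tuple(path))
            return
        for v in sorted(adj[u]):
            # only steps that stay on some geodesic
            if dist_to_b.get(v, 1 << 30) == dist_to_b[u] - 1 and len(path) <= target_len:
                extend(path + [v])

    extend([a])
    return paths


def brute_betweenness(adj, s) -> Fraction:
    """Freeman betweenness: unordered pairs, endpoints excluded, exact rationals."""
    nodes = sorted(adj)
    total = Fraction(0)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            if a == s or b == s:
                continue
            geos = enumerate_geodesics(adj, a, b)
            through = sum(1 for g in geos if s in g[1:-1])
            total += Fraction(through, len(geos))
    return total


def brute_betweenness_total(adj) -> Fraction:
    """Summed betweenness over all nodes (conservation cross-check)."""
    return sum((brute_betweenness(adj, s) for s in adj), Fraction(0))


def naive_design_column(onsets, durations, amplitudes, kernel, tr, n_scans,
                        oversampling=16):
    """Direct kernel-sum convolution: for every scan time, sum each event's
    kernel contribution evaluated at the scan's offset from the (bin-snapped)
    event onset.  Independent of numpy.convolve."""
    dt = tr / oversampling
    out = [0.0] * n_scans
    for onset, dur, amp in zip(onsets, durations, amplitudes):
        i0 = round(onset / dt)
        if dur == 0.0:
            for n in range(n_scans):
                k = n * oversampling - i0
                if 0 <= k < len(kernel):
                    out[n] += amp * kernel[k]
        else:
            i1 = round((onset + dur) / dt)
            for i in range(i0, i1):
                for n in range(n_scans):
                    k = n * oversampling - i
                    if 0 <= k < len(kernel):
                        out[n] += amp * kernel[k] * dt
    return out
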