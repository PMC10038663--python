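"""Independent brute-force oracles used to validate the implementations.

These deliberately avoid the library code paths they check: interval
merging by pairwise transitive closure, window scoring by per-position
dictionary lookup, and betweenness both by explicit shortest-path
enumeration (small graphs) and by batched walk-count matrices
(exhaustive sweeps).
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# --- interval merging -------------------------------------------------------


def naive_merge(intervals: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    """O(n^2) transitive-closure merge of (start, end) half-open intervals."""
    clusters = [[iv] for iv in intervals]

    def close(a, b):
        lo = max(min(s for s, _ in a), min(s for s, _ in b))
        # separation between two clusters' hulls
        a_lo, a_hi = min(s for s, _ in a), max(e for _, e in a)
        b_lo, b_hi = min(s for s, _ in b), max(e for _, e in b)
        if a_hi < b_lo:
            return b_lo - a_hi <= gap
        if b_hi < a_lo:
            return a_lo - b_hi <= gap
        return True  # overlapping hulls

    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if close(clusters[i], clusters[j]):
                    clusters[i] = clusters[i] + clusters[j]
                    del clusters[j]
                    changed = True
                    break
            if changed:
                break
    out = sorted(
        (min(s for s, _ in c), max(e for _, e in c)) for c in clusters
    )
    return out


# --- PWM window scoring -----------------------------------------------------


def score_window(counts, kmer: str, pseudocount: float = 0.1) -> float:
    """Per-position dict-based log2-odds sum (uniform background)."""
    total = 0.0
    bg = 0.25
    for i, base in enumerate(kmer.upper()):
        col = counts[i]
        colsum = sum(col)
        if base in "ACGT":
            f = (col["ACGT".index(base)] + pseudocount * bg) / (colsum + pseudocount)
            total += math.log2(f / bg)
        # N contributes 0
    return total


def brute_scan(sequence: str, counts, threshold: float, pseudocount: float = 0.1):
    """All above-threshold windows on both strands, by direct enumeration."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    L = len(counts)
    seq = sequence.upper()
    hits = []
    for off in range(len(seq) - L + 1):
        window = seq[off : off + L]
        s = score_window(counts, window, pseudocount)
        if s > threshold:
            hits.append((off, "+", s, window))
        rc = "".join(comp[b] for b in reversed(window))
        s = score_window(counts, rc, pseudocount)
        if s > threshold:
            hits.append((off, "-", s, rc))
    return sorted(hits, key=lambda h: (h[0], h[1]))


# --- betweenness ------------------------------------------------------------


def enumerate_betweenness(adj: dict) -> dict:
    """CB by explicit enumeration of every shortest directed path."""
    nodes = sorted(adj)
    succ = {u: sorted(set(adj.get(u, ())) - {u}) for u in nodes}

    def all_shortest_paths(s, t):
        # BFS distances, then DFS along decreasing remaining distance
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in succ[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        if t not in dist:
            return []
        paths = []

        def dfs(u, path):
            if u == t:
                paths.append(path)
                return
            for v in succ[u]:
                if dist.get(v) == dist[u] + 1 and dist[v] <= dist[t]:
                    dfs(v, path + [v])

        dfs(s, [s])
        return [p for p in paths if len(p) - 1 == dist[t]]

    cb = {v: 0.0 for v in nodes}
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            paths = all_shortest_paths(s, t)
            if not paths:
                continue
            sigma = len(paths)
            for v in nodes:
                if v == s or v == t:
                    continue
                through = sum(1 for p in paths if v in p[1:-1])
                cb[v] += through / sigma
    return cb


def batch_betweenness(adjacency: np.ndarray) -> np.ndarray:
    """CB for a batch of digraphs via shortest-walk count matrices.

    ``adjacency``: (B, n, n) 0/1 array (diagonal ignored).  Returns a
    (B, n) array.  A minimal-length walk is necessarily a simple path,
    so the count of walks at the shortest length equals the count of
    shortest paths.
    """
    A = adjacency.astype(np.float64).copy()
    B, n, _ = A.shape
    idx = np.arange(n)
    A[:, idx, idx] = 0.0

    INF = np.inf
    dist = np.full((B, n, n), INF)
    sigma = np.zeros((B, n, n))
    dist[:, idx, idx] = 0.0
    sigma[:, idx, idx] = 1.0

    walk = A.copy()
    for length in range(1, n):
        newly = (walk > 0) & (dist == INF)
        dist[newly] = length
        sigma[newly] = walk[newly]
        if length < n - 1:
            walk = walk @ A

    cb = np.zeros((B, n))
    for i in range(n):
        d_si = dist[:, :, i]  # (B, n) distances s -> i
        d_it = dist[:, i, :]  # (B, n) distances i -> t
        s_si = sigma[:, :, i]
        s_it = sigma[:, i, :]
        # through[b, s, t] for this i
        on_path = (
            d_si[:, :, None] + d_it[:, None, :] == dist
        ) & np.isfinite(dist)
        contrib = np.where(
            on_path & (sigma > 0),
            (s_si[:, :, None] * s_it[:, None, :]) / np.where(sigma > 0, sigma, 1.0),
            0.0,
        )
        contrib[:, i, :] = 0.0
        contrib[:, :, i] = 0.0
        contrib[:, idx, idx] = 0.0
        cb[:, i] = contrib.sum(axis=(1, 2))
    return cb


def all_digraph_masks(n: int):
    """Iterate adjacency matrices of every labelled digraph on n nodes."""
    offdiag = [(i, j) for i in range(n) for j in range(n) if i != j]
    m = len(offdiag)
    for mask in range(2 ** m):
        A = np.zeros((n, n), dtype=np.int8)
        for bit, (i, j) in enumerate(offdiag):
            if mask >> bit & 1:
                A[i, j] = 1
        yield A


def mask_batch(n: int, masks: np.ndarray) -> np.ndarray:
    """Vectorized adjacency construction for an array of bitmasks."""
    offdiag = [(i, j) for i in range(n) for j in range(n) if i != j]
    m = len(offdiag)
    bits = (masks[:, None] >> np.arange(m)[None, :]) & 1
    A = np.zeros((len(masks), n, n), dtype=np.int8)
    for bit, (i, j) in enumerate(offdiag):
        A[:, i, j] = bits[:, bit]
    return A
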