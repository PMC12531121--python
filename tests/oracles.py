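"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result by exhaustive search or direct
enumeration, deliberately sharing no code with the implementation paths
it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra


def brute_force_best_candidate(x: np.ndarray, min_seg: int = 2):
    """Exhaustive argmax of the two-sample energy statistic over all
    (split, right-end) candidates, by direct triple loop.

    Returns (q, k1, k2) with ties resolved to the smallest (k1, k2).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    best = (-np.inf, None, None)
    for k1 in range(min_seg, n - min_seg + 1):
        for k2 in range(k1 + min_seg, n + 1):
            left, right = x[:k1], x[k1:k2]
            cross = np.abs(left[:, None] - right[None, :]).mean()
            wl = (
                np.abs(left[:, None] - left[None, :])[np.triu_indices(len(left), 1)].mean()
                if len(left) > 1 else 0.0
            )
            wr = (
                np.abs(right[:, None] - right[None, :])[np.triu_indices(len(right), 1)].mean()
                if len(right) > 1 else 0.0
            )
            q = (len(left) * len(right) / (len(left) + len(right))) * (2 * cross - wl - wr)
            if q > best[0] + 1e-12:
                best = (q, k1, k2)
    return best


def bfs_event_distance(a, b, max_overshoot: int = 1) -> float:
    """Minimum number of contiguous +/-1 events turning ``a`` into ``b``.

    Breadth-first search over the full state graph: an event picks a
    contiguous interval whose states are all >= 1 (state 0 can neither
    be raised nor lowered) and adds +1 or -1 to it.  States are capped
    at ``max(a, b) + max_overshoot`` per position, which is sufficient
    for minimal paths.  Returns inf when unreachable.
    """
    a = tuple(int(v) for v in a)
    b = tuple(int(v) for v in b)
    n = len(a)
    caps = tuple(max(max(a), max(b)) + max_overshoot for _ in range(n))
    if a == b:
        return 0.0

    # enumerate all states once, index them, build the unit-cost graph
    spaces = [range(c + 1) for c in caps]
    states = list(itertools.product(*spaces))
    index = {s: i for i, s in enumerate(states)}
    rows, cols = [], []
    for s in states:
        si = index[s]
        for i in range(n):
            for j in range(i, n):
                window = s[i : j + 1]
                if min(window) < 1:
                    continue
                for delta in (1, -1):
                    t = list(s)
                    for p in range(i, j + 1):
                        t[p] += delta
                    t = tuple(t)
                    if all(0 <= t[p] <= caps[p] for p in range(n)):
                        rows.append(si)
                        cols.append(index[t])
    m = len(states)
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(m, m))
    dist = dijkstra(graph, directed=True, indices=index[a], unweighted=True)
    return float(dist[index[b]])


def bfs_all_pairs_matrix(length: int, max_state: int, overshoot: int = 1):
    """All-pairs minimum event counts over every state vector of a length.

    Builds the unit-cost event graph once (states 0..max_state+overshoot
    per position; an event adds +/-1 to a contiguous all-positive run)
    and returns (states, dist) where ``dist[i, j]`` is the directed
    minimum number of events from ``states[i]`` to ``states[j]`` (inf if
    unreachable).
    """
    cap = max_state + overshoot
    spaces = [range(cap + 1)] * length
    states = list(itertools.product(*spaces))
    index = {s: i for i, s in enumerate(states)}
    rows, cols = [], []
    for s in states:
        si = index[s]
        for i in range(length):
            for j in range(i, length):
                if min(s[i : j + 1]) < 1:
                    continue
                for delta in (1, -1):
                    t = list(s)
                    for p in range(i, j + 1):
                        t[p] += delta
                    if all(0 <= v <= cap for v in t):
                        rows.append(si)
                        cols.append(index[tuple(t)])
    m = len(states)
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(m, m))
    dist = dijkstra(graph, directed=True, unweighted=True)
    return states, dist


def energy_argmax_direct(x: np.ndarray, min_seg: int = 2):
    """Argmax of the two-sample energy statistic over all (k1, k2)
    candidates on the series and its reversal, evaluated from the
    definition (per-k1 loop with running sums; no shared code with the
    implementation).

    Returns (q, boundaries) where ``boundaries`` is the set of interior
    boundary positions of the winning candidate in forward coordinates.
    """
    x = np.asarray(x, dtype=float)

    def orientation_best(y):
        n = len(y)
        # within-left sums for every prefix
        wl_cum = np.zeros(n + 1)
        for j in range(1, n):
            wl_cum[j + 1] = wl_cum[j] + np.abs(y[:j] - y[j]).sum()
        best = (-np.inf, None, None)
        for k1 in range(min_seg, n - min_seg + 1):
            left = y[:k1]
            rest = y[k1:]
            m_max = len(rest)
            cross = np.abs(left[:, None] - rest[None, :]).sum(axis=0).cumsum()
            t = np.zeros(m_max)
            for j in range(1, m_max):
                t[j] = np.abs(rest[:j] - rest[j]).sum()
            within_r = np.cumsum(t)
            ms = np.arange(1, m_max + 1)
            with np.errstate(divide="ignore", invalid="ignore"):
                mean_cross = cross / (k1 * ms)
                mean_wl = (wl_cum[k1] / (k1 * (k1 - 1) / 2)) if k1 > 1 else 0.0
                mean_wr = np.where(ms > 1, within_r / (ms * (ms - 1) / 2), 0.0)
                q = (k1 * ms / (k1 + ms)) * (2 * mean_cross - mean_wl - mean_wr)
            q[: min_seg - 1] = -np.inf
            i = int(np.argmax(q))
            if q[i] > best[0] + 1e-12:
                best = (float(q[i]), k1, k1 + i + 1)
        return best

    n = len(x)
    qf, k1f, k2f = orientation_best(x)
    qr, k1r, k2r = orientation_best(x[::-1])
    if qf >= qr:
        bounds = {k1f} | ({k2f} if k2f < n else set())
        return qf, bounds
    bounds = {n - k1r} | ({n - k2r} if k2r < n else set())
    return qr, {b for b in bounds if 0 < b < n}


def exhaustive_min_consistent_segments(states: np.ndarray) -> int:
    """Smallest number of segments exactly representing every row.

    ``states`` is (cells x bins) for a single chromosome.  Tries every
    subset of internal boundaries and counts the cheapest consistent one;
    feasibility of a subset means every cell is constant on every
    resulting segment.
    """
    states = np.asarray(states)
    n = states.shape[1]
    best = n
    for mask in range(1 << (n - 1)):
        bounds = [0] + [i + 1 for i in range(n - 1) if mask >> i & 1] + [n]
        ok = all(
            (states[:, a:b] == states[:, a : a + 1]).all()
            for a, b in zip(bounds[:-1], bounds[1:])
        )
        if ok:
            best = min(best, len(bounds) - 1)
    return best


def pooled_t_statistic(a, b) -> float:
    """Classic pooled two-sample t statistic, written out arithmetically."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
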