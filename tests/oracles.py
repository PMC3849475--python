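"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive: exact rational arithmetic and
exhaustive enumeration, sharing no code path with the implementations
they check.
"""

from __future__ import annotations

import itertools
from collections import deque
from fractions import Fraction
from math import comb


def brute_betweenness(nodes, edges) -> dict:
    """Unordered-pair betweenness by exhaustive geodesic counting.

    Pure-python BFS from every source computes distances and shortest-
    path counts; a node v lies on a shortest s-t path iff
    d(s,v)+d(v,t)=d(s,t), contributing paths(s,v)*paths(v,t)/paths(s,t).
    Exact rational arithmetic throughout.
    """
    adj: dict = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    def bfs(src):
        dist = {src: 0}
        paths = {src: 1}
        queue = deque([src])
        while queue:
            u = queue.popleft()
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    paths[w] = 0
                    queue.append(w)
                if dist[w] == dist[u] + 1:
                    paths[w] += paths[u]
        return dist, paths

    sp = {n: bfs(n) for n in nodes}
    result = {n: Fraction(0) for n in nodes}
    for s, t in itertools.combinations(list(nodes), 2):
        dist_s, paths_s = sp[s]
        if t not in dist_s:
            continue
        d_st = dist_s[t]
        sigma = paths_s[t]
        dist_t, paths_t = sp[t]
        for v in nodes:
            if v is s or v is t or v == s or v == t:
                continue
            if v in dist_s and v in dist_t and dist_s[v] + dist_t[v] == d_st:
                result[v] += Fraction(paths_s[v] * paths_t[v], sigma)
    return result


def hypergeom_pmf_exact(N: int, K: int, n: int, k: int) -> Fraction:
    return Fraction(comb(K, k) * comb(N - K, n - k), comb(N, n))


def hypergeom_sf_exact(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) by direct enumeration over the support."""
    hi = min(n, K)
    return sum((hypergeom_pmf_exact(N, K, n, j) for j in range(k, hi + 1)), Fraction(0))


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher by enumerating the full hypergeometric support.

    Sums the point probabilities of every table with the observed
    margins whose probability does not exceed the observed table's.
    """
    N = a + b + c + d
    K = a + b
    n = a + c
    lo, hi = max(0, n + K - N), min(n, K)
    p_obs = hypergeom_pmf_exact(N, K, n, a)
    total = Fraction(0)
    for x in range(lo, hi + 1):
        p = hypergeom_pmf_exact(N, K, n, x)
        if p <= p_obs:
            total += p
    return total
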