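"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library routines they check: radiality is
evaluated with a hand-written BFS and a direct transcription of the formula,
cis-window assignment with an all-pairs scan, and hypergeometric tails with
exact rational enumeration.
"""

from collections import deque
from fractions import Fraction
from math import comb


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                queue.append(w)
    return dist


def brute_radiality(edges, nodes) -> dict:
    """Crad per node: per-component diameter/distances via plain BFS."""
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    out = {}
    seen = set()
    for v in nodes:
        if v in seen:
            continue
        dist_from = {u: bfs_distances(adj, u) for u in bfs_distances(adj, v)}
        comp = list(dist_from)
        seen.update(comp)
        n = len(comp)
        if n == 1:
            out[comp[0]] = 0.0
            continue
        diameter = max(d for dd in dist_from.values() for d in dd.values())
        for u in comp:
            total = sum(diameter + 1 - dist_from[u][w] for w in comp if w != u)
            out[u] = total / (n - 1)
    return out


def brute_cis_links(lnc_spans, gene_spans, window) -> set:
    """All-pairs scan: {(lnc_id, gene_id)} with span gap <= window."""
    links = set()
    for lid, (lc, ls, le) in lnc_spans.items():
        for gid, (gc, gs, ge) in gene_spans.items():
            if lc != gc:
                continue
            if gs <= le and ls <= ge:
                gap = 0
            elif gs > le:
                gap = gs - le - 1
            else:
                gap = ls - ge - 1
            if gap <= window:
                links.add((lid, gid))
    return links


def exact_hypergeom_tail(k: int, M: int, K: int, n: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeom(M, K, n), as an exact rational."""
    total = Fraction(0)
    for i in range(max(k, 0), min(K, n) + 1):
        total += Fraction(comb(K, i) * comb(M - K, n - i), comb(M, n))
    return total
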