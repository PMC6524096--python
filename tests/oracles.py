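"""Independent brute-force reference implementations used to cross-check the
package's metrics. These deliberately avoid the code paths (and, where
practical, the libraries) used by the implementation."""

from __future__ import annotations

import itertools

import numpy as np


def bray_curtis_pair(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    return float(np.abs(x - y).sum() / (x + y).sum())


def unifrac_pair(tree, present_a: set, present_b: set) -> float:
    """Unweighted UniFrac by explicit branch enumeration.

    For every branch (node above the root), look at the tips below it:
    the branch is 'observed' if either community has a tip there, and
    'unique' if exactly one does.
    """
    unique = total = 0.0
    for node in tree.traverse(include_self=False):
        below = {t.name for t in node.tips()} or {node.name}
        in_a = bool(below & present_a)
        in_b = bool(below & present_b)
        if in_a or in_b:
            total += node.length
            if in_a != in_b:
                unique += node.length
    return unique / total if total else 0.0


def average_ranks(v) -> np.ndarray:
    """Ranks with ties averaged, built from plain sorting."""
    v = np.asarray(v, float)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_pair(x, y) -> float:
    rx, ry = average_ranks(x), average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    return float((rx * ry).sum() / denom)


def venn_regions(presence: dict) -> dict:
    """Region membership by enumerating all 2^n_age patterns."""
    ages = sorted(presence)
    union = set().union(*presence.values())
    out = {}
    for r in range(1, len(ages) + 1):
        for pattern in itertools.combinations(ages, r):
            inside = set(pattern)
            members = set(union)
            for a in ages:
                if a in inside:
                    members &= set(presence[a])
                else:
                    members -= set(presence[a])
            if members:
                out[frozenset(pattern)] = frozenset(members)
    return out


def betweenness(nodes, edges) -> dict:
    """Normalized betweenness by exhaustive simple-path enumeration."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    def all_paths(s, t):
        paths, stack = [], [(s, [s])]
        while stack:
            node, path = stack.pop()
            if node == t:
                paths.append(path)
                continue
            for nxt in adj[node]:
                if nxt not in path:
                    stack.append((nxt, path + [nxt]))
        return paths

    score = dict.fromkeys(nodes, 0.0)
    nodes = list(nodes)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            paths = all_paths(s, t)
            if not paths:
                continue
            m = min(len(p) for p in paths)
            shortest = [p for p in paths if len(p) == m]
            for p in shortest:
                for v in p[1:-1]:
                    score[v] += 1.0 / len(shortest)
    n = len(nodes)
    if n > 2:
        scale = 2.0 / ((n - 1) * (n - 2))
        score = {v: s * scale for v, s in score.items()}
    return score
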