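"""Independent brute-force oracles used by the test suite.

The path enumerator mirrors the scoring conventions of the DP engine
(log2-odds emissions, uniform entry into any match state, free exit from
any match state, no D<->I moves, inserts cannot open or close a path)
but shares no code with it: paths are enumerated explicitly, which is
tractable for toy profiles (n_match <= 4) and short targets (<= 6).
"""

from __future__ import annotations

import math

import numpy as np

from gpcrminer.seqio import AA_INDEX


def enumerate_scores(profile, seq: str) -> tuple[float, float]:
    """(viterbi_bits, forward_bits) by explicit path enumeration."""
    m = profile.n_match
    esc = np.empty((m, 21))
    esc[:, :20] = np.log2(profile.match_emissions / profile.background)
    esc[:, 20] = 0.0
    obs = [AA_INDEX[c] for c in seq.upper()]
    L = len(obs)
    entry = math.log2(1.0 / m)

    def tlog(arr, j):
        v = arr[j]
        return math.log2(v) if v > 0 else -math.inf

    completed: list[float] = []

    def extend(i: int, j: int, state: str, score: float) -> None:
        # (i, j) = last consumed target position / current state index
        if state == "M":
            completed.append(score)  # exit is free from any match state
        if j >= m:
            return
        if state == "M":
            if i < L:  # M_j -> M_{j+1}
                extend(i + 1, j + 1, "M",
                       score + tlog(profile.t_mm, j)
                       + esc[j, obs[i]])
            if i < L:  # M_j -> I_j
                extend(i + 1, j, "I", score + tlog(profile.t_mi, j))
            extend(i, j + 1, "D", score + tlog(profile.t_md, j))
        elif state == "I":
            if i < L:
                extend(i + 1, j, "I", score + tlog(profile.t_ii, j))
            if i < L:
                extend(i + 1, j + 1, "M",
                       score + tlog(profile.t_im, j) + esc[j, obs[i]])
        else:  # D
            if i < L and j < m:
                tj = tlog(profile.t_dm, j) if j >= 2 else -math.inf
                extend(i + 1, j + 1, "M", score + tj + esc[j, obs[i]])
            if j < m:
                tj = tlog(profile.t_dd, j) if j >= 2 else -math.inf
                extend(i, j + 1, "D", score + tj)

    for i0 in range(L):
        for j0 in range(1, m + 1):
            extend(i0 + 1, j0, "M", entry + esc[j0 - 1, obs[i0]])

    finite = [s for s in completed if s > -math.inf]
    if not finite:
        return -math.inf, -math.inf
    vit = max(finite)
    fwd = vit + math.log2(sum(2.0 ** (s - vit) for s in finite))
    return vit, fwd


def consensus_oracle(msa_rows: list[str], pseudocount: float = 1.0,
                     match_gap_fraction: float = 0.5) -> str:
    """Per-column argmax over smoothed counts, computed independently."""
    from gpcrminer.seqio import AMINO_ACIDS

    ncol = len(msa_rows[0])
    nseq = len(msa_rows)
    out = []
    for c in range(ncol):
        col = [r[c] for r in msa_rows]
        gaps = sum(1 for ch in col if ch in "-.")
        if gaps / nseq > match_gap_fraction:
            continue
        best, best_count = None, -1.0
        for aa in AMINO_ACIDS:  # alphabetical order fixes ties
            count = sum(1 for ch in col if ch == aa) + pseudocount
            if count > best_count:
                best, best_count = aa, count
        out.append(best)
    return "".join(out)


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """A random binary tree and its additive leaf-distance matrix.

    Returns (labels, distance_matrix, bipartitions) where bipartitions
    are canonicalised as frozensets of the side not containing the
    lexicographically smallest label.
    """
    labels = [f"t{i:02d}" for i in range(n_taxa)]
    # random topology by sequential attachment; store as adjacency
    next_id = n_taxa
    edges: dict[tuple[int, int], float] = {}

    def add_edge(a, b, w):
        edges[(a, b)] = w
        edges[(b, a)] = w

    def blen():
        return float(rng.uniform(0.1, 1.0))

    # start with a cherry
    add_edge(0, next_id, blen())
    add_edge(1, next_id, blen())
    internal = [next_id]
    next_id += 1
    for leaf in range(2, n_taxa):
        # split a random existing edge with a new internal node
        keys = sorted({tuple(sorted(k)) for k in edges})
        a, b = keys[int(rng.integers(len(keys)))]
        w = edges[(a, b)]
        del edges[(a, b)]
        del edges[(b, a)]
        mid = next_id
        next_id += 1
        u = float(rng.uniform(0.2, 0.8))
        add_edge(a, mid, w * u)
        add_edge(mid, b, w * (1 - u))
        add_edge(leaf, mid, blen())
        internal.append(mid)
    # all-pairs leaf distances by BFS over the tree
    adj: dict[int, list[tuple[int, float]]] = {}
    for (a, b), w in edges.items():
        adj.setdefault(a, []).append((b, w))
    d = np.zeros((n_taxa, n_taxa))
    for s in range(n_taxa):
        dist = {s: 0.0}
        stack = [s]
        while stack:
            x = stack.pop()
            for y, w in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        for t in range(n_taxa):
            d[s, t] = dist[t]
    # bipartitions of internal edges
    ref = min(labels)
    biparts = set()
    for (a, b) in {tuple(sorted(k)) for k in edges}:
        if a < n_taxa or b < n_taxa:
            continue  # leaf edge, trivial
        # leaves on the 'a' side when edge (a, b) is cut
        seen = {a, b}
        stack = [a]
        side = set()
        while stack:
            x = stack.pop()
            for y, _ in adj[x]:
                if y == b and x == a:
                    continue
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
            if x < n_taxa:
                side.add(labels[x])
        if 2 <= len(side) <= n_taxa - 2:
            names = frozenset(side)
            if ref in names:
                names = frozenset(set(labels) - names)
            biparts.add(names)
    return labels, d, biparts
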