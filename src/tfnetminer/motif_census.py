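"""Colored three-node motif census with a degree-preserving randomized null.

Every connected induced 3-node subgraph of the mixed network — directed
regulatory edges, undirected PPI edges, nodes colored up/down — is counted
and assigned to a *canonical class*: an integer code invariant under all 3!
relabelings of the triad.  Class counts are compared against an ensemble of
randomized networks produced by degree-preserving edge switching applied
independently per layer (the FANMOD-style null), yielding a z-score and an
empirical p-value per class.  Counting is induced-subgraph (each connected
triple contributes exactly one instance), and connectivity is judged on the
union of the two layers, so patterns mixing regulatory and PPI edges are
first-class motif candidates.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network_build import IntegratedNetwork

__all__ = [
    "MotifCensus",
    "canonical_code",
    "sketch",
    "enumerate_triads",
    "randomize",
    "motif_zscores",
]

# Triad encoding: 12-bit integer.
#   bits 0-2   node colors (1 = up, 0 = down) for local positions 0,1,2
#   bits 3-8   directed reg edges over ordered pairs (0,1),(0,2),(1,0),(1,2),(2,0),(2,1)
#   bits 9-11  undirected ppi edges over pairs (0,1),(0,2),(1,2)
_REG_PAIRS = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]
_PPI_PAIRS = [(0, 1), (0, 2), (1, 2)]
_PERMS = list(itertools.permutations(range(3)))


def _encode(colors: tuple[int, int, int], reg: frozenset, ppi: frozenset) -> int:
    key = colors[0] | (colors[1] << 1) | (colors[2] << 2)
    for bit, pair in enumerate(_REG_PAIRS):
        if pair in reg:
            key |= 1 << (3 + bit)
    for bit, pair in enumerate(_PPI_PAIRS):
        if pair in ppi:
            key |= 1 << (9 + bit)
    return key


def _decode(key: int) -> tuple[tuple[int, int, int], frozenset, frozenset]:
    colors = ((key >> 0) & 1, (key >> 1) & 1, (key >> 2) & 1)
    reg = frozenset(p for bit, p in enumerate(_REG_PAIRS) if key & (1 << (3 + bit)))
    ppi = frozenset(p for bit, p in enumerate(_PPI_PAIRS) if key & (1 << (9 + bit)))
    return colors, reg, ppi


def _build_tables() -> tuple[np.ndarray, np.ndarray]:
    canon = np.zeros(4096, dtype=np.int32)
    connected = np.zeros(4096, dtype=bool)
    for key in range(4096):
        colors, reg, ppi = _decode(key)
        union_pairs = {frozenset(p) for p in reg} | {frozenset(p) for p in ppi}
        connected[key] = len(union_pairs) >= 2  # any 2 of 3 possible pairs connect a triple
        best = key
        for perm in _PERMS:
            c2 = (colors[perm[0]], colors[perm[1]], colors[perm[2]])
            inv = [0, 0, 0]
            for new, old in enumerate(perm):
                inv[old] = new
            reg2 = frozenset((inv[a], inv[b]) for a, b in reg)
            ppi2 = frozenset(tuple(sorted((inv[a], inv[b]))) for a, b in ppi)
            best = min(best, _encode(c2, reg2, ppi2))
        canon[key] = best
    return canon, connected


_CANON, _CONNECTED = _build_tables()


def canonical_code(colors, reg=(), ppi=()) -> int:
    """Canonical class code of one triad given local-position edge lists.

    ``colors`` is a 3-tuple of 0/1 (down/up); ``reg`` an iterable of ordered
    local-position pairs; ``ppi`` an iterable of unordered pairs.
    """
    key = _encode(tuple(colors), frozenset(reg), frozenset(tuple(sorted(p)) for p in ppi))
    return int(_CANON[key])


def sketch(code: int) -> str:
    """Human-readable rendering of a class, e.g. ``"A→B; A→C; B–C [up,up,down]"``."""
    colors, reg, ppi = _decode(code)
    names = "ABC"
    parts = [f"{names[a]}→{names[b]}" for a, b in sorted(reg)]
    parts += [f"{names[a]}–{names[b]}" for a, b in sorted(ppi)]
    tags = ",".join("up" if c else "down" for c in colors)
    return "; ".join(parts) + f" [{tags}]"


_COLOR_BIT = {"up": 1, "down": 0}


def _color_bits(net: IntegratedNetwork) -> dict[str, int]:
    bits: dict[str, int] = {}
    for n, d in net.nodes.items():
        if d.color not in _COLOR_BIT:
            raise ValueError(f"node {n!r} has no up/down color; motif census needs colored nodes")
        bits[n] = _COLOR_BIT[d.color]
    return bits


def _adjacency(reg: set[tuple[str, str]], ppi: set[tuple[str, str]], nodes) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for a, b in reg:
        if a != b:
            adj[a].add(b)
            adj[b].add(a)
    for a, b in ppi:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def _census(
    adj: dict[str, set[str]],
    colors: dict[str, int],
    reg: set[tuple[str, str]],
    ppi: set[tuple[str, str]],
) -> Counter:
    """Count connected induced triads by canonical class.

    Every connected 3-set has at least one node adjacent to the other two, so
    enumerating neighbour pairs around each centre (with de-duplication)
    covers all instances exactly once.
    """
    counts: Counter = Counter()
    seen: set[frozenset] = set()
    canon = _CANON
    for u, nbrs in adj.items():
        if len(nbrs) < 2:
            continue
        for v, w in itertools.combinations(sorted(nbrs), 2):
            trip = frozenset((u, v, w))
            if trip in seen:
                continue
            seen.add(trip)
            key = colors[u] | (colors[v] << 1) | (colors[w] << 2)
            if (u, v) in reg:
                key |= 1 << 3
            if (u, w) in reg:
                key |= 1 << 4
            if (v, u) in reg:
                key |= 1 << 5
            if (v, w) in reg:
                key |= 1 << 6
            if (w, u) in reg:
                key |= 1 << 7
            if (w, v) in reg:
                key |= 1 << 8
            if ((u, v) if u < v else (v, u)) in ppi:
                key |= 1 << 9
            if ((u, w) if u < w else (w, u)) in ppi:
                key |= 1 << 10
            if ((v, w) if v < w else (w, v)) in ppi:
                key |= 1 << 11
            counts[int(canon[key])] += 1
    return counts


def enumerate_triads(net: IntegratedNetwork) -> dict[int, int]:
    """Census of the real network: canonical class code → count.

    Networks with fewer than three nodes yield an empty census.  Regulatory
    self-loops do not participate in triads and are ignored here.
    """
    if net.n_nodes < 3:
        return {}
    reg = {e for e in net.reg_edges if e[0] != e[1]}
    ppi = set(net.ppi_edges)
    colors = _color_bits(net)
    adj = _adjacency(reg, ppi, net.nodes)
    return dict(_census(adj, colors, reg, ppi))


# ---------------------------------------------------------------------------
# Degree-preserving randomization
# ---------------------------------------------------------------------------


def _switch_directed(
    edges: set[tuple[str, str]], attempts: int, rng: np.random.Generator
) -> set[tuple[str, str]]:
    """Directed double-edge swaps preserving every in- and out-degree."""
    lst = [e for e in edges if e[0] != e[1]]
    fixed = {e for e in edges if e[0] == e[1]}
    m = len(lst)
    if m < 2:
        return set(edges)
    eset = set(lst)
    idx = rng.integers(0, m, size=2 * attempts)
    for t in range(attempts):
        i, j = idx[2 * t], idx[2 * t + 1]
        if i == j:
            continue
        a, b = lst[i]
        c, d = lst[j]
        # proposed: a→d, c→b
        if a == d or c == b or (a, d) in eset or (c, b) in eset:
            continue
        eset.discard((a, b))
        eset.discard((c, d))
        eset.add((a, d))
        eset.add((c, b))
        lst[i] = (a, d)
        lst[j] = (c, b)
    return eset | fixed


def _switch_undirected(
    edges: set[tuple[str, str]], attempts: int, rng: np.random.Generator
) -> set[tuple[str, str]]:
    """Undirected double-edge swaps preserving every degree."""
    lst = list(edges)
    m = len(lst)
    if m < 2:
        return set(edges)
    eset = set(lst)
    idx = rng.integers(0, m, size=2 * attempts)
    flips = rng.integers(0, 2, size=attempts)
    for t in range(attempts):
        i, j = idx[2 * t], idx[2 * t + 1]
        if i == j:
            continue
        a, b = lst[i]
        c, d = lst[j]
        if flips[t]:
            c, d = d, c
        # proposed: {a, d}, {c, b}
        if len({a, b, c, d}) < 4:
            continue
        e1 = (a, d) if a < d else (d, a)
        e2 = (b, c) if b < c else (c, b)
        if e1 in eset or e2 in eset:
            continue
        eset.discard(lst[i])
        eset.discard(lst[j])
        eset.add(e1)
        eset.add(e2)
        lst[i] = e1
        lst[j] = e2
    return eset


def randomize(
    net: IntegratedNetwork,
    n_swaps_factor: int = 10,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> IntegratedNetwork:
    """Randomize each edge layer independently by degree-preserving switching.

    Directed swaps preserve each node's in- and out-degree; undirected swaps
    preserve degree.  Node colors and annotations are unchanged.  Attempted
    swaps per layer = ``n_swaps_factor`` × layer size; proposals creating
    self-loops or duplicate edges are rejected.  Layers with fewer than two
    switchable edges pass through unchanged.
    """
    if n_swaps_factor < 1:
        raise ValueError("n_swaps_factor must be a positive integer")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = net.copy()
    out.reg_edges = _switch_directed(net.reg_edges, n_swaps_factor * len(net.reg_edges), rng)
    out.ppi_edges = _switch_undirected(net.ppi_edges, n_swaps_factor * len(net.ppi_edges), rng)
    return out


# ---------------------------------------------------------------------------
# z-scores against the null ensemble
# ---------------------------------------------------------------------------


@dataclass
class MotifCensus:
    """Per-class real counts and null statistics.

    ``table`` is indexed by canonical class code with columns ``sketch,
    count_real, null_mean, null_sd, z_score, p_empirical, is_motif``.  Only
    classes present in the real network are reported; the z-score is NaN
    where the null is degenerate (sd 0, equal count) and ±inf where the null
    is degenerate but the real count differs.  ``p_empirical`` is the
    fraction of random networks whose class count reaches the real count
    (resolution 1/n_random).
    """

    table: pd.DataFrame
    n_random: int

    def motifs(self) -> pd.DataFrame:
        return self.table[self.table["is_motif"]]


def motif_zscores(
    net: IntegratedNetwork,
    n_random: int = 1000,
    seed: int = 0,
    n_swaps_factor: int = 10,
    z_threshold: float = 2.0,
) -> MotifCensus:
    """Score each real triad class against the switching-randomized ensemble."""
    if n_random < 2:
        raise ValueError("n_random must be at least 2")
    real = enumerate_triads(net)
    classes = sorted(real)
    if not classes:
        empty = pd.DataFrame(
            columns=["sketch", "count_real", "null_mean", "null_sd", "z_score", "p_empirical", "is_motif"]
        )
        empty.index.name = "canonical_code"
        return MotifCensus(table=empty, n_random=n_random)
    rng = np.random.default_rng(seed)
    reg0 = {e for e in net.reg_edges if e[0] != e[1]}
    ppi0 = set(net.ppi_edges)
    colors = _color_bits(net)
    pos = {c: i for i, c in enumerate(classes)}
    null_counts = np.zeros((n_random, len(classes)), dtype=np.int64)
    for r in range(n_random):
        reg = _switch_directed(reg0, n_swaps_factor * len(reg0), rng)
        ppi = _switch_undirected(ppi0, n_swaps_factor * len(ppi0), rng)
        adj = _adjacency(reg, ppi, net.nodes)
        for cls, cnt in _census(adj, colors, reg, ppi).items():
            if cls in pos:
                null_counts[r, pos[cls]] = cnt
    real_arr = np.array([real[c] for c in classes], dtype=float)
    mean = null_counts.mean(axis=0)
    sd = null_counts.std(axis=0, ddof=1)
    z = np.full(len(classes), np.nan)
    nonzero = sd > 0
    z[nonzero] = (real_arr[nonzero] - mean[nonzero]) / sd[nonzero]
    degen_hi = (~nonzero) & (real_arr > mean)
    degen_lo = (~nonzero) & (real_arr < mean)
    z[degen_hi] = np.inf
    z[degen_lo] = -np.inf
    p_emp = (null_counts >= real_arr[None, :]).mean(axis=0)
    with np.errstate(invalid="ignore"):
        is_motif = np.where(np.isnan(z), False, (z >= z_threshold) & (p_emp <= 0.05))
    table = pd.DataFrame(
        {
            "sketch": [sketch(c) for c in classes],
            "count_real": real_arr.astype(int),
            "null_mean": mean,
            "null_sd": sd,
            "z_score": z,
            "p_empirical": p_emp,
            "is_motif": is_motif.astype(bool),
        },
        index=pd.Index(classes, name="canonical_code"),
    )
    return MotifCensus(table=table, n_random=n_random)
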