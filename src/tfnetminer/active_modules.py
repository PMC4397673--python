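"""Active-subnetwork search by aggregate z-scores (jActiveModules-style).

Each node's DE p-value is mapped to ``z_i = Φ⁻¹(1 − p_i)``; a candidate
subnetwork A scores ``Z_A = Σ_{i∈A} z_i / √|A|``.  The raw score is not
comparable across sizes — even on null data a *searched* maximum of Z over
connected k-subgraphs grows with k — so each size is calibrated against the
background of the search itself: node scores are permuted across the
network, the same greedy growth is run, and the best ``Z_k`` found at every
size k is recorded.  The corrected score is ``(Z_A − μ_k)/σ_k`` with
``μ_k, σ_k`` the permutation mean and sd of that searched maximum.  This
max-calibration is what stops a module from opportunistically absorbing
moderately scoring neighbours: an addition only helps if it beats what an
equally greedy search finds on scrambled data.

Growth is deterministic best-z-neighbour expansion from the top-z seed
nodes; every seed's trajectory is scored at all sizes and the best prefix
(argmax of the corrected score) becomes a candidate module.

:func:`background_calibration` additionally exposes the simpler Monte-Carlo
background over uniform random k-subsets (no connectivity, no search); it is
the building block for validating the z aggregation itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .network_build import IntegratedNetwork

__all__ = [
    "ActiveModule",
    "node_z",
    "aggregate_z",
    "background_calibration",
    "subset_moments",
    "search_background",
    "search_modules",
]

_P_CLIP = 1e-12
_SD_FLOOR = 1e-9


@dataclass(frozen=True)
class ActiveModule:
    """A connected subnetwork enriched for low p-values."""

    members: frozenset[str]
    raw_score: float
    corrected_score: float
    member_tfs: frozenset[str]


def node_z(p):
    """Map a p-value (or array) to ``z = Φ⁻¹(1 − p)``.

    p must lie in (0, 1]; values are clipped into [1e−12, 1 − 1e−12] so that
    underflowing p-values keep a finite z.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0.0) or np.any(arr > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    z = stats.norm.isf(np.clip(arr, _P_CLIP, 1.0 - _P_CLIP))
    return float(z) if np.isscalar(p) else z


def aggregate_z(zs) -> float:
    """``Z_A = Σ z_i / √k`` for a set of member z-values."""
    arr = np.asarray(zs, dtype=float)
    if arr.size == 0:
        raise ValueError("empty member set")
    return float(arr.sum() / np.sqrt(arr.size))


def background_calibration(
    all_z, k: int, n_draws: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo mean and sd of Z over uniform random k-subsets of nodes.

    Subsets are drawn without a connectivity constraint.  A degenerate
    background (σ_k = 0, e.g. all z equal) is an error.
    """
    z = np.asarray(all_z, dtype=float)
    if not 1 <= k <= z.size:
        raise ValueError("k must satisfy 1 <= k <= number of nodes")
    if n_draws < 100:
        raise ValueError("n_draws must be at least 100")
    rng = np.random.default_rng(seed)
    sums = np.empty(n_draws)
    for i in range(n_draws):
        sums[i] = z[rng.choice(z.size, size=k, replace=False)].sum()
    scores = sums / np.sqrt(k)
    mu = float(scores.mean())
    sd = float(scores.std(ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate background: sigma_k is zero")
    return mu, sd


def subset_moments(all_z, k: int) -> tuple[float, float]:
    """Exact moments of Z over uniform k-subsets (SRS without replacement).

    ``μ_k = √k · z̄`` and ``σ_k = S · √((N − k)/N)`` with S the sample
    standard deviation (ddof = 1) of the node z-values.  Closed form of what
    :func:`background_calibration` estimates by Monte Carlo.
    """
    z = np.asarray(all_z, dtype=float)
    n = z.size
    if not 1 <= k <= n:
        raise ValueError("k must satisfy 1 <= k <= number of nodes")
    mu = float(np.sqrt(k) * z.mean())
    if n == 1:
        return mu, 0.0
    s = float(z.std(ddof=1))
    return mu, s * float(np.sqrt((n - k) / n))


# ---------------------------------------------------------------------------
# Greedy growth and permutation calibration
# ---------------------------------------------------------------------------


def _grow_path(
    adj: Mapping[str, set[str]], z: Mapping[str, float], seed_node: str, cap: int
) -> tuple[np.ndarray, list[str]]:
    """Grow by repeatedly adding the best-z frontier node (ties by symbol).

    Returns cumulative member-z sums (one entry per size) and the addition
    order; stops at ``cap`` members or an empty frontier.
    """
    members = [seed_node]
    mem = {seed_node}
    sum_z = z[seed_node]
    frontier = set(adj[seed_node])
    sums = [sum_z]
    while len(mem) < cap and frontier:
        v = max(frontier, key=lambda n: (z[n], n))
        mem.add(v)
        members.append(v)
        sum_z += z[v]
        frontier |= adj[v]
        frontier -= mem
        sums.append(sum_z)
    return np.asarray(sums), members


def _trajectory_scores(sums: np.ndarray) -> np.ndarray:
    return sums / np.sqrt(np.arange(1, sums.size + 1))


def search_background(
    adj: Mapping[str, set[str]],
    all_z: Mapping[str, float],
    cap: int,
    n_perm: int = 100,
    n_seeds: int = 10,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation background of the searched maximum ``Z_k`` per size.

    Node scores are permuted across the fixed topology ``n_perm`` times; the
    same greedy growth used on real data is run from the top ``n_seeds``
    permuted-z seeds, and the best Z at each size across seeds is recorded.
    Returns (μ, σ) arrays of length ``cap`` (index k−1 for size k).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    nodes = sorted(adj)
    arr = np.array([all_z[n] for n in nodes])
    best = np.full((n_perm, cap), -np.inf)
    for p in range(n_perm):
        perm = rng.permutation(arr.size)
        pz = {n: arr[perm[i]] for i, n in enumerate(nodes)}
        seeds = sorted(nodes, key=lambda n: (-pz[n], n))[:n_seeds]
        for s in seeds:
            sums, _ = _grow_path(adj, pz, s, cap)
            zk = _trajectory_scores(sums)
            best[p, : zk.size] = np.maximum(best[p, : zk.size], zk)
    # sizes never reached on some permutation (tiny graphs): ignore -inf rows
    mu = np.empty(cap)
    sd = np.empty(cap)
    for k in range(cap):
        col = best[:, k]
        col = col[np.isfinite(col)]
        if col.size >= 2:
            mu[k] = col.mean()
            sd[k] = col.std(ddof=1)
        elif col.size == 1:
            mu[k], sd[k] = col[0], 0.0
        else:
            mu[k], sd[k] = 0.0, 0.0
    return mu, sd


def _corrected(zk: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    m = zk.size
    diff = zk - mu[:m]
    out = np.zeros(m)
    wide = sd[:m] > _SD_FLOOR
    out[wide] = diff[wide] / sd[:m][wide]
    tight = ~wide & (np.abs(diff) > _SD_FLOOR)
    out[tight] = np.copysign(np.inf, diff[tight])
    return out


def search_modules(
    net: IntegratedNetwork,
    p_values: Mapping[str, float],
    n_modules: int = 5,
    max_size: int = 50,
    seed: int = 0,
    max_overlap: float = 0.5,
    n_seeds: int = 10,
    n_perm: int = 200,
) -> list[ActiveModule]:
    """Find up to ``n_modules`` high-scoring connected modules.

    Growth trajectories from the top-z seed nodes are scored at every size
    against the permutation background (see module docstring); each seed
    contributes its best prefix, and candidates are returned best-first
    subject to pairwise Jaccard overlap <= ``max_overlap`` (set 1.0 to
    disable the filter — overlapping modules can be biologically real).
    Deterministic for a fixed ``seed``.
    """
    if not net.nodes:
        raise ValueError("empty network")
    nodes = sorted(net.nodes)
    missing = [n for n in nodes if n not in p_values]
    if missing:
        raise ValueError(f"nodes without p-values: {missing[:5]}...")
    z = {n: node_z(p_values[n]) for n in nodes}
    adj = net.union_adjacency()
    cap = min(max_size, len(nodes))
    rng = np.random.default_rng(seed)
    mu, sd = search_background(adj, z, cap, n_perm=n_perm, n_seeds=n_seeds, rng=rng)
    tf_set = net.tf_nodes()

    candidates: dict[frozenset[str], ActiveModule] = {}
    seeds = sorted(nodes, key=lambda n: (-z[n], n))[:n_seeds]
    for s in seeds:
        sums, members = _grow_path(adj, z, s, cap)
        corr = _corrected(_trajectory_scores(sums), mu, sd)
        k = int(np.argmax(corr))
        key = frozenset(members[: k + 1])
        if key not in candidates or candidates[key].corrected_score < corr[k]:
            candidates[key] = ActiveModule(
                members=key,
                raw_score=aggregate_z([z[n] for n in key]),
                corrected_score=float(corr[k]),
                member_tfs=frozenset(key & tf_set),
            )

    ranked = sorted(candidates.values(), key=lambda m: (-m.corrected_score, sorted(m.members)))
    selected: list[ActiveModule] = []
    for mod in ranked:
        if len(selected) == n_modules:
            break
        ok = True
        for prev in selected:
            inter = len(mod.members & prev.members)
            union = len(mod.members | prev.members)
            if union and inter / union > max_overlap:
                ok = False
                break
        if ok:
            selected.append(mod)
    return selected
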