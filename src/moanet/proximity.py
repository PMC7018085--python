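"""Network-proximity cross-check via random walk with restart (RWR).

Scores every protein by its stationary random-walk-with-restart probability
on the *unweighted, undirected* skeleton of the network, restarting
uniformly over a seed set.  This is a generic proximity scorer (an RWR
stand-in, not a replication of any specific web service's scoring variant):
top-fraction cuts of several seed sets are unioned and intersected with a
biomarker list, with a hypergeometric enrichment p-value against the
network background.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy import stats

from .netio import SignedDirectedNetwork

__all__ = ["ProximityResult", "propagate_seeds", "top_fraction", "overlap_report"]


@dataclass(frozen=True)
class ProximityResult:
    scores: Mapping[str, float]
    seeds: frozenset[str]
    restart_prob: float


def propagate_seeds(
    network: SignedDirectedNetwork,
    seeds: set[str],
    restart_prob: float = 0.15,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> ProximityResult:
    """RWR stationary distribution on the undirected unweighted skeleton.

    The walker moves to a uniformly chosen neighbour with probability
    ``1 - restart_prob`` and restarts uniformly over the seeds otherwise;
    mass at zero-degree nodes is teleported back to the seeds.  Scores sum
    to 1.  Deterministic power iteration to ``tol`` in L1.
    """
    if not seeds:
        raise ValueError("seed set must be non-empty")
    missing = sorted(seeds - network.nodes)
    if missing:
        raise ValueError(f"seeds not in network: {missing}")
    if not (0.0 < restart_prob <= 1.0):
        raise ValueError("restart_prob must be in (0, 1]")
    nodes = sorted(network.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    pairs = {(index[e.source], index[e.target]) for e in network.edges}
    und = pairs | {(j, i) for i, j in pairs}
    if und:
        rows, cols = map(np.array, zip(*sorted(und)))
        A = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    else:
        A = sp.csr_matrix((n, n))
    deg = np.asarray(A.sum(axis=0)).ravel()
    zero_deg_seeds = sorted(s for s in seeds if deg[index[s]] == 0)
    if zero_deg_seeds:
        warnings.warn(
            f"seeds with no interactions carry restart mass only: {zero_deg_seeds}",
            stacklevel=2,
        )
    inv_deg = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
    W = A @ sp.diags(inv_deg)  # column-stochastic on non-dangling columns
    s = np.zeros(n)
    for seed in seeds:
        s[index[seed]] = 1.0 / len(seeds)
    dangling = deg == 0
    p = s.copy()
    r = restart_prob
    for _ in range(max_iter):
        p_new = (1.0 - r) * (W @ p) + r * s
        p_new += (1.0 - r) * p[dangling].sum() * s
        if np.abs(p_new - p).sum() < tol:
            p = p_new
            break
        p = p_new
    return ProximityResult(
        scores={nodes[i]: float(p[i]) for i in range(n)},
        seeds=frozenset(seeds),
        restart_prob=restart_prob,
    )


def top_fraction(result: ProximityResult, fraction: float = 0.02) -> set[str]:
    """The ceil(fraction * n) top-scoring proteins (ties by id ascending).

    Seeds are always retained even when the cut would drop them; a warning
    is emitted in that case.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    k = math.ceil(fraction * len(result.scores))
    ranked = sorted(result.scores, key=lambda p: (-result.scores[p], p))
    top = set(ranked[:k])
    dropped = result.seeds - top
    if dropped:
        warnings.warn(f"seeds below the cut retained anyway: {sorted(dropped)}", stacklevel=2)
    return top | set(result.seeds)


def overlap_report(
    biomarkers: set[str],
    top_sets: Sequence[set[str]],
    background: set[str],
) -> dict:
    """Overlap of a biomarker list with the union of top-proximity sets.

    Returns the union, the overlap, its size, and a hypergeometric
    enrichment p-value (drawing |biomarkers| from |background| with |union|
    marked successes).
    """
    union: set[str] = set().union(*top_sets) if top_sets else set()
    overlap = biomarkers & union
    N, K, n, k = len(background), len(union), len(biomarkers), len(overlap)
    p = float(stats.hypergeom.sf(k - 1, N, K, n)) if N else 1.0
    return {
        "union": union,
        "overlap": overlap,
        "count": k,
        "p_hypergeom": p,
    }
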