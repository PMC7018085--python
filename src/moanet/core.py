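"""Clamped-input tanh propagation and simulated-annealing weight fitting.

The model treats the signed protein network as a recurrent perceptron-like
system.  Drug-target (stimulus) nodes are clamped at +1/-1; every other node
computes

    x_i = tanh( sum_{edges l: j -> i} w_l * x_j )

and the system is iterated to a fixed point with damped synchronous updates
(``x <- (1 - d) * tanh(Wx) + d * x``).  On acyclic graphs this reduces to
layered feed-forward evaluation; on cyclic graphs the damping stabilises the
iteration.  Nodes unreachable from the stimulus keep signal 0 ("neutral").

A *mechanism of action* (MoA) is one fitted solution: a weight vector, the
propagated signal per protein, and the fraction of active/inactive node
restrictions the signals satisfy.  Weights are fitted by simulated annealing
and an ensemble of MoAs is obtained from independent seeded runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .netio import EffectorSet, RestrictionSet, SignedDirectedNetwork, Stimulus

__all__ = [
    "PropagationParams",
    "AnnealSchedule",
    "MoA",
    "MoAEnsemble",
    "propagate",
    "accuracy",
    "anneal",
    "sample_ensemble",
    "select_top",
    "DEFAULT_MIN_MAGNITUDE",
]

#: Minimum |signal| for a node to count as decidedly active/inactive.
DEFAULT_MIN_MAGNITUDE = 0.05


@dataclass(frozen=True)
class PropagationParams:
    max_iterations: int = 500
    convergence_tol: float = 1e-6
    damping: float = 0.5

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not self.convergence_tol > 0:
            raise ValueError("convergence_tol must be > 0")
        if not (0.0 <= self.damping < 1.0):
            raise ValueError("damping must be in [0, 1)")


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric cooling schedule for the Metropolis weight search.

    ``search_tol`` is the (looser) propagation tolerance used while
    exploring moves; the final reported MoA is always re-propagated at the
    full :class:`PropagationParams` tolerance from a cold start.
    """

    initial_temperature: float = 0.05
    cooling_factor: float = 0.9
    steps_per_temperature: int = 120
    n_temperatures: int = 60
    move_scale: float = 0.4
    search_tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.initial_temperature <= 0 or self.move_scale <= 0:
            raise ValueError("initial_temperature and move_scale must be positive")
        if not (0.0 < self.cooling_factor < 1.0):
            raise ValueError("cooling_factor must be in (0, 1)")
        if self.steps_per_temperature < 0 or self.n_temperatures < 1:
            raise ValueError("invalid step counts")
        if not self.search_tol > 0:
            raise ValueError("search_tol must be > 0")


@dataclass(frozen=True)
class MoA:
    """One sampled mechanism of action."""

    signals: Mapping[str, float]
    weights: Mapping[tuple[str, str], float]
    accuracy: float
    seed: int
    converged: bool = True


@dataclass(frozen=True)
class MoAEnsemble:
    """Selected MoA collection, sorted by accuracy desc (ties: seed asc)."""

    moas: tuple[MoA, ...]
    K: int
    min_accuracy: float
    total_sampled: int

    def __post_init__(self) -> None:
        moas = tuple(self.moas)
        object.__setattr__(self, "moas", moas)
        for m in moas:
            if m.accuracy < self.min_accuracy:
                raise ValueError("ensemble member below min_accuracy")
        keys = [(-m.accuracy, m.seed) for m in moas]
        if keys != sorted(keys):
            raise ValueError("ensemble must be sorted by accuracy desc, seed asc")
        if len({m.seed for m in moas}) != len(moas):
            raise ValueError("ensemble MoA seeds must be unique (they act as ids)")

    def __len__(self) -> int:
        return len(self.moas)

    def ids(self) -> tuple[int, ...]:
        return tuple(m.seed for m in self.moas)


class CompiledModel:
    """Network + stimulus compiled to index arrays for fast propagation.

    Node order is the sorted protein list; the sparse influence matrix has a
    fixed sparsity pattern so annealing only rewrites its data vector.
    """

    def __init__(
        self,
        network: SignedDirectedNetwork,
        stimulus: Stimulus,
        params: PropagationParams | None = None,
        sign_constrained: bool = True,
    ) -> None:
        missing = stimulus.proteins - network.nodes
        if missing:
            raise ValueError(f"stimulus proteins not in network: {sorted(missing)}")
        self.params = params or PropagationParams()
        self.nodes: list[str] = sorted(network.nodes)
        self.index: dict[str, int] = {n: i for i, n in enumerate(self.nodes)}
        n = len(self.nodes)
        edges = sorted(network.edges, key=lambda e: (e.source, e.target))
        self.edges = edges
        self.src = np.array([self.index[e.source] for e in edges], dtype=np.intp)
        self.dst = np.array([self.index[e.target] for e in edges], dtype=np.intp)
        self.signs = np.array([e.sign for e in edges], dtype=np.float64)
        self.init_weights = np.array([e.weight for e in edges], dtype=np.float64)
        if sign_constrained:
            self.lo = np.where(self.signs > 0, 0.0, -1.0)
            self.hi = np.where(self.signs > 0, 1.0, 0.0)
        else:
            self.lo = np.full(len(edges), -1.0)
            self.hi = np.full(len(edges), 1.0)
        # csr with data = edge index, so csr.data order maps back to edge order
        coo = sp.coo_matrix(
            (np.arange(len(edges), dtype=np.float64), (self.dst, self.src)), shape=(n, n)
        )
        csr = coo.tocsr()
        self._perm = csr.data.astype(np.intp).copy()
        self._mat = csr
        self.clamp_idx = np.array(sorted(self.index[p] for p in stimulus.proteins), dtype=np.intp)
        self.clamp_val = np.array(
            [stimulus.states[self.nodes[i]] for i in self.clamp_idx], dtype=np.float64
        )
        self.free_mask = np.ones(n, dtype=bool)
        self.free_mask[self.clamp_idx] = False

    def propagate_array(
        self, weights: np.ndarray, x0: np.ndarray | None = None, tol: float | None = None
    ) -> tuple[np.ndarray, bool, int]:
        """Damped fixed-point iteration; returns (signals, converged, n_iter).

        Convergence is declared on the undamped residual
        ``max_i |tanh((Wx)_i) - x_i| < tol`` over free nodes, so a converged
        state is a fixed point of the plain synchronous update at tolerance.
        """
        if not np.all(np.isfinite(weights)):
            raise ValueError("non-finite edge weight")
        p = self.params
        tol = p.convergence_tol if tol is None else tol
        self._mat.data = weights[self._perm]
        x = np.zeros(len(self.nodes)) if x0 is None else np.array(x0, dtype=np.float64)
        x[self.clamp_idx] = self.clamp_val
        d = p.damping
        converged = False
        it = 0
        for it in range(1, p.max_iterations + 1):
            target = np.tanh(self._mat @ x)
            target[self.clamp_idx] = self.clamp_val
            resid = np.max(np.abs(target - x)) if len(x) else 0.0
            if resid < tol:
                converged = True
                break
            x = (1.0 - d) * target + d * x
            x[self.clamp_idx] = self.clamp_val
        return x, converged, it

    def restriction_arrays(self, restrictions: RestrictionSet) -> tuple[np.ndarray, np.ndarray]:
        unknown = sorted(restrictions.proteins - set(self.index))
        if unknown:
            raise ValueError(f"restriction on unknown proteins: {unknown}")
        idx = np.array([self.index[p] for p in sorted(restrictions.node_states)], dtype=np.intp)
        states = np.array(
            [restrictions.node_states[p] for p in sorted(restrictions.node_states)],
            dtype=np.float64,
        )
        return idx, states

    def signals_dict(self, x: np.ndarray) -> dict[str, float]:
        return {n: float(x[i]) for n, i in self.index.items()}

    def weights_dict(self, w: np.ndarray) -> dict[tuple[str, str], float]:
        return {(e.source, e.target): float(w[k]) for k, e in enumerate(self.edges)}


def propagate(
    network: SignedDirectedNetwork,
    stimulus: Stimulus,
    params: PropagationParams | None = None,
    weights: Mapping[tuple[str, str], float] | None = None,
    return_info: bool = False,
):
    """Propagate the clamped stimulus through the weighted network.

    Returns the signal map protein -> value in [-1, 1]; with
    ``return_info=True`` returns ``(signals, converged, n_iterations)``.
    Weights default to those stored on the network's edges.
    """
    model = CompiledModel(network, stimulus, params)
    w = model.init_weights.copy()
    if weights is not None:
        for k, e in enumerate(model.edges):
            if (e.source, e.target) in weights:
                w[k] = float(weights[(e.source, e.target)])
    x, converged, it = model.propagate_array(w)
    signals = model.signals_dict(x)
    if return_info:
        return signals, converged, it
    return signals


def _satisfied(x_at: np.ndarray, states: np.ndarray, min_magnitude: float) -> np.ndarray:
    return (np.sign(x_at) == states) & (np.abs(x_at) >= min_magnitude)


def accuracy(
    signals: Mapping[str, float],
    restrictions: RestrictionSet,
    min_magnitude: float = DEFAULT_MIN_MAGNITUDE,
) -> float:
    """Fraction of restrictions satisfied by a signal map.

    A restriction (p, s) is satisfied iff sign(signals[p]) == s and
    |signals[p]| >= min_magnitude.
    """
    if len(restrictions) == 0:
        raise ValueError("restrictions must be non-empty")
    missing = sorted(p for p in restrictions.proteins if p not in signals)
    if missing:
        raise ValueError(f"restriction on unknown proteins: {missing}")
    proteins = sorted(restrictions.node_states)
    x = np.array([signals[p] for p in proteins], dtype=np.float64)
    s = np.array([restrictions.node_states[p] for p in proteins], dtype=np.float64)
    return float(np.mean(_satisfied(x, s, min_magnitude)))


#: Weight of the mean restriction-aligned magnitude in the annealing score.
#: Kept below one restriction step (1/n_restrictions for n < 100) so it acts
#: purely as a tie-break / plateau-escape term.
_ALIGN_WEIGHT = 0.01


def anneal(
    network: SignedDirectedNetwork,
    stimulus: Stimulus,
    restrictions: RestrictionSet,
    schedule: AnnealSchedule | None = None,
    params: PropagationParams | None = None,
    seed: int = 0,
    min_magnitude: float = DEFAULT_MIN_MAGNITUDE,
    sign_constrained: bool = True,
    return_trace: bool = False,
    _model: CompiledModel | None = None,
):
    """Fit edge weights by simulated annealing against node restrictions.

    Maximises restriction accuracy with a secondary continuous tie-break (the
    mean restriction-aligned signal magnitude).  Moves perturb one uniformly
    chosen edge weight by a Gaussian step (sd = ``move_scale``), clipped to
    the sign-respecting interval; acceptance follows the Metropolis rule.
    Deterministic given ``seed``.

    Returns the best-so-far :class:`MoA`; with ``return_trace=True`` also the
    per-step best accuracy trace (non-decreasing by construction).
    """
    schedule = schedule or AnnealSchedule()
    model = _model or CompiledModel(network, stimulus, params, sign_constrained=sign_constrained)
    r_idx, r_states = model.restriction_arrays(restrictions)
    if len(r_idx) == 0:
        raise ValueError("restrictions must be non-empty")
    rng = np.random.default_rng(seed)
    n_edges = len(model.edges)

    def objective(x: np.ndarray) -> tuple[float, float]:
        xa = x[r_idx]
        acc = float(np.mean(_satisfied(xa, r_states, min_magnitude)))
        aligned = float(np.mean(r_states * xa))
        return acc, aligned

    w = rng.uniform(model.lo, model.hi)
    x, _, _ = model.propagate_array(w, tol=schedule.search_tol)
    acc, aligned = objective(x)
    score = acc + _ALIGN_WEIGHT * aligned
    best_w, best_key = w.copy(), (acc, aligned)
    trace: list[float] = []
    T = schedule.initial_temperature
    for _ in range(schedule.n_temperatures):
        for _ in range(schedule.steps_per_temperature):
            k = int(rng.integers(n_edges))
            old = w[k]
            w[k] = float(np.clip(old + rng.normal(0.0, schedule.move_scale), model.lo[k], model.hi[k]))
            # warm start: a single-edge move barely shifts the fixed point
            x_new, _, _ = model.propagate_array(w, x0=x, tol=schedule.search_tol)
            acc_new, aligned_new = objective(x_new)
            score_new = acc_new + _ALIGN_WEIGHT * aligned_new
            if score_new >= score or rng.random() < np.exp((score_new - score) / T):
                x, score = x_new, score_new
                if (acc_new, aligned_new) > best_key:
                    best_key = (acc_new, aligned_new)
                    best_w = w.copy()
            else:
                w[k] = old
            trace.append(best_key[0])
        T *= schedule.cooling_factor
    # final signals from a cold start so the reported MoA does not depend on
    # the warm-start trajectory
    x_best, converged, _ = model.propagate_array(best_w)
    acc_best, _ = objective(x_best)
    moa = MoA(
        signals=model.signals_dict(x_best),
        weights=model.weights_dict(best_w),
        accuracy=acc_best,
        seed=seed,
        converged=converged,
    )
    if return_trace:
        return moa, trace
    return moa


def sample_ensemble(
    network: SignedDirectedNetwork,
    stimulus: Stimulus,
    restrictions: RestrictionSet,
    n_runs: int,
    schedule: AnnealSchedule | None = None,
    params: PropagationParams | None = None,
    base_seed: int = 0,
    min_magnitude: float = DEFAULT_MIN_MAGNITUDE,
    sign_constrained: bool = True,
) -> list[MoA]:
    """Run ``n_runs`` independent annealings with seeds base_seed..base_seed+n-1.

    Runs are independent given their seeds, so results do not depend on
    execution order.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    model = CompiledModel(network, stimulus, params, sign_constrained=sign_constrained)
    return [
        anneal(
            network, stimulus, restrictions,
            schedule=schedule, params=params, seed=base_seed + i,
            min_magnitude=min_magnitude, sign_constrained=sign_constrained,
            _model=model,
        )
        for i in range(n_runs)
    ]


def select_top(
    moas: Sequence[MoA],
    K: int = 200,
    min_accuracy: float = 0.8,
    allow_fewer: bool = False,
) -> MoAEnsemble:
    """Keep the K most accurate MoAs with accuracy >= min_accuracy.

    Sorting is by accuracy descending with ties broken by seed ascending.
    Unless ``allow_fewer`` is set, fewer than K survivors is an error.
    """
    if K < 4:
        raise ValueError("K must be >= 4 (quartile groups must be non-empty)")
    survivors = sorted(
        (m for m in moas if m.accuracy >= min_accuracy), key=lambda m: (-m.accuracy, m.seed)
    )
    if not survivors:
        raise ValueError(
            "no MoA reached min_accuracy; lengthen the annealing schedule or "
            "relax the instance"
        )
    if len(survivors) < K and not allow_fewer:
        raise ValueError(
            f"only {len(survivors)} MoAs reached min_accuracy={min_accuracy} "
            f"(K={K}); increase n_runs or pass allow_fewer=True"
        )
    kept = tuple(survivors[:K])
    return MoAEnsemble(
        moas=kept, K=K, min_accuracy=min_accuracy, total_sampled=len(moas)
    )
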