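"""Solvable synthetic instances with planted ground truth.

The real inputs of this kind of study — a curated human protein network, a
proprietary catalogue of phenotype effector states, expression-derived node
restrictions — are not redistributable.  This module emulates all of them:

* a scale-free-ish signed directed network (preferential attachment with
  random edge orientation and Bernoulli inhibition signs),
* a small drug stimulus (clamped +/-1 targets),
* two signed effector sets (indication and adverse event) holding the
  *disease* states, i.e. the negated sign of a *planted* drug-response
  signal obtained by propagating the stimulus through known sign-respecting
  weights (a drug is expected to revert its indication's effector states),
* a restriction set — the drug-response targets (sign of the planted signal
  at the indication effectors, the reversion of their disease states) plus
  extra "expression-like" node states — with optional label-flip noise.

Because the restriction states are read off a real propagation fixed point,
a solver handed the true weights satisfies every noise-free restriction —
every downstream stage is testable against known ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np

from .core import CompiledModel, PropagationParams, accuracy, DEFAULT_MIN_MAGNITUDE
from .netio import (
    Edge,
    EffectorSet,
    RestrictionSet,
    SignedDirectedNetwork,
    Stimulus,
    write_network,
    write_states,
)

__all__ = [
    "PlantedInstance",
    "generate_network",
    "plant_instance",
    "true_accuracy",
    "write_instance",
]

#: Minimum |planted signal| required of an effector candidate, so planted
#: states are not artifacts of numerical noise.
SIGNAL_FLOOR = 0.05


@dataclass(frozen=True)
class PlantedInstance:
    """A complete toy study with known ground truth."""

    network: SignedDirectedNetwork
    stimulus: Stimulus
    indication: EffectorSet
    adverse_event: EffectorSet
    restrictions: RestrictionSet
    true_weights: Mapping[tuple[str, str], float]
    true_signals: Mapping[str, float]
    seed: int


def generate_network(
    n_nodes: int = 300,
    attach_m: int = 2,
    p_inhibition: float = 0.3,
    seed: int = 0,
) -> SignedDirectedNetwork:
    """Scale-free-ish signed directed network.

    Barabási–Albert preferential attachment gives a right-skewed degree
    distribution; each undirected edge is then oriented uniformly at random
    and marked inhibiting with probability ``p_inhibition``.  Deterministic
    given ``seed``.
    """
    if n_nodes < 5:
        raise ValueError("n_nodes must be >= 5")
    if not (0.0 <= p_inhibition <= 1.0):
        raise ValueError("p_inhibition must be in [0, 1]")
    if attach_m < 1 or attach_m >= n_nodes:
        raise ValueError(f"attach_m={attach_m} must satisfy 1 <= m < n_nodes={n_nodes}")
    g = nx.barabasi_albert_graph(n_nodes, attach_m, seed=seed)
    rng = np.random.default_rng(seed)
    width = len(str(n_nodes - 1))
    label = {i: f"P{i:0{width}d}" for i in g.nodes}
    edges = []
    for u, v in sorted(g.edges):
        if rng.random() < 0.5:
            u, v = v, u
        sign = -1 if rng.random() < p_inhibition else 1
        edges.append(Edge(label[u], label[v], sign))
    return SignedDirectedNetwork(edges, extra_nodes=label.values())


def _reachable_from(network: SignedDirectedNetwork, sources: set[str]) -> set[str]:
    g = nx.DiGraph()
    g.add_nodes_from(network.nodes)
    g.add_edges_from((e.source, e.target) for e in network.edges)
    out: set[str] = set()
    for s in sources:
        out |= nx.descendants(g, s)
    return out - sources


def plant_instance(
    network: SignedDirectedNetwork,
    n_targets: int = 2,
    n_eff_ind: int = 15,
    n_eff_adv: int = 15,
    restriction_noise: float = 0.0,
    n_extra_restrictions: int = 20,
    seed: int = 0,
    signal_floor: float = SIGNAL_FLOOR,
    params: PropagationParams | None = None,
) -> PlantedInstance:
    """Plant a satisfiable weight assignment and derive all study inputs.

    True weights are drawn with magnitude U(0.3, 1) on the edge sign's
    half-interval; true signals are the propagation fixed point.  Effectors
    are drawn from nodes reachable from the stimulus with |signal| >=
    ``signal_floor``; their *disease* states are the negated sign of the
    planted signal, so the planted drug response reverts every effector.
    Restrictions are the drug-response targets at the indication effectors
    (sign of the true signal) plus ``n_extra_restrictions`` extra node
    states; every restriction is independently flipped with probability
    ``restriction_noise``.
    """
    if not (0.0 <= restriction_noise <= 1.0):
        raise ValueError("restriction_noise must be in [0, 1]")
    rng = np.random.default_rng(seed)
    nodes = sorted(network.nodes)
    # stimulus: sample hubs (top decile by out-degree) so a useful fraction of
    # the network is downstream of the drug targets
    out_deg: dict[str, int] = {n: 0 for n in nodes}
    for e in network.edges:
        out_deg[e.source] += 1
    ranked = sorted(nodes, key=lambda n: (-out_deg[n], n))
    pool = ranked[: max(n_targets, len(nodes) // 10)]
    targets = sorted(rng.choice(pool, size=n_targets, replace=False))
    stimulus = Stimulus({t: int(rng.choice([-1, 1])) for t in targets})

    model = CompiledModel(network, stimulus, params)
    # rejection-sample the planted truth: some weight draws put the damped
    # dynamics on a slow oscillatory attractor instead of a fixed point;
    # redraw (deterministically from the same stream) until it converges
    for _attempt in range(50):
        w = rng.uniform(0.3, 1.0, size=len(model.edges)) * model.signs
        x, converged, _ = model.propagate_array(w)
        if converged:
            break
    else:
        raise RuntimeError("no convergent planted weight draw found; adjust params")
    true_signals = model.signals_dict(x)
    true_weights = model.weights_dict(w)

    reachable = _reachable_from(network, set(targets))
    candidates = sorted(
        p for p in reachable if abs(true_signals[p]) >= signal_floor
    )
    needed = max(n_eff_ind, n_eff_adv)
    if len(candidates) < needed + n_extra_restrictions:
        raise ValueError(
            f"only {len(candidates)} reachable nodes carry |signal| >= "
            f"{signal_floor} (reachable: {len(reachable)}); requested "
            f"{needed} effectors + {n_extra_restrictions} extra restrictions"
        )
    eff_ind = sorted(rng.choice(candidates, size=n_eff_ind, replace=False))
    eff_adv = sorted(rng.choice(candidates, size=n_eff_adv, replace=False))
    ind = EffectorSet(
        "indication", "indication",
        {p: -int(np.sign(true_signals[p])) for p in eff_ind},
    )
    adv = EffectorSet(
        "adverse_event", "adverse_event",
        {p: -int(np.sign(true_signals[p])) for p in eff_adv},
    )
    remaining = [p for p in candidates if p not in set(eff_ind)]
    extra = sorted(rng.choice(remaining, size=n_extra_restrictions, replace=False))
    node_states: dict[str, int] = {}
    sources: dict[str, str] = {}
    for p in eff_ind:
        # the drug-response target: revert the effector's disease state
        node_states[p] = int(np.sign(true_signals[p]))
        sources[p] = "effector"
    for p in extra:
        node_states[p] = int(np.sign(true_signals[p]))
        sources[p] = "expression"
    for p in sorted(node_states):
        if rng.random() < restriction_noise:
            node_states[p] = -node_states[p]
    restrictions = RestrictionSet(node_states, sources)
    return PlantedInstance(
        network=network.with_weights(true_weights),
        stimulus=stimulus,
        indication=ind,
        adverse_event=adv,
        restrictions=restrictions,
        true_weights=true_weights,
        true_signals=true_signals,
        seed=seed,
    )


def true_accuracy(instance: PlantedInstance, min_magnitude: float = DEFAULT_MIN_MAGNITUDE) -> float:
    """Accuracy of the planted ground-truth signals against the (possibly
    noisy) restriction set; 1.0 whenever ``restriction_noise`` was 0."""
    return accuracy(instance.true_signals, instance.restrictions, min_magnitude)


def write_instance(instance: PlantedInstance, out_dir: str | Path) -> dict[str, Path]:
    """Persist an instance as the standard file formats plus ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": out / "network.tsv",
        "stimulus": out / "stimulus.tsv",
        "indication": out / "effectors_indication.tsv",
        "adverse_event": out / "effectors_adverse_event.tsv",
        "restrictions": out / "restrictions.tsv",
        "truth": out / "ground_truth.json",
    }
    write_network(instance.network, paths["network"])
    write_states(instance.stimulus.states, paths["stimulus"])
    write_states(instance.indication.states, paths["indication"])
    write_states(instance.adverse_event.states, paths["adverse_event"])
    write_states(instance.restrictions.node_states, paths["restrictions"])
    truth = {
        "seed": instance.seed,
        "true_weights": {f"{s}->{t}": w for (s, t), w in sorted(instance.true_weights.items())},
        "true_signals": dict(sorted(instance.true_signals.items())),
        "restriction_sources": dict(sorted(instance.restrictions.sources.items())),
    }
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths
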