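"""Domain types and file I/O for signed protein networks and signed node states.

The central object is a directed, signed protein-interaction network whose
edges carry a tunable weight ``w`` in [-1, +1].  Edge *sign* is fixed biology
(activation / inhibition); the *weight* magnitude is fitted downstream.  By
default a fitted weight is constrained to the half-interval matching the edge
sign ([0, 1] for activating edges, [-1, 0] for inhibiting ones); pass
``sign_constrained=False`` to the fitting routines to free it.

Protein identifiers are opaque strings; no identifier mapping is attempted.
Signal flows source -> target only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Edge",
    "SignedDirectedNetwork",
    "Stimulus",
    "EffectorSet",
    "RestrictionSet",
    "read_network",
    "write_network",
    "read_states",
    "write_states",
]

_SIGN_TOKENS = {
    "+1": 1, "1": 1, "+1.0": 1, "activation": 1, "activates": 1, "active": 1,
    "-1": -1, "-1.0": -1, "inhibition": -1, "inhibits": -1, "inactive": -1,
}


def _parse_sign(token: str, row: int) -> int:
    try:
        return _SIGN_TOKENS[token.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown sign token {token!r} on row {row}") from None


@dataclass(frozen=True)
class Edge:
    """One directed signed interaction with a fitted weight."""

    source: str
    target: str
    sign: int
    weight: float = 0.0

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValueError(f"edge sign must be +/-1, got {self.sign!r}")
        if not (-1.0 <= self.weight <= 1.0):
            raise ValueError(
                f"edge weight must be finite in [-1, 1], got {self.weight!r} "
                f"({self.source}->{self.target})"
            )


class SignedDirectedNetwork:
    """Directed signed network over opaque protein identifiers.

    Parameters
    ----------
    edges
        Iterable of :class:`Edge`.  (source, target) pairs must be unique and
        self-loops are rejected.
    extra_nodes
        Optional isolated nodes to include beyond the edge endpoints.
    """

    def __init__(self, edges: Iterable[Edge], extra_nodes: Iterable[str] = ()) -> None:
        self.edges: list[Edge] = list(edges)
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            if e.source == e.target:
                raise ValueError(f"self-loop on {e.source!r} is not allowed")
            pair = (e.source, e.target)
            if pair in seen:
                raise ValueError(f"duplicate edge {e.source}->{e.target}")
            seen.add(pair)
        self.nodes: set[str] = {n for e in self.edges for n in (e.source, e.target)}
        self.nodes.update(extra_nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(e.source, e.target) for e in self.edges}

    def with_weights(self, weights: Mapping[tuple[str, str], float]) -> "SignedDirectedNetwork":
        """Return a copy whose edge weights are replaced from ``weights``."""
        new = [
            Edge(e.source, e.target, e.sign, float(weights.get((e.source, e.target), e.weight)))
            for e in self.edges
        ]
        return SignedDirectedNetwork(new, extra_nodes=self.nodes)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SignedDirectedNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


def _check_states(states: Mapping[str, int], what: str) -> dict[str, int]:
    if not states:
        raise ValueError(f"{what} must be non-empty")
    out: dict[str, int] = {}
    for protein, s in states.items():
        if s not in (-1, 1):
            raise ValueError(f"{what}: state for {protein!r} must be +/-1, got {s!r}")
        out[str(protein)] = int(s)
    return out


@dataclass(frozen=True)
class Stimulus:
    """Drug input: target proteins clamped at +1 (activated) or -1 (inhibited)."""

    states: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", _check_states(self.states, "Stimulus"))

    @property
    def proteins(self) -> set[str]:
        return set(self.states)


@dataclass(frozen=True)
class EffectorSet:
    """Signed effector states molecularly defining one phenotype.

    ``role`` distinguishes the drug's indication (whose effectors the drug is
    expected to revert) from an adverse-event phenotype (whose effectors the
    drug may induce).  Proteins absent from the set are neutral.
    """

    name: str
    role: str
    states: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.role not in ("indication", "adverse_event"):
            raise ValueError(f"role must be 'indication' or 'adverse_event', got {self.role!r}")
        object.__setattr__(self, "states", _check_states(self.states, f"EffectorSet {self.name!r}"))

    @property
    def proteins(self) -> set[str]:
        return set(self.states)


@dataclass(frozen=True)
class RestrictionSet:
    """Active/inactive node constraints a fitted model should satisfy.

    Each entry carries a provenance tag in {'effector', 'expression',
    'literature'}; a protein cannot be constrained to both +1 and -1.
    """

    node_states: Mapping[str, int]
    sources: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "node_states", _check_states(self.node_states, "RestrictionSet"))
        src = {p: self.sources.get(p, "effector") for p in self.node_states}
        bad = {t for t in src.values() if t not in ("effector", "expression", "literature")}
        if bad:
            raise ValueError(f"unknown restriction source tags: {sorted(bad)}")
        object.__setattr__(self, "sources", src)

    def __len__(self) -> int:
        return len(self.node_states)

    @property
    def proteins(self) -> set[str]:
        return set(self.node_states)


# ---------------------------------------------------------------------------
# File I/O.  Networks: TSV edge list (source, target, sign, [weight]) with a
# header line, or SIF dialect "source<TAB>rel<TAB>target" with rel in
# {activates, inhibits}.  States: two-column TSV with a header line.
# ---------------------------------------------------------------------------


def read_network(path: str | Path, undirected: bool = False) -> SignedDirectedNetwork:
    """Read a signed edge list (TSV with header, or SIF dialect).

    With ``undirected=True`` every input row is expanded to the two directed
    edges, carrying the same sign and weight.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[tuple[str, str, int, float]] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        lines = [r for r in reader if r and not r[0].startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty network file")
    is_sif = path.suffix.lower() == ".sif" or (
        len(lines[0]) == 3 and lines[0][1].strip().lower() in ("activates", "inhibits")
    )
    if is_sif:
        for i, r in enumerate(lines, start=1):
            if len(r) != 3:
                raise ValueError(f"{path}: SIF row {i} needs 3 columns, got {len(r)}")
            rows.append((r[0].strip(), r[2].strip(), _parse_sign(r[1], i), 0.0))
    else:
        header = [c.strip().lower() for c in lines[0]]
        if header[:3] != ["source", "target", "sign"]:
            raise ValueError(
                f"{path}: expected header 'source<TAB>target<TAB>sign[<TAB>weight]', got {header}"
            )
        has_weight = len(header) > 3 and header[3] == "weight"
        for i, r in enumerate(lines[1:], start=2):
            if len(r) < 3:
                raise ValueError(f"{path}: row {i} needs at least 3 columns")
            w = float(r[3]) if has_weight and len(r) > 3 and r[3].strip() else 0.0
            rows.append((r[0].strip(), r[1].strip(), _parse_sign(r[2], i), w))
    edges = []
    for s, t, sign, w in rows:
        edges.append(Edge(s, t, sign, w))
        if undirected:
            edges.append(Edge(t, s, sign, w))
    return SignedDirectedNetwork(edges)


def write_network(network: SignedDirectedNetwork, path: str | Path) -> None:
    """Write a network as a TSV edge list; isolated nodes are not representable."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write("source\ttarget\tsign\tweight\n")
        for e in sorted(network.edges, key=lambda e: (e.source, e.target)):
            fh.write(f"{e.source}\t{e.target}\t{e.sign:+d}\t{e.weight!r}\n")


def _read_state_rows(path: str | Path) -> dict[str, int]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        lines = [r for r in reader if r and not r[0].startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty state file")
    if lines[0][0].strip().lower() in ("protein", "node", "id"):
        lines = lines[1:]
    states: dict[str, int] = {}
    for i, r in enumerate(lines, start=1):
        if len(r) < 2:
            raise ValueError(f"{path}: row {i} needs 2 columns (protein, state)")
        protein = r[0].strip()
        s = _parse_sign(r[1], i)
        if protein in states and states[protein] != s:
            raise ValueError(f"{path}: contradictory states for {protein!r}")
        states[protein] = s
    if not states:
        raise ValueError(f"{path}: no state rows")
    return states


def read_states(
    path: str | Path,
    kind: str = "restrictions",
    network: SignedDirectedNetwork | None = None,
    name: str = "",
    role: str = "indication",
    missing: str = "drop",
) -> tuple[Stimulus | EffectorSet | RestrictionSet, list[str]]:
    """Read a two-column (protein, state) TSV into a typed state container.

    ``kind`` selects the container ('stimulus', 'effectors', 'restrictions');
    name/role come from configuration, never from the file.  If ``network`` is
    given, proteins absent from it are collected into the returned warning
    list and either dropped (``missing='drop'``) or rejected
    (``missing='fail'``).
    """
    if missing not in ("drop", "fail"):
        raise ValueError("missing policy must be 'drop' or 'fail'")
    states = _read_state_rows(path)
    unknown: list[str] = []
    if network is not None:
        unknown = sorted(p for p in states if p not in network.nodes)
        if unknown and missing == "fail":
            raise ValueError(f"{path}: proteins absent from network: {unknown}")
        for p in unknown:
            del states[p]
        if not states:
            raise ValueError(f"{path}: no proteins left after dropping unknowns {unknown}")
    if kind == "stimulus":
        return Stimulus(states), unknown
    if kind == "effectors":
        return EffectorSet(name=name or Path(path).stem, role=role, states=states), unknown
    if kind == "restrictions":
        return RestrictionSet(states), unknown
    raise ValueError(f"unknown state kind {kind!r}")


def write_states(states: Mapping[str, int], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write("protein\tstate\n")
        for p in sorted(states):
            fh.write(f"{p}\t{states[p]:+d}\n")
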