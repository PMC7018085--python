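"""Response-intensity stratification of a MoA ensemble.

TSignal quantifies how strongly one mechanism of action responds at a
phenotype's effectors.  We use the signed projection

    P = (1/|E|) * sum_e state_e * signal_e      in [-1, +1]

so P = +1 means the model reproduces every effector state exactly and
P = -1 means it reverts all of them.  Response *intensity* is role-dependent:
a drug is expected to revert its indication's effectors (intensity = -P,
"reversion strength") and may induce an adverse event's (intensity = +P,
"induction strength").  Ranking by intensity and cutting the top/bottom
quartiles yields the High/Low groups: for the indication the top quartile is
the Low-disease group (strongest reversion), for the adverse event it is the
High-adverseEvent group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import floor
from typing import Mapping

from .core import MoA, MoAEnsemble
from .netio import EffectorSet

__all__ = ["StratifiedGroups", "tsignal", "stratify", "intersect"]

LOW, MID, HIGH = "Low", "Mid", "High"


@dataclass(frozen=True)
class StratifiedGroups:
    """Quartile labels and intensities for one phenotype over one ensemble."""

    phenotype: str
    role: str
    labels: Mapping[int, str]          # MoA id (seed) -> Low/Mid/High
    intensity: Mapping[int, float]     # MoA id -> role-oriented intensity
    projection: Mapping[int, float]    # MoA id -> raw signed projection P
    ensemble_ids: frozenset[int]

    def group(self, label: str) -> set[int]:
        return {i for i, l in self.labels.items() if l == label}


def tsignal(moa: MoA, effectors: EffectorSet) -> float:
    """Signed projection of a MoA's signals onto an effector state vector."""
    if not effectors.states:
        raise ValueError("effector set is empty")
    missing = sorted(p for p in effectors.states if p not in moa.signals)
    if missing:
        raise ValueError(f"effector proteins missing from signal map: {missing}")
    return sum(s * moa.signals[p] for p, s in effectors.states.items()) / len(effectors.states)


def stratify(
    ensemble: MoAEnsemble,
    effectors: EffectorSet,
    role: str | None = None,
    quartile: float = 0.25,
) -> StratifiedGroups:
    """Split an ensemble into High/Mid/Low groups by response intensity.

    The top ``floor(K * quartile)`` MoAs by intensity get the role's extreme
    label (indication -> Low, i.e. low residual disease; adverse_event ->
    High), the bottom block the opposite label, the rest Mid.  Ties are
    broken by MoA seed ascending so the ranking is total.
    """
    role = role or effectors.role
    if role not in ("indication", "adverse_event"):
        raise ValueError(f"invalid role {role!r}")
    K = len(ensemble)
    if K < 4:
        raise ValueError("ensemble must have >= 4 MoAs")
    if not (0.0 < quartile <= 0.5):
        raise ValueError("quartile fraction must be in (0, 0.5]")
    sign = -1.0 if role == "indication" else 1.0
    projection = {m.seed: tsignal(m, effectors) for m in ensemble.moas}
    intensity = {i: sign * p for i, p in projection.items()}
    order = sorted(intensity, key=lambda i: (-intensity[i], i))
    g = floor(K * quartile)
    if len(set(intensity.values())) == 1:
        warnings.warn(
            "all intensities equal; quartile groups filled by seed order",
            stacklevel=2,
        )
    top_label = LOW if role == "indication" else HIGH
    bottom_label = HIGH if role == "indication" else LOW
    labels = {i: MID for i in order}
    for i in order[:g]:
        labels[i] = top_label
    for i in order[K - g:]:
        labels[i] = bottom_label
    return StratifiedGroups(
        phenotype=effectors.name,
        role=role,
        labels=labels,
        intensity=intensity,
        projection=projection,
        ensemble_ids=frozenset(ensemble.ids()),
    )


def intersect(
    groups_a: StratifiedGroups,
    groups_b: StratifiedGroups,
    label_a: str,
    label_b: str,
) -> set[int]:
    """MoA ids carrying ``label_a`` in one stratification and ``label_b`` in
    the other; both stratifications must come from the same ensemble."""
    if groups_a.ensemble_ids != groups_b.ensemble_ids:
        raise ValueError("stratifications come from different ensembles")
    return groups_a.group(label_a) & groups_b.group(label_b)
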