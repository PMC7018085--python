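"""Differential biomarker extraction between two MoA groups.

Pipeline: (1) rank proteins (or protein pairs) by how well a simple
threshold rule separates the two groups of models — the *best-classifier
proteins* (BCPs); (2) compare the groups' per-protein signal distributions
with the Mann–Whitney U test; (3) adjust for multiplicity; (4) keep proteins
that are significant AND whose group-mean signals have opposite signs —
the *differential best-classifier proteins* (active in one group, inactive
in the other).  A generic Fisher-exact over-representation utility on
user-supplied gene sets is included for downstream functional reading.

A reference table of 30 published differential biomarkers (group means,
adjusted p-values and BCP membership) is shipped as package data; its
printed strength column is kept verbatim as read-only reference because the
formula behind it is not recoverable (it is not the product of the printed
means), while the package's own reports use |mean_A * mean_B|.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .compare import MoAPointCloud

__all__ = [
    "ClassifierCandidate",
    "BiomarkerRecord",
    "best_classifiers",
    "mann_whitney",
    "adjust_pvalues",
    "differential_filter",
    "filter_records",
    "biomarker_report",
    "load_reference_biomarkers",
    "reference_records",
    "overrepresentation",
    "read_gmt",
]


@dataclass(frozen=True)
class ClassifierCandidate:
    """A protein (or pair) with its threshold rule and LOO accuracy."""

    proteins: tuple[str, ...]
    classification_accuracy: float
    rule: str

    def __post_init__(self) -> None:
        if not (0.5 - 1e-12 <= self.classification_accuracy <= 1.0 + 1e-12):
            raise ValueError("oriented accuracy must lie in [0.5, 1]")


@dataclass(frozen=True)
class BiomarkerRecord:
    """One differential-biomarker row (Table-style report)."""

    protein: str
    mean_a: float
    mean_b: float
    strength: float
    p_raw: float
    p_adjusted: float
    bcp_membership: frozenset[str] = frozenset()

    @property
    def partition(self) -> str:
        """'A-active/B-inactive' or 'A-inactive/B-active' by the sign of mean_a."""
        return "A-active/B-inactive" if self.mean_a > 0 else "A-inactive/B-active"


# ---------------------------------------------------------------------------
# Best-classifier search (optimal threshold stumps, leave-one-out accuracy)
# ---------------------------------------------------------------------------


def _stump_candidates(x: np.ndarray) -> np.ndarray:
    """Thresholds: midpoints between consecutive distinct values + extremes."""
    u = np.unique(x)
    if len(u) == 1:
        return np.array([u[0] - 1.0])
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate(([u[0] - 1.0], mids, [u[-1] + 1.0]))


def _best_stump(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Best single-threshold rule on (x, labels y in {0,1}).

    Returns (threshold, orientation, training accuracy) where orientation +1
    means 'predict class 1 if x > threshold'.  Ties prefer the smallest
    threshold and +1 orientation.
    """
    n = len(x)
    thr = _stump_candidates(x)
    # above[i, j] = x[j] > thr[i]
    above = x[None, :] > thr[:, None]
    acc_pos = (above == (y[None, :] == 1)).mean(axis=1)
    acc_neg = 1.0 - acc_pos
    best_pos = int(np.argmax(acc_pos))
    best_neg = int(np.argmax(acc_neg))
    if acc_pos[best_pos] >= acc_neg[best_neg]:
        return float(thr[best_pos]), 1, float(acc_pos[best_pos])
    return float(thr[best_neg]), -1, float(acc_neg[best_neg])


def _loo_accuracy(x: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out accuracy of the optimal threshold stump."""
    n = len(x)
    mask = np.ones(n, dtype=bool)
    correct = 0
    for i in range(n):
        mask[i] = False
        thr, orient, _ = _best_stump(x[mask], y[mask])
        pred = 1 if orient * (x[i] - thr) > 0 else 0
        correct += int(pred == y[i])
        mask[i] = True
    return correct / n


def _pair_loo_accuracy(x1: np.ndarray, x2: np.ndarray, y: np.ndarray) -> float:
    """LOO accuracy of the best axis-aligned two-threshold conjunction."""
    n = len(y)
    mask = np.ones(n, dtype=bool)
    correct = 0
    for i in range(n):
        mask[i] = False
        rule = _best_pair_rule(x1[mask], x2[mask], y[mask])
        t1, o1, t2, o2, flip = rule[:5]
        inside = (o1 * (x1[i] - t1) > 0) and (o2 * (x2[i] - t2) > 0)
        pred = (1 if inside else 0) ^ flip
        correct += int(pred == y[i])
        mask[i] = True
    return correct / n


def _best_pair_rule(
    x1: np.ndarray, x2: np.ndarray, y: np.ndarray
) -> tuple[float, int, float, int, int, float]:
    """Exhaustive search of axis-aligned conjunction rules (quadratic cost)."""
    best = None
    t1s, t2s = _stump_candidates(x1), _stump_candidates(x2)
    for o1 in (1, -1):
        s1 = o1 * x1[None, :] > o1 * t1s[:, None]
        for o2 in (1, -1):
            s2 = o2 * x2[None, :] > o2 * t2s[:, None]
            inside = s1[:, None, :] & s2[None, :, :]
            acc = (inside == (y[None, None, :] == 1)).mean(axis=2)
            for flip, a in ((0, acc), (1, 1.0 - acc)):
                k = np.unravel_index(np.argmax(a), a.shape)
                cand = (float(a[k]), float(t1s[k[0]]), o1, float(t2s[k[1]]), o2, flip)
                if best is None or cand[0] > best[0]:
                    best = cand
    acc, t1, o1, t2, o2, flip = best
    return t1, o1, t2, o2, flip, acc


def best_classifiers(
    group_a: MoAPointCloud,
    group_b: MoAPointCloud,
    top_n: int = 200,
    include_pairs: bool = False,
) -> list[ClassifierCandidate]:
    """Rank proteins (and optionally pairs) by threshold-rule LOO accuracy.

    Per protein, the optimal single-threshold stump is refit on each
    leave-one-out fold and scored on the held-out MoA.  A protein constant
    across both groups scores 0.5 by convention.  Candidates are ranked by
    accuracy descending with ties broken by protein id, then truncated to
    ``top_n``.
    """
    if group_a.protein_order != group_b.protein_order:
        raise ValueError("groups span different protein orders")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 MoAs")
    proteins = group_a.protein_order
    y = np.concatenate([np.ones(len(group_a), dtype=int), np.zeros(len(group_b), dtype=int)])
    X = np.vstack([group_a.matrix, group_b.matrix])
    out: list[ClassifierCandidate] = []
    for j, p in enumerate(proteins):
        x = X[:, j]
        if np.ptp(x) == 0.0:
            out.append(ClassifierCandidate((p,), 0.5, "constant signal; accuracy 0.5 by convention"))
            continue
        acc = _loo_accuracy(x, y)
        thr, orient, _ = _best_stump(x, y)
        flipped = acc < 0.5
        if flipped:
            acc, orient = 1.0 - acc, -orient
        cmp = ">" if orient == 1 else "<"
        rule = f"group A if signal {cmp} {thr:.4g}" + (" (orientation flipped)" if flipped else "")
        out.append(ClassifierCandidate((p,), acc, rule))
    if include_pairs:
        for (j1, p1), (j2, p2) in combinations(enumerate(proteins), 2):
            x1, x2 = X[:, j1], X[:, j2]
            if np.ptp(x1) == 0.0 and np.ptp(x2) == 0.0:
                continue
            acc = _pair_loo_accuracy(x1, x2, y)
            if acc < 0.5:
                acc = 1.0 - acc
            out.append(
                ClassifierCandidate(
                    (p1, p2), acc, "axis-aligned two-threshold conjunction"
                )
            )
    out.sort(key=lambda c: (-c.classification_accuracy, c.proteins))
    return out[:top_n]


# ---------------------------------------------------------------------------
# Differential testing
# ---------------------------------------------------------------------------


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Uses the exact null distribution when both samples have n <= 8 and no
    ties, the tie-corrected normal approximation (no continuity correction)
    otherwise.  Returns (U statistic for the first sample, p-value).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=False)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def adjust_pvalues(ps: Sequence[float], method: str = "bh") -> list[float]:
    """Multiplicity adjustment; 'bh' (Benjamini–Hochberg), 'bonferroni' or 'none'."""
    arr = np.asarray(ps, dtype=np.float64)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none":
        return [float(p) for p in arr]
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    if arr.size == 0:
        return []
    return [float(p) for p in multipletests(arr, method=key)[1]]


def filter_records(records: Sequence[BiomarkerRecord], alpha: float = 0.01) -> list[BiomarkerRecord]:
    """Keep records with adjusted p < alpha and opposite-signed group means.

    A zero mean fails the sign requirement.
    """
    return [
        r
        for r in records
        if r.p_adjusted < alpha and np.sign(r.mean_a) != 0 and np.sign(r.mean_a) == -np.sign(r.mean_b)
    ]


def differential_filter(
    candidates: Sequence[ClassifierCandidate],
    group_a: MoAPointCloud,
    group_b: MoAPointCloud,
    alpha: float = 0.01,
    adjustment: str = "bh",
) -> list[BiomarkerRecord]:
    """Differential best-classifier proteins between two MoA groups.

    Single-protein candidates are tested (Mann–Whitney on the two groups'
    signal distributions), p-values adjusted across the candidate list, and
    only significant proteins whose group means have opposite signs are kept.
    Strength is |mean_a * mean_b|.
    """
    if group_a.protein_order != group_b.protein_order:
        raise ValueError("groups span different protein orders")
    singles = [c for c in candidates if len(c.proteins) == 1]
    col = {p: j for j, p in enumerate(group_a.protein_order)}
    rows = []
    for c in singles:
        p = c.proteins[0]
        if p not in col:
            raise ValueError(f"candidate protein {p!r} not in point cloud")
        va, vb = group_a.matrix[:, col[p]], group_b.matrix[:, col[p]]
        _, praw = mann_whitney(va, vb)
        rows.append((p, float(va.mean()), float(vb.mean()), praw))
    adj = adjust_pvalues([r[3] for r in rows], method=adjustment)
    records = [
        BiomarkerRecord(
            protein=p,
            mean_a=ma,
            mean_b=mb,
            strength=abs(ma * mb),
            p_raw=praw,
            p_adjusted=padj,
        )
        for (p, ma, mb, praw), padj in zip(rows, adj)
    ]
    return filter_records(records, alpha=alpha)


def biomarker_report(
    records: Sequence[BiomarkerRecord],
    bcp_sets: Mapping[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Table-style report: rows sorted by strength descending.

    ``bcp_sets`` maps phenotype names to best-classifier protein sets; the
    report annotates each record with the phenotypes whose BCP set contains
    it.
    """
    bcp_sets = bcp_sets or {}
    annotated = [
        replace(
            r,
            bcp_membership=frozenset(k for k, s in bcp_sets.items() if r.protein in s),
        )
        for r in records
    ]
    annotated.sort(key=lambda r: (-r.strength, r.protein))
    return pd.DataFrame(
        {
            "protein": [r.protein for r in annotated],
            "mean_A": [r.mean_a for r in annotated],
            "mean_B": [r.mean_b for r in annotated],
            "strength": [r.strength for r in annotated],
            "p_raw": [r.p_raw for r in annotated],
            "p_adjusted": [r.p_adjusted for r in annotated],
            "partition": [r.partition for r in annotated],
            "bcp": ["&".join(sorted(r.bcp_membership)) or "-" for r in annotated],
        }
    )


# ---------------------------------------------------------------------------
# Packaged reference table
# ---------------------------------------------------------------------------


def load_reference_biomarkers() -> pd.DataFrame:
    """Load the packaged 30-row published differential-biomarker table.

    Columns: rank, uniprot, gene_symbol, gene_name, mean_low (group mean in
    the low-adverse-event intersection group), mean_high, strength_printed
    (read-only; its formula is not recoverable from the published means),
    p_adjusted, bcp.
    """
    with resources.files("moanet.data").joinpath("table1_biomarkers.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def reference_records() -> list[BiomarkerRecord]:
    """The reference table as :class:`BiomarkerRecord` objects.

    ``p_raw`` is not published, so it is set equal to the adjusted value;
    only the adjusted value enters the differential filter.
    """
    df = load_reference_biomarkers()
    out = []
    for row in df.itertuples(index=False):
        bcp = frozenset() if row.bcp == "-" else frozenset(row.bcp.split("&"))
        out.append(
            BiomarkerRecord(
                protein=row.gene_symbol,
                mean_a=float(row.mean_low),
                mean_b=float(row.mean_high),
                strength=abs(float(row.mean_low) * float(row.mean_high)),
                p_raw=float(row.p_adjusted),
                p_adjusted=float(row.p_adjusted),
                bcp_membership=bcp,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Over-representation utility
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line needs >= 3 columns: {line!r}")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def overrepresentation(
    genes: set[str],
    gene_sets: Mapping[str, set[str]],
    background: set[str],
) -> pd.DataFrame:
    """One-sided Fisher-exact over-representation of ``genes`` in each set.

    LOD is log10 of the odds ratio with a Haldane 0.5 correction applied to
    any zero cell; p-values are BH-adjusted across the gene sets.
    """
    if not background:
        raise ValueError("background must be non-empty")
    if not genes <= background:
        raise ValueError("query genes must be a subset of the background")
    names = sorted(gene_sets)
    rows = []
    for name in names:
        s = gene_sets[name] & background
        a = len(genes & s)
        b = len(genes - s)
        c = len(s - genes)
        d = len(background) - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        if min(a, b, c, d) == 0:
            odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            odds = (a * d) / (b * c)
        rows.append((name, a, len(s), odds, math.log10(odds), float(p)))
    df = pd.DataFrame(
        rows, columns=["gene_set", "overlap", "set_size", "odds_ratio", "lod", "p"]
    )
    df["p_adjusted"] = adjust_pvalues(df["p"].tolist(), method="bh")
    return df
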