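"""End-to-end pipeline orchestration and provenance capture.

A :class:`PipelineConfig` collects every tunable of the study; defaults
follow the published analysis where it states them (ensemble of K=200 MoAs
at >= 80% restriction accuracy, 25% quartile strata, top 200 classifier
proteins, adjusted p < 0.01, top 2% proximity cut).  ``run_all`` executes
simulate -> fit -> stratify -> compare -> biomarkers -> proximity on either
a synthetic instance or user-supplied files, writing every intermediate
artifact plus a manifest, and is byte-identical under a fixed config.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomarkers import best_classifiers, biomarker_report, differential_filter
from .compare import MoAPointCloud, dispersion, group_dendrogram, mds_embed, mhd, to_newick
from .core import (
    AnnealSchedule,
    MoAEnsemble,
    PropagationParams,
    sample_ensemble,
    select_top,
)
from .netio import read_network, read_states
from .proximity import overlap_report, propagate_seeds, top_fraction
from .stratify import intersect, stratify
from .synthetic import generate_network, plant_instance, write_instance

__all__ = ["PipelineConfig", "run_all", "ensemble_to_frame", "frame_to_ensemble"]


@dataclass
class PipelineConfig:
    """Validated configuration for the full pipeline."""

    # input files; when network is None a synthetic instance is generated
    network: str | None = None
    stimulus: str | None = None
    indication_effectors: str | None = None
    adverse_effectors: str | None = None
    restrictions: str | None = None
    # synthetic instance
    n_nodes: int = 300
    attach_m: int = 2
    p_inhibition: float = 0.3
    n_targets: int = 2
    n_eff_ind: int = 15
    n_eff_adv: int = 15
    n_extra_restrictions: int = 20
    restriction_noise: float = 0.0
    # ensemble
    n_runs: int = 240
    K: int = 200
    min_accuracy: float = 0.8
    allow_fewer: bool = False
    min_magnitude: float = 0.05
    sign_constrained: bool = True
    # propagation / annealing
    max_iterations: int = 500
    convergence_tol: float = 1e-6
    damping: float = 0.5
    initial_temperature: float = 0.05
    cooling_factor: float = 0.9
    steps_per_temperature: int = 120
    n_temperatures: int = 60
    move_scale: float = 0.4
    search_tol: float = 1e-3
    # stratification / biomarkers / proximity
    quartile: float = 0.25
    top_n_classifiers: int = 200
    alpha: float = 0.01
    adjustment: str = "bh"
    restart_prob: float = 0.15
    top_proximity_fraction: float = 0.02
    # global seed driving every stochastic stage
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 4:
            raise ValueError("K must be >= 4")
        if not (0.0 <= self.min_accuracy <= 1.0):
            raise ValueError("min_accuracy must be in [0, 1]")
        if not (0.0 < self.quartile <= 0.5):
            raise ValueError("quartile must be in (0, 0.5]")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.adjustment not in ("bh", "bonferroni", "none"):
            raise ValueError("adjustment must be one of bh/bonferroni/none")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not (0.0 < self.top_proximity_fraction <= 1.0):
            raise ValueError("top_proximity_fraction must be in (0, 1]")
        # propagation / schedule invariants are re-checked by their dataclasses
        self.propagation_params()
        self.anneal_schedule()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def propagation_params(self) -> PropagationParams:
        return PropagationParams(
            max_iterations=self.max_iterations,
            convergence_tol=self.convergence_tol,
            damping=self.damping,
        )

    def anneal_schedule(self) -> AnnealSchedule:
        return AnnealSchedule(
            initial_temperature=self.initial_temperature,
            cooling_factor=self.cooling_factor,
            steps_per_temperature=self.steps_per_temperature,
            n_temperatures=self.n_temperatures,
            move_scale=self.move_scale,
            search_tol=self.search_tol,
        )


def ensemble_to_frame(ensemble: MoAEnsemble) -> pd.DataFrame:
    """Ensemble as a matrix: rows = MoAs, columns = proteins (+ accuracy, seed)."""
    proteins = sorted(ensemble.moas[0].signals)
    rows = {
        "seed": [m.seed for m in ensemble.moas],
        "accuracy": [m.accuracy for m in ensemble.moas],
    }
    for p in proteins:
        rows[p] = [m.signals[p] for m in ensemble.moas]
    return pd.DataFrame(rows)


def frame_to_ensemble(df: pd.DataFrame, K: int, min_accuracy: float) -> MoAEnsemble:
    """Inverse of :func:`ensemble_to_frame` (weights are not persisted)."""
    from .core import MoA

    proteins = [c for c in df.columns if c not in ("seed", "accuracy")]
    moas = tuple(
        MoA(
            signals={p: float(row[p]) for p in proteins},
            weights={},
            accuracy=float(row["accuracy"]),
            seed=int(row["seed"]),
        )
        for _, row in df.iterrows()
    )
    return MoAEnsemble(moas=moas, K=K, min_accuracy=min_accuracy, total_sampled=len(moas))


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_all(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute every stage, writing artifacts and a manifest to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.propagation_params()
    schedule = config.anneal_schedule()

    # --- stage 1: inputs -------------------------------------------------
    if config.network is None:
        net = generate_network(
            config.n_nodes, config.attach_m, config.p_inhibition, seed=config.seed
        )
        instance = plant_instance(
            net,
            n_targets=config.n_targets,
            n_eff_ind=config.n_eff_ind,
            n_eff_adv=config.n_eff_adv,
            restriction_noise=config.restriction_noise,
            n_extra_restrictions=config.n_extra_restrictions,
            seed=config.seed,
            params=params,
        )
        write_instance(instance, out / "instance")
        network = instance.network
        stimulus = instance.stimulus
        indication = instance.indication
        adverse = instance.adverse_event
        restrictions = instance.restrictions
    else:
        network = read_network(config.network)
        stimulus, _ = read_states(config.stimulus, kind="stimulus", network=network)
        indication, _ = read_states(
            config.indication_effectors, kind="effectors", network=network,
            name="indication", role="indication",
        )
        adverse, _ = read_states(
            config.adverse_effectors, kind="effectors", network=network,
            name="adverse_event", role="adverse_event",
        )
        restrictions, _ = read_states(config.restrictions, kind="restrictions", network=network)

    # --- stage 2: ensemble ----------------------------------------------
    moas = sample_ensemble(
        network, stimulus, restrictions,
        n_runs=config.n_runs, schedule=schedule, params=params,
        base_seed=config.seed, min_magnitude=config.min_magnitude,
        sign_constrained=config.sign_constrained,
    )
    ensemble = select_top(moas, K=config.K, min_accuracy=config.min_accuracy,
                          allow_fewer=config.allow_fewer)
    _write_tsv(ensemble_to_frame(ensemble), out / "ensemble.tsv")

    # --- stage 3: stratification -----------------------------------------
    strat_ind = stratify(ensemble, indication, quartile=config.quartile)
    strat_adv = stratify(ensemble, adverse, quartile=config.quartile)
    strat_df = pd.DataFrame(
        {
            "moa": list(strat_ind.labels),
            "projection_indication": [strat_ind.projection[i] for i in strat_ind.labels],
            "intensity_indication": [strat_ind.intensity[i] for i in strat_ind.labels],
            "label_indication": [strat_ind.labels[i] for i in strat_ind.labels],
            "projection_adverse": [strat_adv.projection[i] for i in strat_ind.labels],
            "intensity_adverse": [strat_adv.intensity[i] for i in strat_ind.labels],
            "label_adverse": [strat_adv.labels[i] for i in strat_ind.labels],
        }
    )
    _write_tsv(strat_df, out / "stratification.tsv")

    # --- stage 4: group geometry ------------------------------------------
    cloud = MoAPointCloud.from_moas(ensemble.moas)
    group_ids = {
        "High-indication": strat_ind.group("High"),
        "Low-indication": strat_ind.group("Low"),
        "High-adverse": strat_adv.group("High"),
        "Low-adverse": strat_adv.group("Low"),
    }
    names = sorted(group_ids)
    clouds = {g: cloud.subset(ids) for g, ids in group_ids.items()}
    D = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j:
                D[i, j] = D[j, i] = mhd(clouds[a], clouds[b])
    dist_df = pd.DataFrame(D, index=names, columns=names)
    dist_df.to_csv(out / "group_distances.tsv", sep="\t", float_format="%.10g")
    disp = {g: dispersion(clouds[g]) for g in names}
    _write_tsv(
        pd.DataFrame({"group": names, "dispersion": [disp[g] for g in names]}),
        out / "group_dispersion.tsv",
    )
    (out / "group_dendrogram.nwk").write_text(to_newick(group_dendrogram(names, D)) + "\n")
    coords = mds_embed(cloud, dims=2)
    _write_tsv(
        pd.DataFrame(
            {
                "moa": list(coords),
                "mds1": [coords[i][0] for i in coords],
                "mds2": [coords[i][1] for i in coords],
            }
        ),
        out / "mds_coordinates.tsv",
    )

    # --- stage 5: biomarkers ----------------------------------------------
    # intersection groups: strongest indication responders split by adverse
    # event intensity
    inter_low = intersect(strat_ind, strat_adv, "Low", "Low")
    inter_high = intersect(strat_ind, strat_adv, "Low", "High")
    result: dict = {
        "intersection_low_low": sorted(inter_low),
        "intersection_low_high": sorted(inter_high),
    }
    bcp_sets = {}
    for tag, sa, sb in (
        ("indication", strat_ind.group("Low"), strat_ind.group("High")),
        ("adverse", strat_adv.group("Low"), strat_adv.group("High")),
    ):
        cands = best_classifiers(
            cloud.subset(sa), cloud.subset(sb), top_n=config.top_n_classifiers
        )
        bcp_sets[tag] = {c.proteins[0] for c in cands}
    if len(inter_low) >= 2 and len(inter_high) >= 2:
        ga, gb = cloud.subset(inter_low), cloud.subset(inter_high)
        cands = best_classifiers(ga, gb, top_n=config.top_n_classifiers)
        records = differential_filter(
            cands, ga, gb, alpha=config.alpha, adjustment=config.adjustment
        )
        report = biomarker_report(records, bcp_sets=bcp_sets)
    else:
        records = []
        report = biomarker_report([])
    _write_tsv(report, out / "biomarkers.tsv")

    # --- stage 6: proximity cross-check ----------------------------------
    seed_sets = {
        "drug": stimulus.proteins,
        "indication": indication.proteins,
        "adverse": adverse.proteins,
    }
    top_sets = []
    score_frames = []
    for tag, seeds in seed_sets.items():
        res = propagate_seeds(network, seeds, restart_prob=config.restart_prob)
        top_sets.append(top_fraction(res, config.top_proximity_fraction))
        score_frames.append(
            pd.DataFrame(
                {"protein": sorted(res.scores), "seed_set": tag,
                 "score": [res.scores[p] for p in sorted(res.scores)]}
            )
        )
    _write_tsv(pd.concat(score_frames, ignore_index=True), out / "proximity_scores.tsv")
    biomarker_set = {r.protein for r in records}
    overlap = overlap_report(biomarker_set, top_sets, background=set(network.nodes))
    result["proximity_overlap"] = {
        "union_size": len(overlap["union"]),
        "overlap": sorted(overlap["overlap"]),
        "count": overlap["count"],
        "p_hypergeom": overlap["p_hypergeom"],
    }
    (out / "overlap_report.json").write_text(json.dumps(result, indent=1, sort_keys=True))

    # --- manifest ---------------------------------------------------------
    cfg = asdict(config)
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "moanet_version": __version__,
        "python": platform.python_version(),
        "n_moas_sampled": len(moas),
        "n_moas_selected": len(ensemble),
        "mean_accuracy": float(np.mean([m.accuracy for m in ensemble.moas])),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
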