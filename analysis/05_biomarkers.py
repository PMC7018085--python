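#!/usr/bin/env python
"""Extract differential biomarker proteins.

Between the two intersection groups from step 03 (strong indication
responders with low vs high adverse-event intensity): ranks best-classifier
proteins by threshold-rule accuracy, Mann-Whitney-tests each candidate,
adjusts with Benjamini-Hochberg and keeps significant proteins whose group
means have opposite signs.  Also re-derives the partition counts of the
packaged published reference table as a sanity anchor.
"""

import json
from pathlib import Path

import pandas as pd

from moanet import (
    best_classifiers,
    biomarker_report,
    differential_filter,
    filter_records,
    reference_records,
)
from moanet.compare import MoAPointCloud
from moanet.pipeline import frame_to_ensemble

OUT = Path("results/analysis")


def main() -> None:
    df = pd.read_csv(OUT / "ensemble.tsv", sep="\t")
    ens = frame_to_ensemble(df, K=len(df), min_accuracy=0.0)
    strat = pd.read_csv(OUT / "stratification.tsv", sep="\t")
    inter = json.loads((OUT / "intersections.json").read_text())
    cloud = MoAPointCloud.from_moas(ens.moas)

    # best-classifier sets per phenotype (Low vs High groups)
    bcp_sets = {}
    for role, col in (("indication", "label_indication"), ("adverse", "label_adverse")):
        ga = cloud.subset(set(strat.loc[strat[col] == "Low", "moa"]))
        gb = cloud.subset(set(strat.loc[strat[col] == "High", "moa"]))
        bcp_sets[role] = {c.proteins[0] for c in best_classifiers(ga, gb, top_n=200)}

    # Table-style comparison 1: strong responders split by adverse intensity
    ga = cloud.subset(set(inter["low_low"]))
    gb = cloud.subset(set(inter["low_high"]))
    cands = best_classifiers(ga, gb, top_n=200)
    records = differential_filter(cands, ga, gb, alpha=0.01)
    report = biomarker_report(records, bcp_sets=bcp_sets)
    report.to_csv(OUT / "biomarkers.tsv", sep="\t", index=False, float_format="%.6g")
    print(f"intersection groups: {len(ga)} vs {len(gb)} MoAs -> "
          f"{len(report)} differential biomarkers")

    # comparison 2: adverse-event quartile groups (unconstrained phenotype)
    ga = cloud.subset(set(strat.loc[strat["label_adverse"] == "Low", "moa"]))
    gb = cloud.subset(set(strat.loc[strat["label_adverse"] == "High", "moa"]))
    cands = best_classifiers(ga, gb, top_n=200)
    records = differential_filter(cands, ga, gb, alpha=0.01)
    report_adv = biomarker_report(records, bcp_sets=bcp_sets)
    report_adv.to_csv(OUT / "biomarkers_adverse.tsv", sep="\t", index=False,
                      float_format="%.6g")
    n_act = (report_adv["partition"] == "A-active/B-inactive").sum()
    n_inact = (report_adv["partition"] == "A-inactive/B-active").sum()
    print(f"adverse Low vs High groups ({len(ga)} vs {len(gb)}): "
          f"{len(report_adv)} differential biomarkers "
          f"({n_act} active in the Low group, {n_inact} inactive)")

    kept = filter_records(reference_records(), alpha=0.01)
    act = sum(r.partition == "A-active/B-inactive" for r in kept)
    print(f"reference-table anchor: {len(kept)} rows pass the filter, "
          f"partitioned {act} / {len(kept) - act}")


if __name__ == "__main__":
    main()
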