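#!/usr/bin/env python
"""Cross-check biomarkers by network proximity.

Scores every protein by random-walk-with-restart proximity to three seed
sets (drug targets, indication effectors, adverse-event effectors) on the
undirected network skeleton, takes the top 2% per seed set, unions them and
counts how many differential biomarkers from step 05 fall inside, with a
hypergeometric enrichment p-value.
"""

import json
import warnings
from pathlib import Path

import pandas as pd

from moanet import overlap_report, propagate_seeds, read_network, read_states, top_fraction

INST = Path("results/analysis/instance")
OUT = Path("results/analysis")


def main() -> None:
    network = read_network(INST / "network.tsv")
    seed_sets = {}
    for tag, fname in (("drug", "stimulus.tsv"),
                       ("indication", "effectors_indication.tsv"),
                       ("adverse", "effectors_adverse_event.tsv")):
        states, _ = read_states(INST / fname, network=network)
        seed_sets[tag] = states.proteins
    tops, frames = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tag, seeds in seed_sets.items():
            res = propagate_seeds(network, seeds)
            tops.append(top_fraction(res, 0.02))
            frames.append(pd.DataFrame({
                "protein": sorted(res.scores), "seed_set": tag,
                "score": [res.scores[p] for p in sorted(res.scores)],
            }))
    pd.concat(frames, ignore_index=True).to_csv(
        OUT / "proximity_scores.tsv", sep="\t", index=False, float_format="%.6g")
    biomarkers: set[str] = set()
    for fname in ("biomarkers.tsv", "biomarkers_adverse.tsv"):
        df = pd.read_csv(OUT / fname, sep="\t")
        biomarkers |= set(df["protein"])
    rep = overlap_report(biomarkers, tops, background=set(network.nodes))
    summary = {"n_biomarkers": len(biomarkers), "union_size": len(rep["union"]),
               "overlap": sorted(rep["overlap"]), "count": rep["count"],
               "p_hypergeom": rep["p_hypergeom"]}
    (OUT / "proximity_overlap.json").write_text(json.dumps(summary, indent=1))
    print(f"top-2% union: {len(rep['union'])} proteins across "
          f"{len(tops)} seed sets (proximity scorer: RWR stand-in)")
    print(f"{rep['count']} of {len(biomarkers)} biomarkers inside the union "
          f"(hypergeometric p = {rep['p_hypergeom']:.3g})")


if __name__ == "__main__":
    main()
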