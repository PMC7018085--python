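#!/usr/bin/env python
"""Compare the stratified groups geometrically.

Each MoA is a point in the 300-dimensional protein-signal space.  Computes
the modified Hausdorff distance between the four quartile groups, their
within-group dispersion, an average-linkage dendrogram over the group
distances, and a 2-D classical MDS embedding of all selected MoAs.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from moanet import dispersion, group_dendrogram, mds_embed, mhd, to_newick
from moanet.compare import MoAPointCloud
from moanet.pipeline import frame_to_ensemble

OUT = Path("results/analysis")


def main() -> None:
    df = pd.read_csv(OUT / "ensemble.tsv", sep="\t")
    ens = frame_to_ensemble(df, K=len(df), min_accuracy=0.0)
    strat = pd.read_csv(OUT / "stratification.tsv", sep="\t")
    cloud = MoAPointCloud.from_moas(ens.moas)
    groups = {}
    for role, col in (("indication", "label_indication"), ("adverse", "label_adverse")):
        for label in ("Low", "High"):
            groups[f"{label}-{role}"] = set(strat.loc[strat[col] == label, "moa"])
    names = sorted(groups)
    clouds = {g: cloud.subset(ids) for g, ids in groups.items()}
    D = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j:
                D[i, j] = D[j, i] = mhd(clouds[a], clouds[b])
    pd.DataFrame(D, index=names, columns=names).to_csv(
        OUT / "group_distances.tsv", sep="\t", float_format="%.6g")
    disp = pd.DataFrame({"group": names,
                         "dispersion": [dispersion(clouds[g]) for g in names]})
    disp.to_csv(OUT / "group_dispersion.tsv", sep="\t", index=False, float_format="%.6g")
    tree = group_dendrogram(names, D)
    (OUT / "group_dendrogram.nwk").write_text(to_newick(tree) + "\n")
    coords = mds_embed(cloud, dims=2)
    pd.DataFrame({
        "moa": list(coords),
        "mds1": [c[0] for c in coords.values()],
        "mds2": [c[1] for c in coords.values()],
    }).to_csv(OUT / "mds_coordinates.tsv", sep="\t", index=False, float_format="%.6g")
    print("group MHD matrix:")
    print(pd.DataFrame(D, index=names, columns=names).round(3))
    print("\ndispersion per group:")
    print(disp.round(3).to_string(index=False))
    print(f"\ndendrogram: {to_newick(tree)}")


if __name__ == "__main__":
    main()
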