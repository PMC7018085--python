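#!/usr/bin/env python
"""Stratify the ensemble by response intensity.

Projects every MoA onto each phenotype's effector states (TSignal), ranks by
role-oriented intensity and cuts 25% quartile groups: Low/High-indication
and High/Low-adverse-event.  Also counts the intersection groups used for
biomarker extraction (strong responders with low vs high adverse-event
intensity).
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from moanet import intersect, read_states, stratify
from moanet.pipeline import frame_to_ensemble

INST = Path("results/analysis/instance")
OUT = Path("results/analysis")


def main() -> None:
    df = pd.read_csv(OUT / "ensemble.tsv", sep="\t")
    ensemble = frame_to_ensemble(df, K=len(df), min_accuracy=0.0)
    ind, _ = read_states(INST / "effectors_indication.tsv", kind="effectors",
                         name="indication", role="indication")
    adv, _ = read_states(INST / "effectors_adverse_event.tsv", kind="effectors",
                         name="adverse_event", role="adverse_event")
    si = stratify(ensemble, ind)
    sa = stratify(ensemble, adv)
    ids = list(si.labels)
    pd.DataFrame({
        "moa": ids,
        "projection_indication": [si.projection[i] for i in ids],
        "label_indication": [si.labels[i] for i in ids],
        "projection_adverse": [sa.projection[i] for i in ids],
        "label_adverse": [sa.labels[i] for i in ids],
    }).to_csv(OUT / "stratification.tsv", sep="\t", index=False)
    inter = {
        "low_low": sorted(intersect(si, sa, "Low", "Low")),
        "low_high": sorted(intersect(si, sa, "Low", "High")),
    }
    (OUT / "intersections.json").write_text(json.dumps(inter, indent=1))
    low_p = np.mean([si.projection[i] for i in si.group("Low")])
    high_p = np.mean([si.projection[i] for i in si.group("High")])
    print(f"groups of {len(si.group('Low'))} (quartiles of {len(ensemble)})")
    print(f"indication projection: Low group mean {low_p:.3f}, High group mean {high_p:.3f}")
    print(f"strong responders splitting by adverse event: "
          f"{len(inter['low_low'])} Low-ind&Low-adv, {len(inter['low_high'])} Low-ind&High-adv")


if __name__ == "__main__":
    main()
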