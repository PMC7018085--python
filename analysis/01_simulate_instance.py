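#!/usr/bin/env python
"""Generate the synthetic study instance.

Builds the default 300-node signed scale-free network, plants a ground-truth
weight assignment, and derives the drug stimulus (2 clamped targets), the two
15-effector phenotype sets (indication and adverse event, disease states
reverted by the planted response) and the 35-entry restriction set.  All
files go to results/analysis/instance/.
"""

import json
from pathlib import Path

from moanet import generate_network, plant_instance, write_instance
from moanet.synthetic import true_accuracy

SEED = 7
OUT = Path("results/analysis/instance")


def main() -> None:
    net = generate_network(n_nodes=300, attach_m=2, p_inhibition=0.3, seed=SEED)
    inst = plant_instance(net, seed=SEED)
    paths = write_instance(inst, OUT)
    print(f"network: {net.n_nodes} proteins, {net.n_edges} signed edges")
    print(f"stimulus: {dict(inst.stimulus.states)}")
    print(f"effectors: {len(inst.indication.states)} indication, "
          f"{len(inst.adverse_event.states)} adverse-event")
    print(f"restrictions: {len(inst.restrictions)} "
          f"(true-weight accuracy {true_accuracy(inst):.3f})")
    print(f"written to {paths['network'].parent}")


if __name__ == "__main__":
    main()
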