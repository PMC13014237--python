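"""Label multi-metric affinity records at the 50 uM cutoff, sample decoys,
and build a scaffold-balanced split.

Run:  python examples/02_curation_and_split.py
"""

from collections import Counter

from funcscreen import scaffold_balanced_split
from funcscreen.curation import (ActivityRecord, label_activity_table,
                                 sample_decoys)
from funcscreen.synthdata import WorldSpec, generate_world

world = generate_world(WorldSpec(n_proteins=10, n_molecules=80,
                                 records_per_protein=30, seed=42))
pairs, ambiguous = label_activity_table(world.records, cutoff_um=50.0)
print("label counts:", dict(Counter(p.label for p in pairs)),
      f"(+{len(ambiguous)} ambiguous pairs excluded)")
# A pair is active only if EVERY reported metric (Ki/IC50/EC50/Kd) is below
# 50 uM, inactive if every metric is above; conflicts are excluded.

actives = [p for p in pairs if p.label == "active"]
measured = [(p.protein_id, p.mol_id) for p in pairs]
pool = sorted({r.mol_id for r in world.records})
decoys = sample_decoys(actives, pool, measured, ratio=1.0, seed=0)
print(f"sampled {len(decoys)} decoys (assumed negatives, 1 per active, "
      "never overlapping measured pairs)")

split = scaffold_balanced_split(world.molecules, (0.8, 0.1, 0.1), seed=0)
sizes = {p: len(split.partition(p)) for p in ("train", "val", "test")}
print("scaffold-balanced split sizes:", sizes)
# All molecules sharing a Murcko scaffold land in the same partition, so the
# test set never contains a scaffold seen in training.
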