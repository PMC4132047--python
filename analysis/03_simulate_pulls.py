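#!/usr/bin/env python
"""Synthetic force-probe pulling campaign.

Constant-velocity spring pulls (830 pN/nm per bundle, 7 bundles) of the
amorphous bundles across the crystal interface and through water alone,
at 0.02-20 m/s, four replicas each; Langevin emulation whose friction is the
washboard bond model plus per-residue water drag.
"""

import json
from pathlib import Path

from silkfric import synth

SEED = 1
OUT = Path("results")
with open(OUT / "contact.json") as fh:
    contact = json.load(fh)

truth = synth.GroundTruth(N=contact["n_contact_residues"],
                          N_total=contact["n_total_amorphous_residues"])
traces = synth.generate_dataset(seed=SEED, truth=truth)
manifest = synth.write_traces(traces, OUT / "traces")
print(f"{len(traces)} traces (7 velocities x 4 replicas x "
      f"{{total, water_only}}), master seed {SEED} -> {manifest}")
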