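#!/usr/bin/env python
"""Turn raw pulling traces into the per-velocity friction dataset.

Smoothed peak force per trace, replica mean +- SEM, water subtraction
(F_ac = F_total - F_water), per-residue force f_res = F_ac / N, water-law
fit F_w = N_total xi_w V, and shear stress tau = F_ac / A.
"""

import json
from pathlib import Path

from silkfric import extract, synth

OUT = Path("results")
with open(OUT / "contact.json") as fh:
    contact = json.load(fh)

traces = synth.read_traces(OUT / "traces")
ds = extract.aggregate(traces, contact["n_contact_residues"],
                       contact["n_total_amorphous_residues"])
xi_w, xi_se = extract.fit_water_law(ds)
ds = extract.to_stress(ds, contact["area_nm2"])
ds.to_csv(OUT / "friction_dataset.csv")

print(ds.to_dataframe().to_string(index=False))
print(f"\nwater drag per residue: xi_w = {xi_w:.3e} +- {xi_se:.1e} Ns/m "
      f"(bulk-water scale is 1e-12 Ns/m)")
print(f"dataset -> {OUT/'friction_dataset.csv'}")
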