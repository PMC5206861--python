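#!/usr/bin/env python
"""Set algebra over the comparison profiles.

Venn-decomposes the simulated injury and treatment called sets, extracts
the treatment-exclusive miRNAs, and reruns the inverse-regulation worked
example on the published top lists of the mouse cisplatin-AKI MSC study
(expected: miR-141 down in injury / up with treatment, miR-377 the
reverse).  Outputs under results/03_setops/.
"""

import json
from pathlib import Path

import pandas as pd

from mirnet.qpcr import ComparisonProfile
from mirnet.setops import exclusive_set, inverse_regulated, venn
from mirnet.worked_example import injury_profile, treatment_profile

indir = Path("results/02_profiles")
outdir = Path("results/03_setops")
outdir.mkdir(parents=True, exist_ok=True)


def load(name):
    table = pd.read_csv(indir / name, sep="\t", index_col="feature")
    return ComparisonProfile(name.removesuffix(".tsv"), "", "",
                             table[["magnitude", "direction"]],
                             float(table["threshold"].iloc[0]))


injury = load("Cis_vs_Saline_fc3.tsv")
treatment = load("CisMSC_vs_Cis_fc3.tsv")

v = venn({"injury": injury.called, "treatment": treatment.called})
(outdir / "venn.json").write_text(json.dumps(v.to_dict(), indent=2) + "\n")
print("Venn regions:", v.to_dict()["counts"])

excl = exclusive_set(treatment.called, {"injury": injury.called})
(outdir / "treatment_exclusive.txt").write_text(
    "\n".join(excl) + ("\n" if excl else ""))
print(f"treatment-exclusive miRNAs: {len(excl)}")

inv_sim = inverse_regulated(injury, treatment)
print(f"inverse-regulated (simulated): {len(inv_sim)}")

inv_pub = inverse_regulated(injury_profile(), treatment_profile())
(outdir / "inverse_published.json").write_text(
    json.dumps(inv_pub.to_dict(), indent=2) + "\n")
print("inverse-regulated (published top lists):",
      ", ".join(f"{m} ({a}->{b})" for m, (a, b)
                in sorted(inv_pub.members.items())))
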