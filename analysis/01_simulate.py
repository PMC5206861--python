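#!/usr/bin/env python
"""Simulate the miRNome qPCR screen with planted injury regulation.

Generates the default 528-miRNA panel across saline / cisplatin /
cisplatin+MSC groups (3 replicates each) with 39 upregulated and 37
downregulated miRNAs planted at >= 5-fold in the cisplatin-vs-saline
comparison, plus three-database target-prediction tables and a gene-set
annotation.  Writes everything under results/01_simulated/.
"""

import argparse
import json
from pathlib import Path

from mirnet.synthetic import (generate_annotation, generate_ct_table,
                              generate_prediction_tables,
                              injury_screen_config)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=17)
args = parser.parse_args()

outdir = Path("results/01_simulated")
outdir.mkdir(parents=True, exist_ok=True)

config = injury_screen_config(seed=args.seed)
ct, truth = generate_ct_table(config)
ct.write_csv(outdir / "ct_table.csv", outdir / "groups.csv")
for table in generate_prediction_tables(config, truth):
    db = table.records["db"].iloc[0]
    table.write_tsv(outdir / f"targets_{db}.tsv")
generate_annotation(config, truth).write_gmt(outdir / "annotation.gmt")
(outdir / "truth.json").write_text(json.dumps(
    {cid: {"up": sorted(r["up"]), "down": sorted(r["down"])}
     for cid, r in truth.regulation.items()}, indent=2) + "\n")

print(f"panel features: {len(ct.features)}; samples: {len(ct.samples)}")
print(f"planted (Cis_vs_Saline): {len(truth.up('Cis_vs_Saline'))} up, "
      f"{len(truth.down('Cis_vs_Saline'))} down")
print(f"wrote {outdir}/")
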