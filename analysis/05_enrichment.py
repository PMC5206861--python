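#!/usr/bin/env python
"""Pathway over-representation of the consensus target genes.

Scores the pooled miR-141/miR-377 consensus targets against the pathway
annotation over the universe of all predicted genes (hypergeometric upper
tail, BH-adjusted).  Output: results/05_enrichment/enrichment.tsv.
"""

import json
from pathlib import Path

from mirnet.enrich import hypergeom_enrich, write_enrichment_tsv
from mirnet.network import TargetEdgeTable
from mirnet.worked_example import pathway_annotation, prediction_tables

outdir = Path("results/05_enrichment")
outdir.mkdir(parents=True, exist_ok=True)

consensus = json.loads(
    Path("results/04_network/consensus_targets.json").read_text())
query = set().union(*(set(v) for v in consensus.values()))
tables = prediction_tables()
universe = set(TargetEdgeTable.concat(tables).records["gene"])

result = hypergeom_enrich(query, pathway_annotation(), universe=universe)
write_enrichment_tsv(result, outdir / "enrichment.tsv")
print(result.to_string(index=False))
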