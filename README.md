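# mirnet

Inference of miRNA–mRNA regulatory networks from qPCR-array expression
profiles, for the kind of study design used in mesenchymal stromal cell
(MSC) therapy experiments: a miRNome PCR array profiled across control,
injury and treatment groups, followed by set analysis of the differential
miRNAs, multi-database target prediction, bipartite network construction
and pathway enrichment.

## The analysis

1. **Relative quantification.** Each feature's threshold cycle is
   normalized within-sample to a housekeeping small RNA (ΔCt), and
   abundance is expressed as `q = 10000 / 2^ΔCt` — a feature as abundant
   as the reference scores exactly 10,000, and each cycle of ΔCt is a
   twofold change.
2. **Differential calling.** Between-group fold change is the ratio of
   geometric-mean relative quantities, `FC = 2^(mean ΔCt_den − mean
   ΔCt_num)`; a miRNA is called up/down when `max(FC, 1/FC)` meets an
   inclusive threshold (default 3; a "top" tier at 5 seeds the network).
   Features undetected (Ct > 35) in more than half of a group's
   replicates are excluded from that comparison.
3. **Set analysis.** Venn-region decomposition of the called sets,
   exclusivity selection, and inverse-regulation detection — miRNAs called
   in opposite directions in the injury (cisplatin vs. saline) and
   treatment (cisplatin+MSC vs. cisplatin) comparisons.
4. **Network.** A bipartite miRNA→gene graph from target-prediction
   tables; edges carry the number of supporting databases, gene nodes
   targeted by fewer than 2 of the differential miRNAs are pruned, and
   consensus targets are genes predicted by all databases.
5. **Enrichment.** Upper-tail hypergeometric over-representation of a
   gene set against an annotation collection
   (`p = Σ_{i≥k} C(K,i)·C(N−K,n−i)/C(N,n)`) with Benjamini–Hochberg FDR.

A seeded synthetic generator (`mirnet.synthetic`) emulates a 528-miRNA
mouse miRNome array with planted differential regulation, so every stage
can be validated against known ground truth; `mirnet.worked_example`
packages the published top-regulated lists and consensus target genes of
a mouse cisplatin acute-kidney-injury MSC study for offline worked
examples.

## Worked example

```python
from mirnet.setops import inverse_regulated
from mirnet.network import consensus_targets
from mirnet.worked_example import injury_profile, treatment_profile, prediction_tables

inv = inverse_regulated(injury_profile(), treatment_profile())
print(inv.members)
# {'miR-141': ('down', 'up'), 'miR-377': ('up', 'down')}

tables = prediction_tables()
print(sorted(consensus_targets(tables, "miR-141", 3)))
# ['Ccne2', 'Ulk2', 'Yaf2']
print(len(consensus_targets(tables, "miR-377", 3)))
# 8
```

miR-141 is suppressed by injury and restored by treatment, miR-377 the
reverse — the two inversely regulated miRNAs — and the three-database
intersection yields their 3 and 8 consensus target genes.

The numbered scripts under `analysis/` run the same stages over a
simulated screen (`python analysis/01_simulate.py --seed 17`, then
`02_…` through `05_…`); with the default planted truth, the fold ≥ 3
caller reports exactly the 39 upregulated and 37 downregulated planted
miRNAs on the 528-feature panel. The `mirnet` CLI exposes each stage
(`simulate`, `call`, `venn`, `exclusive`, `inverse`, `network`,
`consensus`, `enrich`, `run`).

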