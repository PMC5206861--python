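# Methods

## Quantification model

Ct is the PCR cycle at which a transcript's amplification crosses
detection; one cycle corresponds to a twofold abundance difference under
the ideal-efficiency assumption made throughout. Within each sample,
ΔCt(f) = Ct(f) − Ct(reference) removes input-amount variation, and the
relative quantity is q = 10000/2^ΔCt. The constant 10000 is a display
scale: a feature as abundant as the housekeeping reference scores
10,000, and all fold-change arithmetic is invariant to it.

Between-group fold change uses geometric means: FC =
geomean(q, numerator)/geomean(q, denominator) = 2^(mean ΔCt_den − mean
ΔCt_num). Arithmetic means on the ΔCt (log) scale are the standard ΔΔCt
convention for qPCR and make the estimator unbiased for the planted fold
under Gaussian Ct noise. Calling is by magnitude, max(FC, 1/FC), with an
*inclusive* threshold; a downregulation of "fold ≥ 3" means FC ≤ 1/3.
No replicate-level significance test is applied — calling thresholds
point estimates only, matching the array-screening practice this package
models.

**Detection.** Wells with Ct above the detection limit (default 35
cycles) are undetected. A feature enters a comparison only when detected
in ≥ 50% of each group's replicates and in ≥ 2 wells per group;
otherwise it is reported `undetected` for that comparison rather than
producing an unbounded fold change. Both constants are arguments.

**Identifiers** are opaque, case-sensitive strings; `miR-92a` and
`miR-92a*` (the passenger strand) are distinct features and are never
merged — collapsing them would manufacture a spurious inverse-regulation
call in the worked example.

## Set operations

Venn decomposition assigns every element of the union to exactly one
region (the combination of sets containing it), so region sizes sum to
the union size; 2–5 sets are supported and outputs are sorted
lexicographically for stable files. `exclusive_set` filters a target set
against any collection of excluded sets. `inverse_regulated` returns
miRNAs called (up or down) in *both* profiles with differing directions;
it is symmetric in its arguments and a subset of the jointly-called set.
Which Venn regions constitute an "exclusive" signature is left to the
caller's configuration; the package provides the algebra, not a recipe.

## Network construction

The regulatory graph is bipartite: miRNA nodes (with an up/down
direction attribute taken from a caller-named comparison profile) and
gene nodes. One edge per predicted (miRNA, gene) pair, with `support` =
number of distinct predicting databases; database multiplicity is never
conflated with the minimum-targeting rule, which counts *distinct miRNA
neighbors* of a gene. `filter_min_targeting(net, k)` removes gene nodes
with fewer than k miRNA neighbors (default 2) and keeps all miRNA nodes,
so hub miRNAs remain visible even when isolated; the operation is
idempotent. Consensus targets of a miRNA are genes predicted by at least
`min_databases` distinct sources (default: all supplied — the full
intersection). No target-prediction algorithm is implemented; edge
tables are inputs. Exports: SIF (`mirna targets gene`; isolated nodes as
single-column lines) and GraphML with all node/edge attributes, which
round-trips exactly.

## Enrichment

One-sided over-representation only (the screening context never asks for
depletion): p = P(X ≥ k) for X hypergeometric with universe N,
annotation size K, query size n, computed by `scipy.stats.hypergeom.sf`.
Query members outside the universe are dropped with a logged count; set
members outside the universe count toward neither K nor k. The BH
step-up (via statsmodels, validated against hand-computed step-up values
in the tests) converts p to q in input order; the default significance
convention is q ≤ 0.05. The recommended universe is the set of all genes
appearing in the supplied prediction tables — the frame targets were
drawn from — and is overridable.

## Synthetic data generator

The generator emulates a 528-feature mouse miRNome qPCR array profiled
over saline / cisplatin / cisplatin+MSC groups with 3 replicates each,
the design of the study this package's worked examples come from.

* **Baseline:** each feature draws a latent mean Ct ~ N(26, 1.5²),
  shared by all samples; the spread keeps the whole panel comfortably
  inside the detection limit so the "expressed in common" filter retains
  all 528 features under default noise. The housekeeping feature sits at
  Ct 20 in every sample and is noise-free by default (so ΔCt noise has a
  single source; `reference_noise_sd` overrides).
* **Planted effects:** an f-fold "up" effect in a comparison sets the
  numerator group's Ct offset to the denominator group's offset −
  log2(f) ("down": + log2(f)), processed in list order. Anchoring to the
  denominator's *current* offset makes every comparison in a chain
  realize its planted fold exactly, e.g. a miRNA down 8× in injury and
  up 4× under treatment. A corollary: a miRNA planted only in the injury
  comparison reverts to baseline in the treatment group and therefore
  appears inverse-regulated between the two comparisons — the shape of a
  treatment that normalizes injury-induced changes.
* **Noise:** Gaussian per well on the Ct scale (log-normal abundance),
  default sd 0.1 cycles, the technical-replicate scale of array qPCR.
  Wells above the detection limit (35) become undetected, exercising the
  detection-handling path.
* **Prediction tables:** per miRNA, a `consensus_fraction` share of its
  true targets (default 10 per miRNA from a 2000-gene universe) appears
  in all databases; remaining per-database slots are database-unique
  decoys, so the full intersection recovers exactly the consensus share.
* **Annotation:** random gene sets (default 20, sizes 10–50), plus an
  optional set over-representing one miRNA's true targets.

Everything is a deterministic function of the seed (independent crc32-
derived substreams per output kind), and byte-identical across runs.

What the generator does *not* emulate: amplification-efficiency
variation between assays, inter-plate batch effects, correlated
biological replicate variation, hemolysis-style contamination, or any
sequence-determined target structure. Passing recovery tests therefore
shows the pipeline's arithmetic and thresholds are correct under the
stated error model, not that threshold 3 is well-calibrated for real
tissue data.

## Problem sizes and determinism

The default test and acceptance runs operate at the study's own scale —
a 529 × 9 Ct matrix — which takes milliseconds per replicate; the
recovery check uses 100 seeded replicates. With planted folds ≥ 5, a
calling threshold of 3 and noise sd 0.1, the margin between effect and
threshold is log2(5) − log2(3) ≈ 0.74 cycles against a group-mean-
difference sd of 0.1·√(2/3) ≈ 0.08 cycles, so exact recovery of the
planted 39-up/37-down sets is the overwhelmingly probable outcome of
every seed; the acceptance bar (≥ 95/100 seeds exact) leaves room for
tail events.

Ties at the threshold are resolved by the inclusive ≥ rule; all set
outputs are sorted lexicographically; report JSON is written with sorted
keys. Pipeline reruns under the same config and seed are byte-identical
except for the report's timestamp field.

## Known limitations

* The vendor web tool's internal normalization used by the original
  screen is unpublished; geometric-mean ΔΔCt is this package's pinned
  convention and may differ in detail.
* The worked-example prediction tables contain only the published
  consensus genes plus synthetic decoys, so the ≥ 2-miRNA filter leaves
  no gene nodes there (miR-141's and miR-377's consensus sets are
  disjoint); realistic edge tables are needed for a populated filtered
  network.
* Enrichment reproduces the statistic, not any external pathway
  database's term lists; GO-graph propagation and topology-aware scoring
  are out of scope.
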