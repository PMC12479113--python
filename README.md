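# tfcoverage

Audit coverage gaps in transcription-factor (TF) ChIP-seq compendia.

Public ChIP-seq collections are large but lopsided: a handful of famous TFs
and cell lines account for most experiments, while many TFs that *are*
expressed in a given cell type have never been assayed there. `tfcoverage`
makes those gaps explicit and quantifies their consequences. For TFs **T**
and samples **S** (cell lines or cell-type classes) it classifies every pair
(t, s) as

* **measured** — at least one ChIP-seq experiment targets (t, s);
* **unmeasured** — t is expressed in s (one-step expression threshold per
  TF) but no experiment exists: a biologically relevant missing experiment;
* **not expressed** — everything else.

On top of this inventory the package computes:

* **Inequality** — Gini coefficient
  `G = Σᵢⱼ |xᵢ − xⱼ| / (2 n² x̄)` and Lorenz curves of per-TF / per-cell-type
  experiment counts, plus the counterfactual Gini under one-experiment-per-
  expressed-pair coverage, and Spearman research-attention correlations.
* **Cover ratios** — per cell line and year, the fraction of its expressed
  genes (top 25% by expression) with a peak in the TSS ± 500 bp window
  ("Reg-TF cover ratio"); per entity and year, the fraction of GWAS SNPs
  inside at least one peak ("GWAS-SNP cover ratio"). Both use peaks
  deposited up to the target year, so the annual series are cumulative.
* **Acquisition-order simulation** — shuffle the deposit dates over the
  fixed experiment set, score each order by the span-normalized area under
  its annual GWAS-SNP cover-ratio trajectory (higher AUC = earlier
  coverage), and compare orders to the real one with subsampled Welch
  t-tests. Diverse-early orders win.
* **Prioritization** — "hidden gems": unmeasured pairs with > 1000
  knockout/knockdown DEGs whose TF is a known cell-type marker.

A synthetic-world generator (preferential-attachment metadata, bimodal
log-normal expression, TSS-enriched peaks, planted gems) provides ground
truth against which the whole pipeline is validated. See
[docs/methods.md](docs/methods.md) for the model details and conventions.

## Worked example

```python
from tfcoverage import (WorldConfig, generate_world, call_expression,
                        aggregate_to_class, build_inventory, measured_pairs,
                        gini, hidden_gems)
from tfcoverage.inventory import experiment_counts
from tfcoverage.synthetic_data import tf_names

world = generate_world(WorldConfig(seed=1))
tfs = tf_names(world.config)

counts = experiment_counts(world.metadata, by="tf", universe=tfs)
print(f"Gini of per-TF experiment counts: {gini(counts.to_numpy()):.3f}")

calls = call_expression(world.expression.loc[tfs]).calls
class_pairs = aggregate_to_class(calls, world.class_map)
measured, _ = measured_pairs(world.metadata, level="class",
                             mapping=world.class_map)
inv = build_inventory(class_pairs, measured, level="class",
                      tf_universe=tfs,
                      sample_universe=sorted(set(world.class_map)))
print(inv.status_counts().to_string())

gems, _ = hidden_gems(inv, world.deg, set(world.markers["tf"]))
print(gems[["tf", "sample", "n_deg"]].to_string(index=False))
```

prints

```
Gini of per-TF experiment counts: 0.584
status
measured         201
unmeasured       126
not_expressed     33
   tf  sample  n_deg
TF038 CLASS06   2580
TF060 CLASS02   1997
```

Read: with 600 experiments spread by rich-get-richer dynamics over 60 TFs,
experiment counts are strongly unequal (G = 0.58); of the 60 × 6 (TF, class)
pairs, 126 are expressed but never measured — and two of them (exactly the
world's planted gems) also have > 1000 knockout DEGs and a marker TF, making
them the top candidates for the next experiments.

The same pipeline runs from the shell:

```sh
tfcoverage make-world --seed 1 --out world/
tfcoverage run-all --seed 1 --out results/
tfcoverage simulate-order --world world/ --reps 100 --seed 1 --out sims.tsv
```

`run-all` writes one tidy TSV per stage (step fits, calls, name-match log,
inventories, Gini/Lorenz, cover-ratio series, order-simulation summary,
gems with a per-pair flag audit) plus a manifest with the run ID and output
hashes; reruns with the same config and seed are byte-identical. On user
data, point a YAML config at your own metadata/expression/TSS/SNP/DEG/marker
tables instead of a synthetic world.

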