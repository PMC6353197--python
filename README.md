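# sbnet

Bayesian-network analysis of sedentary-behaviour (SB) determinants on
categorical survey data: operationalisation of Eurobarometer-style raw fields
into 33 analysis variables, hybrid constraint/score structure learning,
bootstrap edge-stability averaging, and the graph statistics used to rank
determinants (network denseness, distance-to-SB, per-cluster mean distance,
stability-weighted betweenness centrality).

The real survey microdata is not redistributable, so the package ships a
first-class synthetic-data module: a configurable ground-truth Bayesian
network with Dirichlet-sampled conditional probability tables generates
Eurobarometer-like records (including raw instrument fields, regional
macro-level variables and missing-at-random gaps), which makes every pipeline
stage testable end to end against a known truth.

## Modules

| Module | Purpose |
| --- | --- |
| `sbnet.schema` | Variable declarations: name, determinant cluster, ordered levels, micro/macro scope. |
| `sbnet.synthetic_data` | Ground-truth models, ancestral sampling, raw-field decoding, MAR missingness. |
| `sbnet.operationalize` | All derivation rules (sitting bands, PA partition, tertiles, dichotomisations, ...) and the complete-case filter. |
| `sbnet.bnlearn_core` | G² conditional-independence test, decomposable BIC score, PC-stable skeleton, restricted hill climbing. |
| `sbnet.bootstrap_averaging` | Bootstrap resampling, edge-stability table, 40%/70% thresholded averaged networks. |
| `sbnet.netstats` | Denseness, distance-to-SB, cluster mean distance, weighted betweenness, top-node ranking. |
| `sbnet.pipeline` | Stratified end-to-end orchestration (overall + 8 sex-by-age strata) and report export (GraphML, DOT, CSV, JSON). |

## CLI

```bash
# simulate a raw survey table from a random ground truth
sbnet simulate --seed 1 --n 24000 --out raw.csv --save-model truth.yaml

# derive the analysis categories and drop incomplete cases
sbnet recode --input raw.csv --out categorical.csv

# one network / bootstrap stabilities / statistics
sbnet learn --data categorical.csv --out arcs.csv
sbnet bootstrap --data categorical.csv --replicates 1000 --seed 1 --out strengths.csv
sbnet stats --strengths strengths.csv --out stats.json

# the whole analysis (overall sample + 8 sex-by-age strata)
sbnet run --seed 1 --n 24000 --replicates 50 --outdir reports/
```

`sbnet run` writes, per stratum, a GraphML network (cluster node attributes,
strength/stability edge attributes), a DOT rendering (cluster-coloured nodes,
edge width by stability class), a strength CSV and a stats JSON, plus a
summary `table1.csv` (one column per stratum) and a `manifest.json` recording
seeds and configuration.  Outputs are byte-identical for a fixed seed.

## Notes on defaults

* The learner defaults to G² at α = 0.05 with BIC scoring; test, score, α and
  the maximum conditioning-set size are configurable (`StructureConfig`).
* `RunConfig` (the pipeline) caps conditioning sets at size 1 by default so
  full-scale bootstrap runs stay fast; `bnlearn_core` defaults to size 2.
* Physical activity is excluded from the networks by default (it is collinear
  with SB); pass `--include-pa` / `RunConfig(include_pa=True)` for the
  sensitivity analysis.
* Betweenness uses edge cost `1/strength` by default; `1 - strength` is
  available via `weight_mode="one_minus"`.
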