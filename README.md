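# psnkit

Supervised patient classification with **patient similarity networks**
(PSNs). Each feature of patient data — a clinical layer, a single
variable, or a pathway's gene-expression subset — is turned into a weighted
graph whose nodes are patients and whose edges encode pairwise similarity.
The package selects the networks that are predictive for each patient
class, integrates them, and classifies held-out patients by their graph
proximity to known class members. Because every data type becomes the same
kind of object (a similarity network), heterogeneous data integrate
naturally, and the selected features are directly interpretable (e.g. "the
cell-cycle pathway network is predictive of this subtype").

It is aimed at computational biologists who want both a classifier and a
ranked, class-specific list of predictive features from multi-modal cohort
data.

## Method in brief

- **Similarity.** Single variables use the normalized similarity
  S(a,b,G) = 1 − |a−b| / (max G − min G); small layers average S over their
  variables; layers with ≥ 6 variables and pathway gene subsets use Pearson
  correlation of the patient profiles. Networks are sparsified by a weight
  cutoff (0.3), a per-node top-50 rule, and an optional global edge cap
  with orphan re-attachment.
- **Feature weighting.** For a query of class members, each network earns a
  weight from ridge regression of its pairwise edge weights onto the
  label-derived target t_ij = u_i·u_j (u the zero-mean label vector);
  non-positive weights are dropped and the system re-solved. A feature's
  **score** (0–10) counts the resampling rounds in which its weight was
  positive; features scoring ≥ 9/10 are selected per class.
- **Classification.** Each class's selected networks are averaged into one
  integrated network; label propagation f = (I + λ·L_sym)⁻¹y ranks all
  patients by similarity to the class query, and a test patient is assigned
  to the class giving its highest normalized rank. Performance is reported
  as AUROC, AUPR, and accuracy over stratified 80:20 train/test splits.
- **Interpretation.** Features consistently at the top across splits are
  combined into a single PSN; within- vs between-class shortest-path
  distances (Dijkstra, on 1 − similarity) with a one-tailed
  Wilcoxon–Mann–Whitney test quantify class separation.

See `docs/methods.md` for assumptions, parameters, and numerical details.

## Worked example

Simulate the standard two-class cohort (60 patients per class, 30 disjoint
20-gene pathways, 3 of them carrying a ±1.5 per-gene shift in the cases)
and run the full predictor with pathway-level features:

```python
from psnkit import (SimulationSpec, simulate_cohort, PredictorConfig,
                    run_predictor, integrate_top_features, class_separation,
                    build_pathway_networks, sparsify, SparsifierConfig)

expr, _, labels, sets, truth = simulate_cohort(SimulationSpec(seed=7))
cfg = PredictorConfig(n_splits=5, feature_mode="pathway", master_seed=11)
report = run_predictor([expr], labels, cfg, sets)
print(report.summary())
# {'mean_auroc': 1.0, 'sd_auroc': 0.0, 'mean_aupr': 1.0, 'sd_aupr': 0.0,
#  'mean_accuracy': 1.0, 'sd_accuracy': 0.0}

print(report.splits[0].score_table.scores.head(4))
#         case  control
# SET001    10       10
# SET002    10        9
# SET003    10       10
# SET004     6        7
```

The three planted pathways (SET001–SET003) score at or near the maximum of
10 for both classes and are selected; noise pathways such as SET004 fall
below the 9/10 threshold. Held-out classification is perfect on this
strongly separable cohort (mean AUROC 1.0 over five splits). Integrating
the features that score 10/10 in every split and measuring shortest-path
class separation:

```python
nets = [sparsify(n, SparsifierConfig()) for n in build_pathway_networks(expr, sets)]
integrated = integrate_top_features(report.score_tables(), nets)
print(class_separation(integrated, labels))
# SeparationStats(within_class_mean_distance=0.860,
#                 between_class_mean_distance=1.141,
#                 wmw_p=3.6e-104, n_within_pairs=3540,
#                 n_between_pairs=3600, n_unreachable_pairs=0)
```

Same-class patients sit significantly closer together in the integrated
network than cross-class patients (0.86 vs 1.14 mean shortest-path
distance, one-tailed WMW p ≈ 4e-104).

The same workflow is available from the shell:

```bash
psnkit simulate --out-dir cohort --seed 7
psnkit train --layer expression=cohort/expression.tsv --gmt cohort/genesets.gmt \
             --labels cohort/labels.tsv --mode pathway --n-splits 5 --seed 11 \
             --out-dir run
psnkit report --layer expression=cohort/expression.tsv --gmt cohort/genesets.gmt \
              --labels cohort/labels.tsv --scores run/feature_scores.tsv \
              --mode pathway --out-dir rep
```

`build-networks` exports the sparsified per-feature edge lists, and
`predict` classifies new patients against a selected-feature table from a
previous run.

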