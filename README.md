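# crowdome

Consensus multi-omic association networks for dominance-typed microbiome
cohorts.

The package implements an end-to-end analysis pipeline for vagino-cervical
(or similar) microbiome cohort studies, together with a synthetic cohort
generator with planted ground truth for validating every stage:

- **`crowdome.simulate`** — synthetic multi-omic cohorts: Dirichlet
  compositions partitioned into dominance-defined community types, mixed-kind
  host-factor tables, planted factor→taxon effects on the arcsine-sqrt scale,
  metadata missingness, and paired replicate cohorts sharing the same truth.
- **`crowdome.io`** — MetaPhlAn-style profile TSV reader/writer (species-rank
  extraction, percent/fraction auto-detection), metadata CSV with a JSON
  variable-kind sidecar, prevalence filtering (inclusive ≥10% boundary), and
  the arcsine-square-root compositional transform.
- **`crowdome.community`** — ≥50% dominance community typing (lexicographic
  tie-break, "diverse" fallback), centroid-linkage sample ordering, Gaussian
  likelihood-ratio group tests with pooled-t post hocs, Wilcoxon rank-sum
  comparison, and Fisher exact co-occurrence with the conditional-MLE odds
  ratio.
- **`crowdome.importance`** — per-factor prediction power: Spearman ρ between
  a factor and its out-of-fold random-forest predictions (5-fold, 500 trees,
  mtry=⌊p/3⌋ defaults), one-sided add-one permutation P (999 permutations by
  default), BH Q across the factor family.
- **`crowdome.rda`** — redundancy analysis (multivariate least squares R²,
  Ezekiel-adjusted) with greedy forward selection, Freedman–Lane permutation
  tests per step, and the double stopping rule (alpha + global adjusted R²).
- **`crowdome.network`** — the three-learner consensus network: Step-1
  preprocessing (dummy/rank coding, 70% missingness cap, central-95%-interval
  outlier masking, median imputation, near-zero-variance removal), Step-2
  learners (pairwise Spearman with BH Q, fold-averaged RF importances,
  bootstrap-aggregated lasso coefficients at a frozen cross-validated λ with
  0.632 resampling), Step-3 average-rank consensus keeping the top 5
  predictors per target gated by Spearman Q < 0.1, GraphML/TSV export, and
  two-cohort replication by Edgington-combined P values with sign agreement.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (Fisher oracle over
all small 2×2 tables, forward-RDA brute-force agreement, permutation-test
type-I calibration, Edgington Monte-Carlo check, planted-edge recovery and
replication, community-typing agreement, hand-computed BH/arcsine values).
The full suite takes ~10 minutes on one CPU; the simulation-heavy tests are
scaled down (tree/bootstrap counts) but keep the stated replicate counts.

## CLI

```sh
crowdome simulate --seed 1 --out run/sim
crowdome type --profiles run/sim/profiles.tsv --out run/typed
crowdome importance --profiles run/sim/profiles.tsv --metadata run/sim/metadata.csv \
    --n-perm 99 --out run/imp
crowdome rda --profiles run/sim/profiles.tsv --metadata run/sim/metadata.csv --out run/rda
crowdome network --profiles run/sim/profiles.tsv --metadata run/sim/metadata.csv --out run/net
crowdome replicate --edges1 run/net/edges.tsv --edges2 run/net2/edges.tsv --out run/rep
crowdome all --seed 1 --out run/full        # simulate a cohort pair + every stage
```

Each stage writes a JSON manifest (seed, config, input/output SHA-256) next
to its outputs. A YAML config can override the simulation defaults; flags
override the config.

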