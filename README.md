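# specdiff

Label-free spectral-count differential proteomics toolkit. Starting from a
protein × sample matrix of non-negative integer spectral counts and a
two-group sample design, it provides:

- **Presence filtering** — retain proteins detected in at least half the
  subjects of one group (`ceil(n/2)` for odd group sizes).
- **Spectral-index (SI) differential expression** — per protein,
  `SI = r_A·f_A − r_B·f_B` where `r` is the relative group mean abundance and
  `f` the detection fraction; `SI ∈ [−1, +1]`, `+1` for universal detection
  exclusive to the first group. Significance via a label-permutation null
  (default 10,000 permutations, 95% confidence, pooled "global" band; a
  per-protein mode is available). Small cohorts switch automatically to
  exhaustive enumeration of all label assignments.
- **Correspondence analysis** of the count table (principal coordinates,
  per-axis inertias, total inertia = χ²/N).
- **Hierarchical clustering** (default 1 − Pearson distance, average linkage,
  on log2(count+1) per-protein z-scores) and **K-medians** partitioning
  (L1 Lloyd iterations, best of restarts) with cluster-to-group accuracy
  matching.
- **Nearest-shrunken-centroid classification** with leave-one-out
  cross-validated shrinkage, two-criterion limited-signature selection
  (top discrimination scores among SI-significant proteins), a per-sample
  combined z-score, and ROC analysis (trapezoid AUC, Youden point).
- **Over-representation analysis** of a protein list against GMT annotation
  sets with permutation p-values and Benjamini–Hochberg FDR (significant:
  overlap ≥ 3 members and FDR < 5%).
- **Synthetic data** — an overdispersed (negative-binomial + dropout) count
  generator with planted differential proteins (abundance-shift and
  presence/absence archetypes) and full ground truth.

## CLI

All functionality is exposed through the `specdiff` entry point:

```bash
# synthetic dataset (counts/design/truth TSVs)
specdiff simulate --preset vap-study --seed 1 --out-prefix sim/

# stage by stage
specdiff filter  --counts sim/counts.tsv --design sim/design.tsv --out sim/filtered.tsv
specdiff diffexp --counts sim/filtered.tsv --design sim/design.tsv \
                 --n-perm 10000 --confidence 0.95 --seed 1 --out sim/differential.tsv
specdiff ca       --counts sim/filtered.tsv --out-prefix sim/ca_
specdiff hcluster --counts sim/filtered.tsv --out sim/dendrograms.json
specdiff kmedians --counts sim/filtered.tsv --k 2 --seed 1 --out sim/clusters.tsv
specdiff classify train  --counts sim/filtered.tsv --design sim/design.tsv --out sim/model.json
specdiff classify select --model sim/model.json --differential sim/differential.tsv --out sim/signature.json
specdiff classify score  --counts sim/filtered.tsv --signature sim/signature.json --out sim/scores.tsv
specdiff classify roc    --scores sim/scores.tsv --design sim/design.tsv --positive A --out sim/roc.tsv
specdiff enrich --hits hits.txt --background bg.txt --gmt sets.gmt --seed 1 --out enrichment.tsv

# or the whole pipeline from a YAML config (simulate -> filter -> diffexp ->
# ca -> hcluster -> classify -> kmedians -> enrich), with a manifest for
# byte-identical re-runs
specdiff run --config pipeline.yaml
```

A single global seed deterministically derives per-stage substream seeds, so
re-running with the same config reproduces identical result tables.

## File formats

- Count matrix: TSV, header row of sample ids, first column protein ids,
  proteins as rows. Missing detection is count 0 (no NA state).
- Design: two-column TSV `sample<TAB>group`.
- Annotation sets: standard GMT.
- Results: TSV tables at full float precision; models/signatures/configs as
  JSON; pipeline config as YAML or JSON.
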