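# netstrat — network-based pan-cancer stratification

Tumor cohorts profiled across cancer types carry sparse binary alteration
profiles: each patient harbors a handful of somatic events (copy-number
gains/losses, mutations, promoter hypermethylation) out of hundreds of
recurrent ones, and two patients driven by the same pathway often alter
*different* genes of it.  Direct clustering of such 0/1 profiles fragments
on this heterogeneity.  Network-based stratification (NBS) resolves it by
diffusing each patient's profile over a gene interaction network before
clustering, so patients hitting neighboring genes become similar.

`netstrat` implements that pipeline end to end for systems-biology
analysts, together with a synthetic cohort generator that plants the
ground truth the real data withholds:

1. **Ingestion** — binary event × sample TSVs with region-event gene
   annotations, STRING-style weighted edge lists, per-sample clinical
   tables (stage substages merged, e.g. `Stage IIB → Stage II`), optional
   expression matrices.
2. **Preprocessing** — events expanded to member genes with per-gene
   merging, columns aligned to the network's largest connected component.
3. **Smoothing** — random walk with restart,
   `F_{t+1} = α F_t W + (1−α) F₀`, with fixed point
   `F = (1−α) F₀ (I − αW)^{-1}`, then quantile normalization across
   samples.
4. **Clustering** — graph-regularized NMF,
   `min ‖Fᵀ − WH‖²_F + λ·tr(Wᵀ L W)` over `W, H ≥ 0` with a kNN Laplacian
   of the propagation kernel, fitted by multiplicative updates under
   consensus resampling; the co-clustering matrix is cut by average-linkage
   hierarchical clustering into k subgroups (k = 3…15).
5. **Characterization** — chi-squared cancer-type enrichment (BH-corrected),
   Kaplan-Meier / log-rank survival contrasts, Fisher r×c stage/grade
   tests, SAM statistics `d = (x̄_in − x̄_out)/(s + s₀)` with permutation
   FDR on the smoothed scores (selection at d > 15, q < 0.05), induced
   subnetwork modules, and Wilcoxon expression contrasts.
6. **Robustness** — subsample-and-reclassify stability scored by adjusted
   Rand index and Hungarian best-match accuracy.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
cohort (6 planted 25-gene modules, 6 subgroups × 150 samples, 8 expected
alterations per sample of which 80 % hit the subgroup's own module):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_smooth_profiles.py
python analysis/03_consensus_stratify.py
python analysis/04_clinical_association.py
python analysis/05_influence_modules.py
python analysis/06_robustness_stability.py
```

`03_consensus_stratify.py` prints the agreement of every stratification
with the planted truth — the planted subgroup count attains the maximum:

```
agreement with planted truth (adjusted Rand index):
  k=3: ARI 0.476
  k=4: ARI 0.681
  k=5: ARI 0.818
  k=6: ARI 0.997
  k=7: ARI 0.939
  k=8: ARI 0.878
  k=9: ARI 0.829
```

`04_clinical_association.py` then recovers the planted clinical structure
(each subgroup enriched in one pseudo cancer type, display p floored at
1e-10 as in the enrichment heat maps this mimics):

```
strongest subgroup enrichments (chi-squared, BH q):
  subgroup 1 x T6: 137/149 samples, q = 4.11e-167 (display p 1.0e-10)
  subgroup 4 x T4: 142/150 samples, q = 7.45e-163 (display p 1.0e-10)
  ...
log-rank survival contrasts with p < 0.05: 14/34
```

and `05_influence_modules.py` recovers the planted modules as
subgroup-specific influenced gene sets with zero pairwise overlap:

```
  subgroup 1: 22 genes in 1 modules; 22 with expression change (q < 0.05)
  ...
pairwise gene-set overlap: max 0 genes (mean 0.00)
```

The same pipeline runs from a single YAML config via the CLI
(`netstrat all --config config.yaml --outdir out --seed 0`), stage by
stage (`simulate`, `preprocess`, `smooth`, `cluster`, `enrich`,
`survival`, `influence`, `robustness`), on real TSV inputs declared under
an `inputs:` block.

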