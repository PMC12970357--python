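# wmhpheno

Spatial phenotyping of white-matter hyperintensities (WMH) from 36-region
"bullseye" representations: stability-selected clustering of lesion
distribution patterns, risk-factor association via centroid proximity, and
longitudinal progression labelling and prediction. A synthetic-cohort
generator makes the whole pipeline runnable and testable without any
restricted imaging data.

## What is in here

| Module | Purpose |
| --- | --- |
| `wmhpheno.synthetic` | Synthetic cohorts (5-component Dirichlet spatial mixture, log-normal burdens, cluster-correlated risk factors, follow-up scans) and geometric phantoms |
| `wmhpheno.bullseye` | Laplace-equation depth field on the white-matter domain, equidistant layer binning, per-(lobe, layer) lesion volumetry, NIfTI I/O |
| `wmhpheno.features` | ICV normalisation, reference-ICV rescaling, relative regional distributions, sqrt + min-max feature transform with train-derived parameters |
| `wmhpheno.engines` | k-means, mini-batch k-means, Gaussian mixture (scikit-learn) and an in-repo subspace k-means; uniform fit/assign contract with plugin registry |
| `wmhpheno.stability` | Bootstrap co-membership Jaccard stability, optimal-k selection (largest k with stability > 0.90), stable-centroid estimation with burden ordering |
| `wmhpheno.association` | Centroid-proximity OLS per (risk factor, cluster) with [0,1] predictor scaling and Benjamini-Hochberg correction |
| `wmhpheno.progression` | Annualised-change labelling at 250 mm³/year, group comparisons, predictor sets (RF/WMHV/RWMHV/distance/clusters/PCV and unions), gradient-boosted prediction with balanced accuracy, bootstrap CIs and McNemar tests |
| `wmhpheno.workflows` | `run_phenotyping`, `run_stratified`, `run_transitions` composite workflows and the `RunConfig` defaults |
| `wmhpheno.cli` | `wmhpheno` command-line interface |

## CLI quick start

```bash
# synthetic longitudinal cohort of 2000 participants
wmhpheno simulate --n 2000 --seed 1 --out cohort.tsv

# stability-selected clustering (writes transform/model/profile JSON + TSV)
wmhpheno phenotype --table cohort.tsv --out artifacts/

# risk-factor associations with BH correction
wmhpheno associate --table cohort.tsv --artifacts artifacts/ --out assoc.tsv

# progression prediction report over predictor sets
wmhpheno progress --table cohort.tsv \
    --model artifacts/selected_model.json \
    --transform artifacts/feature_transform.json \
    --sets RF,WMHV,RWMHV,distance,RWMHV+PCV+RF --seed 7 --out report.json

# 18-30-month transition analysis under the baseline model
wmhpheno transitions --table cohort.tsv --artifacts artifacts/ \
    --out transitions.json

# sensitivity re-clustering by volume bands (0-4, 4-8 mL) and age 67-72
wmhpheno stratify --table cohort.tsv --out strata/
```

Bullseye mapping of label volumes (NIfTI) to regional volumes:

```bash
wmhpheno map --wmh wmh.nii --lobes lobes.nii --wm wm.nii \
    --inner ventricles.nii --outer cortex.nii --out regions.tsv
```

Region columns are named `<lobe>_<layer>` with lobes `frontal_l, frontal_r,
parietal_l, parietal_r, occipital_l, occipital_r, temporal_l, temporal_r,
bgit` and layers 1 (periventricular) to 4 (juxtacortical).

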