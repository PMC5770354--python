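# qsarflow

An automated QSAR (quantitative structure–activity relationship) regression
pipeline for bioactivity modeling: from a raw compound–activity table to an
externally validated model with an applicability domain, with every
intermediate artifact persisted. It is aimed at medicinal chemists and
cheminformaticians who want a standardized, reproducible protocol for
building potency-prediction models without hand-tuning each step.

## What it does

Given compounds with measured activities (Ki, Kd, IC50, EC50, AC50 in nM)
— from a CSV/SMILES/SDF file, a precomputed feature table, or a
ChEMBL-style REST payload — the pipeline runs:

1. **Curation** — keep one activity type, drop missing/non-positive values,
   desalt to the largest organic fragment, deduplicate by canonical
   structure (most recent year wins), with a reconciling per-rule log.
2. **Featurization** — the full RDKit physicochemical descriptor list plus
   any of nine fingerprint types (Morgan, FeatMorgan, AtomPair, Torsion,
   RDKit path, Avalon, Layered, MACCS, Pattern), merged into one matrix
   with constant columns removed.
3. **Scaling & partitioning** — activities are mapped onto [0, 1] by the
   piecewise log transform

       sp(v) = 0                      if v ≥ 10,000 nM
       sp(v) = (4 − log10 v) / 4      if 1 < v < 10,000
       sp(v) = 1                      if v ≤ 1 nM

   the data are split 75/25 into a training set and an Independent
   Validation Set (IVS), and features are min–max scaled,
   x′ = (x − min x)/(max x − min x), with parameters fitted on the
   training rows only.
4. **Modelability gate (MODI)** — the leave-one-out k-nearest-neighbour
   coefficient of determination, 1 − Σ(yᵢ − ŷᵢ)²/Σ(yᵢ − ȳ)², on the scaled
   training set (k = 3 and 5). A score ≤ 0.45 means the dataset is
   unlikely to yield a predictive model; the pipeline halts (or warns).
5. **Feature ranking** — Random-Forest permutation importance: for each
   tree, the increase in out-of-bag MSE when one column is permuted;
   VI(Xⱼ) = Σₜ VI⁽ᵗ⁾(Xⱼ)/ntree ("unscaled") and the z-score
   Zⱼ = VI(Xⱼ)/(σ̂/√ntree) ("scaled"), each averaged over nfold repeated
   forest fits. Both rankings are produced by default.
6. **Stepwise selection** — ranked features are added cumulatively to an
   SVM regressor (RBF kernel) evaluated on a fixed internal 75/25 split of
   the training set; the prefix with minimal internal-test RMSE is the
   selected feature set (SF).
7. **Validation & applicability domain** — the full-feature model and the
   SF-model are fitted on the whole training partition and scored with
   PVE = 1 − Σ(yᵢ − ŷᵢ)²/Σ(yᵢ − ȳ)² and RMSE = √(Σ(yᵢ − ŷᵢ)²/N) on the
   internal test replay and on the IVS. IVS compounds whose Euclidean
   nearest-training-neighbour distance exceeds mean + Z·std of the
   training NN distances are flagged outside the applicability domain
   (flagged, never removed).

Model bundles (learner, feature subset, scaler parameters) are persisted
and can re-predict new compounds — with AD flags — via
`qsarflow predict` or `qsarflow.predict_external`.

## Worked example

Generate a synthetic benchmark (300 compounds, 200 mixed
descriptor/fingerprint-like features, 10 of them truly driving a noisy
nonlinear response) and run the whole pipeline:

```bash
qsarflow simulate --kind regression --n 300 --p 200 --n-informative 10 \
    --seed 1 --out bench.csv
qsarflow run --mode customized_features --input-path bench.csv \
    --activity-prescaled --nfold 5 --ntree 200 --step-size 4 \
    --seed 1 --workdir run
```

The run directory then contains `modi.json`:

```
MODI(k=3) = 0.959, MODI(k=5) = 0.964   ->  gate passed (threshold 0.45)
```

and `validation_report.csv`:

```
      model           set   pve  rmse  n_features
  sf_scaled internal_test 0.970 0.052           4
  sf_scaled           ivs 0.959 0.058           4
sf_unscaled internal_test 0.971 0.051           8
sf_unscaled           ivs 0.959 0.058           8
       full internal_test 0.967 0.054         200
       full           ivs 0.950 0.064         200
```

Read: the dataset is comfortably modelable (MODI ≫ 0.45); stepwise
selection compressed 200 features to 4–8 (all drawn from the planted
informative set) and the selected-feature models predict the held-out IVS
slightly better (RMSE 0.058 vs 0.064; PVE 0.959 vs 0.950) than the model
using every feature — the expected benefit of discarding noise features.
`ad_report.csv` flags the IVS compounds outside each model's Euclidean
applicability domain.

The same `run` command handles real data: `--mode customized_structures`
with a CSV of `compound_id,smiles,activity_type,activity_value[,year]`,
or `--mode fully_automated` with a UniProt accession and a ChEMBL-style
activity endpoint (or a saved JSON payload).

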