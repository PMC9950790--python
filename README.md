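# synergyscreen

A machine-learning screen for synergistic small-molecule drug combinations,
built for the setting where a well-curated set of known combination drugs
(e.g. FDA-approved combinations) is used to rank untested pairs — such as
traditional-Chinese-medicine (TCM) ingredients paired with approved Western
drugs — and the top-ranked pairs are then evaluated in vitro with the
Chou–Talalay combination index.

## What it does

1. **Pair featurization.** For a drug pair (d_A, d_B) with binary molecular
   fingerprints, ADME descriptor vectors and protein-target sets, the package
   computes 16 features:
   - *S*_FP: Tanimoto fingerprint similarity, A·B / (‖A‖² + ‖B‖² − A·B);
   - *S*_ADME: Euclidean distance of min–max-normalized ADME vectors;
   - *S*_Seq{min,max,med,mean}: aggregates over all target cross-pairs of
     normalized Smith–Waterman similarity sw(a,b)/√(sw(a,a)·sw(b,b));
   - *S*_GO{min,max,med,mean}: gene-level GO functional similarity (Wang
     graph-based term similarity, best-match-average per target pair);
   - *S*_Pathway: cosine similarity of binary enriched-pathway membership
     vectors (hypergeometric p < 0.05 and BH q < 0.05 define the pathway
     universe);
   - *S*_PPI{min,max,med,mean}: σ(d) = 1/(1+e^(−d)) of shortest-path
     distances between the target sets on a protein–protein-interaction
     network, and *S*_np = S_PPImean(A,B) − [S_PPImean(A,A)+S_PPImean(B,B)]/2,
     a separation-style network proximity.
2. **Feature screening.** Welch t and Mann–Whitney U tests per feature, plus
   random-forest recursive feature elimination repeated over R resampled
   training sets; features selected in ≥ 70% of resamples are retained.
3. **Resampled imbalanced ensemble.** R training sets, each all positives +
   5× negatives sampled without replacement; one classifier per set (random
   forest with 300 trees by default; k-NN, naive Bayes, RBF-SVM, AdaBoost
   pluggable), evaluated by stratified repeated k-fold CV (precision, recall,
   accuracy, F1, AUROC, AUPRC).
4. **Vote ranking.** Candidates (the TCM × Western cross product) are scored
   by the number of members voting positive; with R = 1000, bins >500,
   100–500, 1–100, 0 and a strict >700 selection threshold.
5. **Synergy evaluation.** Median-effect fits fa/fu = (D/Dm)^m per agent,
   dose inversion Dx = Dm(fa/fu)^(1/m), and the combination index
   CI = D_A/(D_A)_x + D_B/(D_B)_x (<1 synergy, =1 additive, >1 antagonism).

A synthetic-data module generates a complete toy universe (sparse
fingerprints, correlated ADME slots, random sequences, a GO DAG, pathway
sets, a preferential-attachment PPI graph) with labels planted by a logistic
model on true pair features, and median-effect dose–response data with known
(m, Dm) and known CI — so the whole pipeline is testable offline.

## Worked example

```python
from synergyscreen import (RunConfig, UniverseFeaturizer, generate_universe,
                           plant_labels, train_resampled_ensemble,
                           screen_features, score_candidates, FEATURE_NAMES)
from synergyscreen.synthetic_data import UniverseSpec, PlantedLabelModel
from synergyscreen.pipeline import run_synthetic_pipeline

res = run_synthetic_pipeline(master_seed=1)
print("positives:", len(res.positives), "negatives:", len(res.negatives))
print("features kept:", res.screen.selected_features)
print("mean CV AUROC:", round(res.ensemble.mean_cv_metrics().mean["auroc"], 3))
```

prints

```
positives: 16 negatives: 174
features kept: ['S_Pathway', 'S_np']
mean CV AUROC: 0.944
```

i.e. on a 20-drug toy universe with the combination signal planted on
pathway similarity and network proximity, the resampled RFE screen retains
exactly the two planted features and the 50-member forest ensemble separates
combinations from non-combinations with mean cross-validated AUROC 0.944.

Synergy math on simulated curves:

```python
from synergyscreen import fit_median_effect, combination_index, dose_for_effect
from synergyscreen.synthetic_data import simulate_dose_response

fit = fit_median_effect(simulate_dose_response(
    m=1.0, dm=10.0, doses=[1, 10, 100], noise_sd=0.0, seed=0, agent_id="a"))
print(fit.m, fit.dm)          # 1.0 10.0 (exact recovery)
print(dose_for_effect(fit, 0.8))   # 40.0  = 10 * (0.8/0.2)^1
```

There is also a CLI mirroring the stages:

```sh
synergyscreen simulate --out-dir fixture --seed 1
synergyscreen featurize --drug-table fixture/drugs.tsv ... --pairs pairs.tsv --out feats.tsv
synergyscreen screen --features feats.tsv --out screen.tsv
synergyscreen train --features feats.tsv --out-dir ens --metrics-out metrics.tsv
synergyscreen predict --ensemble-dir ens --candidates cands.tsv --out votes.tsv
synergyscreen synergy --single single.csv --combos combos.csv \
    --fits-out fits.tsv --ci-out ci.tsv
```

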