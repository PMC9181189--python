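# percepsim

Predicting whether a panel of chemistry experts would judge a pair of
molecules **similar**.

Regulatory assessment of orphan-drug applications, and many
drug-design decisions, hinge on a subjective question: *would experts
call these two molecules similar?*  `percepsim` turns that question
into a calibrated probability.  It featurizes a molecular pair with

* **tXT** — a 2D fingerprint Tanimoto coefficient, `|A∩B| / |A∪B|`
  over path-fingerprint bit sets, in [0, 1];
* **tCS** — a 3D **TanimotoCombo**: the sum of a Gaussian shape
  Tanimoto and a pharmacophore "color" Tanimoto from the best rigid
  alignment over conformer ensembles, in [0, 2];

and maps features to the expected fraction of experts voting
"similar" (p<sub>xp</sub>) through logistic perception models

```
y = ω₀ + ω₁·tᵢ                 (single feature, tᵢ = tXT or tCS)
y = ω₀ + ω₁·tXT + ω₂·tCS       (double feature)
p̂xp = e^y / (1 + e^y)
```

A pair is labeled *similar* when p̂xp ≥ 0.5 (the majority-vote
convention).  Bundled default models carry survey-calibrated
coefficients (single-feature tXT model: ω₀ = −4.860, ω₁ = 8.449).
The package also ships the survey-design machinery itself:
buffer-zone classification of pairs into the four calculated-similarity
subsets (*sim2D,sim3D* / *sim2D,dis3D* / *dis2D,sim3D* /
*dis2D,dis3D*; 2D similar at tXT ≥ 0.7, dissimilar at ≤ 0.65;
3D similar at tCS ≥ 1.4, dissimilar at ≤ 1.3), stratified random
selection of survey pairs, model fitting (L1-regularized logistic
regression), evaluation (N_correct, ROC AUC, per-subset error
breakdown), and synthetic fixtures for all of it.

The 3D scores come from an open Gaussian-overlap implementation
(soft-sphere atom Gaussians, principal-axes starting poses,
derivative-free rigid optimization); they are methodologically
comparable to, but not bit-compatible with, commercial shape-overlay
tools — see `docs/methods.md`.

## Worked example

Ethyl vs propyl homologs of a phenoxy-acetic acid — a pair most
chemists would call similar:

```bash
$ percepsim tanimoto2d --smiles-a "CCOc1ccc(CC(=O)O)cc1" \
                       --smiles-b "CCCOc1ccc(CC(=O)O)cc1"
0.9495

$ percepsim predict --smiles-a "CCOc1ccc(CC(=O)O)cc1" \
                    --smiles-b "CCCOc1ccc(CC(=O)O)cc1" --model default_tXT
p_similar=0.9594 label=similar
```

The fingerprint Tanimoto is 0.9495; the calibrated single-feature
model turns it into a 96% predicted expert consensus.  Inverting the
same model gives the feature value at any consensus level:

```bash
$ percepsim thresholds --model default_tXT --prob 0.5
tXT=0.5752
$ percepsim thresholds --model default_tXT --prob 0.95
tXT=0.9237
```

i.e. the model predicts an expert majority above tXT ≈ 0.575 and a
95% consensus above tXT ≈ 0.924.  A 3D comparison of a naphthalene /
quinoline isostere pair (2D-dissimilar, 3D-similar):

```bash
$ percepsim tanimoto3d --smiles-a "Cc1ccc2ccccc2c1" \
                       --smiles-b "Cc1ccc2ncccc2c1" --max-confs 2
shape=0.9900 color=0.6714 tCS=1.6615
```

Synthetic survey design end-to-end:

```bash
percepsim synth pool --per-subset 26 --seed 42 --out pool.csv
percepsim select --table pool.csv --per-subset 25 --seed 42 --out survey.csv
percepsim synth votes --omega0 -4 --omega1 8 --n-pairs 200 --out votes.csv
percepsim fit --table votes.csv --features tXT --mode per_vote --out model.json
percepsim evaluate --table votes.csv --model model.json
```

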