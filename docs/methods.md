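# Methods

## The perception model

The quantity modeled is p<sub>xp</sub>, the fraction of a panel of
chemistry experts who judge a molecular pair "similar".  Its logit
y = log(p<sub>xp</sub>/(1−p<sub>xp</sub>)) is taken to be linear in one
or two calculated similarity features: the 2D fingerprint Tanimoto tXT
∈ [0, 1] and/or the 3D TanimotoCombo tCS ∈ [0, 2].  Predicted
probabilities come from the inverse logit, and a pair is labeled
*similar* at p̂ ≥ 0.5, matching the "at least 50% of experts"
majority convention; the tie at exactly 0.5 deliberately falls on the
similar side for the same reason.

Assumptions worth stating: the panel is treated as exchangeable (every
expert an independent draw from the same vote probability), the
features are assumed to carry all pair information relevant to the
panel, and the logit is assumed linear over the whole feature range.
None of these are exactly true of real panels; they are what make the
model a two- or three-parameter calibration rather than a behavioral
theory.

### Fitting

Models are fitted as L1-regularized logistic regressions (liblinear
coordinate descent, tolerance 1e-8, max 10⁴ iterations).  The
customary regularization setting "λ = 1" maps to inverse strength
C = 1.0; both are recorded in the model metadata.  Two fit modes:

* `binary_label` (default) — each pair contributes one observation
  labeled by the expert majority (p<sub>xp</sub> ≥ 0.5).  This is the
  standard workflow for survey calibration and what the bundled
  default coefficients correspond to.
* `per_vote` — each pair contributes its n_similar "yes" and
  n_total − n_similar "no" votes as weighted observations.  This is
  the consistent maximum-likelihood estimator of the vote-level law.

The distinction matters for simulation studies: when votes are drawn
as Binomial(n, σ(ω₀ + ω₁t)), the *majority label* follows a strictly
steeper curve than σ (a binomial majority sharpens the underlying
probability), so `binary_label` fits recover systematically larger
slopes than the generating ω₁.  Parameter-recovery tests therefore use
`per_vote`, which converges to the generating coefficients; with ~21
votes per pair the effective sample size is large and the L1 penalty
is negligible.

Empirical logits of boundary fractions (p<sub>xp</sub> ∈ {0, 1}) are
clamped by 1/(2·n_total) — the usual empirical-logit correction —
with a warning, since the logit is undefined at the boundary.

### Threshold inversion

For a single-feature model, the feature value at which the predicted
consensus equals p is the closed form t = (logit(p) − ω₀)/ω₁, and
`predict` reproduces p at that t to better than 1e-9.  Note that
consensus thresholds published alongside survey-calibrated models are
not always plain inversions of the fitted equation (confidence-band
constructions give more conservative values); this package implements
only the documented closed form and makes no attempt to guess another
rule.

## 2D featurization

The default fingerprint is RDKit's hashed path fingerprint (maximum
path length 7, 2048 bits); Morgan (radius 2) and MACCS are also
registered, and any callable producing an explicit bit vector can be
added.  The reference scheme used to calibrate the bundled models (a
Java-ecosystem "extended" path fingerprint) has no open Python port,
and Tanimoto values are not transferable across fingerprint schemes —
so when reproducing published coefficient tables the deposited tXT
values are the input of record, and recomputed fingerprints are for
new pairs only.  Two empty fingerprints score 0.0 ("no evidence of
similarity") with a warning rather than the equally defensible 1.0.

## 3D featurization

### Shape

Each heavy atom is a spherical Gaussian p·exp(−α r²) with fixed height
p = 2.70 and α = κ/σ² where σ is the element van-der-Waals radius and
κ = π(3p/4π)^(2/3) ≈ 2.344 makes the Gaussian's volume integral equal
the hard-sphere volume — the classic soft-sphere description of
molecular volume.  Molecular overlap is the first-order (pairwise) sum
of two-center Gaussian product integrals, which is exactly the volume
integral of the product of the two molecular densities; the test suite
checks it against an independent 0.1 Å grid quadrature.  Higher-order
intersection corrections are not applied: for Tanimoto *ratios* of
drug-sized molecules the first-order expansion is the standard
compromise.  Hydrogens are excluded throughout.

### Color

Pharmacophore features — donor, acceptor, cation, anion, hydrophobe,
aromatic ring — are detected with RDKit's built-in chemical feature
definitions and each placed as a Gaussian of radius 1.0 Å at the
feature centroid (same functional form as atoms).  Overlap is
accumulated only between features of identical type.  Shape and color
overlaps are turned into Tanimotos O_AB/(O_AA + O_BB − O_AB) and
summed into the TanimotoCombo tCS ∈ [0, 2].  A molecule with no
detected features gets color Tanimoto 0 and the result is flagged.

### Alignment

For each conformer pair the molecules are centered on their heavy-atom
centroids; the four proper principal-axes orientations of the moving
molecule serve as starting poses; from each start the six rigid
parameters (rotation vector + translation) are optimized with Powell's
derivative-free method (xtol 1e-4, ftol 1e-6) to maximize the shape
overlap volume, and both Tanimotos are scored at the optimum.  The
reported result is the maximum-tCS pose over all conformer pairs and
starts.  Two consequences are enforced by tests: the score is
invariant (within 1e-3) to arbitrary rigid pre-transformations of
either input, and enlarging a conformer ensemble can never decrease
the reported best score.  Scoring a rigid conformer against an
identical copy attains the upper bound tCS = 2 within 1e-3.

### Conformers

Ensembles come from RDKit's ETKDG distance-geometry sampler (explicit
seed, default 42; up to 200 conformers by default) with MMFF94
refinement and a greedy symmetry-aware duplicate prune at 0.5 Å
heavy-atom RMSD.  The embedder's own pruning is disabled because it is
not symmetry-aware and collapses distinct torsional minima: an
ideal-geometry torsion enumeration for n-butane puts anti and gauche
rotamers 0.71 Å apart (above the 0.5 Å prune) while gauche⁺/gauche⁻
are mirror-related at 0.46 Å (below it), so the pruned butane ensemble
must contain exactly the two distinct rotamer classes — which the
implementation reproduces.

tCS values from this implementation are *methodologically* comparable
to commercial shape-overlay scores (same score definition, same
[0, 2] range, same best-over-ensembles protocol) but not numerically
interchangeable with them; published tables calibrated on a commercial
tool's scores should be reproduced from deposited feature values.

## Subset design

A pair is 2D-similar at tXT ≥ 0.70, 2D-dissimilar at tXT ≤ 0.65,
3D-similar at tCS ≥ 1.40, 3D-dissimilar at tCS ≤ 1.30; the open
intervals (0.65, 0.70) and (1.30, 1.40) are buffer bands whose members
stay UNASSIGNED, so threshold-straddling pairs cannot flip subsets
under tiny numerical changes.  Boundary equality belongs to the
labeled side, following the ≥/≤ conventions above.  Stratified
selection draws the requested quota uniformly at random within each of
the four subsets under an explicit seed; no secondary stratification
(e.g. by biological target) is applied, since the selection rule is
otherwise unspecified.

## Evaluation

N_correct counts pairs whose predicted label matches the expert
majority label; ROC AUC is the Mann–Whitney (midrank-tie) estimator,
verified in tests against an exhaustive positive–negative
concordance count on inputs of up to 20 items.  Truth at
p<sub>xp</sub> exactly 0.5 counts as similar.  AUC is refused (rather
than silently returned) when the truth labels contain one class.

## Synthetic data

The vote simulator draws features uniformly over their domains and
vote counts as Binomial(votes_per_pair, σ(ω₀ + ω·t)); 21 votes per
pair is the default, a typical per-pair assessment count for an online
expert survey.  It emulates panel exchangeability exactly — which is
precisely why passing recovery tests show estimator correctness, not
robustness to real-panel effects such as expert heterogeneity,
presentation-order bias, or correlated votes.

The pair-pool generator stands in for a large database extraction.
It composes real, parseable drug-like SMILES from a bundled
scaffold/substituent library, featurizes every candidate with the
package's own tXT and tCS, and rejection-samples against the
classifier until each subset's quota fills (candidates that can never
match on the deterministic 2D feature are pruned after one
evaluation; 3D-rejected candidates are retried with fresh conformer
seeds).  Chemistry per subset: identical/homologous molecules on
rigid fused aromatics (*sim2D,sim3D*); flexible close analogues and
regioisomers (*sim2D,dis3D*); heteroatom-swapped ring isosteres
(*dis2D,sim3D*); size- and functionality-mismatched pairs
(*dis2D,dis3D*).  Screening uses one conformer per molecule — a
deliberately small budget that keeps a 25-per-subset pool under a
minute of CPU and is itself the source of genuine conformational
mismatch for the flexible 2D-similar family.  The pool therefore
spans the four subsets by construction but does not mimic
bioactivity filtering or target-specific chemistry.

## Problem sizes used in the checks

Parameter recovery is exercised at 100 and 1000 pairs (with a
200-resample bootstrap interval at 1000); pool generation at 3 and 26
pairs per subset; conformer determinism at 200 requested conformers
for n-hexane; overlap quadrature on 2–3-atom toy shapes.  These sizes
were chosen so the full property surface runs comfortably on a laptop
CPU while leaving each statistical check enough power to fail visibly
if the implementation drifts.

## Known limitations

* tCS is an open reimplementation, not a bit-compatible replacement
  for commercial shape/color scoring; color feature definitions in
  particular differ in detail.
* The default 2D scheme differs from the fingerprint used to
  calibrate the bundled coefficients; predictions for new pairs mix a
  calibrated model with a related-but-different feature and should be
  treated as approximate.
* Alignment optimizes shape overlap only; a pose that trades a little
  shape for much color is found only through the multi-start search,
  not the local optimizer.
* Conformer ensembles from distance geometry under-sample macrocycle
  and ring-pucker diversity.
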