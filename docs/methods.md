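# Methods

This note documents the models and procedures implemented in `purscreen`,
the parameter choices that matter, and what the synthetic benchmark does and
does not demonstrate.

## Structure standardization and curation

The standardization workflow applies, in a fixed order and exactly once:
parse (SMILES or MOL block); drop enhanced-stereo groups and unknown (wavy)
bond stereo, which carry no single-structure meaning for deduplication;
downgrade dative bonds to single; sanitize, flagging `ERR_VALENCE` on
valence violations and `PARSE_FAIL` on anything unparseable; clear isotope
labels; keep the largest component of multicomponent inputs (flag
`MULTICOMPONENT`); neutralize protonation-state charges. Neutralization
covers simple acid/base protonation states (RDKit's uncharger); a +1
nitrogen or phosphorus with four heavy-atom neighbors is treated as a
permanent structural cation and left intact, while any other residual net
charge is flagged `ERR_CHARGE`. "Erroneous" valences and charges are thus
defined by the toolkit's valence model. The workflow is idempotent:
re-standardizing its own output changes nothing and raises no new flags.

Error-flagged records (`PARSE_FAIL`, `ERR_VALENCE`, `ERR_CHARGE`) are
excluded from the curated dataset but retained in the curation log, as are
censored activities (qualifiers `>`/`<`, which have no defined pEC50) and
records lacking an activity. Counts therefore always reconcile:
inputs = Σ merged members + excluded log entries.

Deduplication keys on the InChIKey of the standardized structure, so salt
forms, isotopologues, and charge states of one parent collapse together;
this is why standardization precedes deduplication. Member activities,
already on the pEC50 = −log10(molar) scale, are merged by arithmetic mean
(averaging log-potencies is the geometric mean of EC50s, the convention for
potency data). Every merge logs member SMILES, activities and indices.

Labels: active ⇔ pEC50 ≥ −log10(cutoff). The cutoff is a configurable molar
value, default 5 µM (pEC50 5.301). Boundary equality counts as active —
"an EC50 of 5 µM at a 5 µM cutoff" is conventionally included. Lower EC50 =
more potent = active; loosening the cutoff can only add actives (a tested
monotonicity invariant).

## Fingerprints

Model descriptors are hashed circular (Morgan) fingerprints of radius 3 —
the ECFP6 convention (diameter 6) — at 2048 bits, the field-standard
length; both are configurable. Analog similarity uses the 166 public MACCS
structural keys (stored 0-based) with Tanimoto similarity; the empty-empty
case is defined as 0 to stay within [0, 1]. Different MACCS implementations
disagree on a few key definitions, which can shift reported similarities by
about ±0.01; similarities are conventionally reported at two decimals.

## Classifier panel and evaluation

The eight families use their library-default hyperparameters (none are
tuned), with all stochastic components seeded: DL is a small feed-forward
network (two rectified hidden layers of 64 and 32 units, sigmoid output,
up to 500 iterations), ada/bnb/kNN/lreg/rf/svc are the scikit-learn
defaults (logistic regression capped at 1000 iterations), xgb is XGBoost
with log-loss. Margin-only SVC scores pass through a logistic link
1/(1+e^(−margin)) so every model emits a [0, 1] score; the link is strictly
monotone, so rankings and AUC are unaffected.

Cross-validation is stratified fivefold (per-fold class counts within ±1 of
perfect stratification, enforced and tested over seed sweeps). Out-of-fold
scores are pooled and a single metric table computed on the pool — pooling
rather than per-fold averaging is stated here so results can be compared
either way. The deep-learning path can also be evaluated on a stratified
holdout of ceil(fraction × n) records (20% of 244 → 49), trained on the
remainder. Predicted labels use a 0.5 score threshold (configurable).

Metrics are computed in closed form from the pooled confusion matrix;
AUC comes from the ranks of the continuous scores. Zero-denominator cases
(precision/F1 with no predicted positives, MCC/κ with an empty margin) are
defined as 0. The metric implementations are verified against independent
re-evaluations (scikit-learn's scorers on reconstructed label vectors;
brute-force pair counting for AUC) to 1e-12 on 1000 random confusion
matrices.

## Consensus screening

"Consensus" is implemented as the unweighted mean of the eight per-model
scores, with a majority-vote count (models ≥ 0.5) recorded alongside so
either aggregation can be read off. Library members pass through the same
standardization as training data; failures are logged and skipped, never
silently dropped. Ranking is by mean score descending with ties broken by
ascending InChIKey for reproducibility. The mean is bounded by the per-model
extremes, and a molecule dominated on every model can never outrank its
dominator — both tested properties.

## Dose–response and fluorescence reduction

The three-parameter logistic is the common inhibition form with unit Hill
slope: response = bottom + (top − bottom)/(1 + 10^(x − logIC50)),
x = log10(concentration in molar); bottom, top, and logIC50 are free. (The
alternative "three-parameter" convention fixes bottom = 0 and frees the
slope; the unit-slope form is adopted because the fitted curves here are
single-site inhibition curves.) Initialization takes bottom/top from the
response extrema and logIC50 from the concentration nearest the
half-maximal response. Fits are unweighted by default; a `relative`
weighting option (σᵢ ∝ |yᵢ|, i.e. 1/Y² weights) is provided for data whose
error is a constant percentage of signal, the usual behavior of
fluorescence intensities. A fit reports `converged=False` when the
optimizer fails, the fitted span is essentially flat (< 5% of the response
scale), or the midpoint lands more than a decade outside the tested
concentration range — in all three cases the data do not determine an IC50.

Percent inhibition corrects both sample and control mean fluorescence
intensities by subtracting cell autofluorescence before forming
100 × (1 − (S − A)/(C − A)); values < 0 (enhancement) or > 100 are
preserved. Percent activation is 100 × (R − baseline)/(full − baseline)
with the full-agonist response defining 100%. Both are invariant under a
common affine rescaling of all fluorescence inputs.

## Synthetic benchmark

The generator emulates a curated agonist export at desk scale: 244 records
by default with motif probability 139/244, matching the class balance the
pipeline is designed around. Molecules are assembled from a 9-scaffold ×
15-decoration × (14 decoy | 5 motif) fragment vocabulary; actives embed an
indole moiety, so the activity signal is a substructure that circular
fingerprints genuinely encode — mirroring how a congeneric agonist series
carries its SAR — rather than a label painted onto arbitrary structures.
Motif carriers draw pEC50 ~ N(6.8, 0.45) (≈16 nM–1 µM), others
N(3.9, 0.45) (≈6 µM–400 µM): both classes sit ≳3 standard deviations from
the 5 µM threshold, so the motif and the binarized label agree for ≥ 99% of
clean records, with rare tail draws providing a realistic trickle of label
noise.

Corruption rates are fixed defaults chosen to resemble a real public-data
export while leaving the majority of records clean: 6% duplicates
(re-reported with pEC50 jitter of SD 0.15), 8% salt forms, 5% protonation
variants, 2% isotope-labeled forms, 3% malformed strings, 4% censored
activities. Screening libraries are generated clean: motif-free decoys
(verified by substructure match) with planted motif carriers at random
positions. Dose–response curves are simulated from the logistic model with
either additive or constant-CV ("proportional") Gaussian noise.

What passing these benchmarks shows: the plumbing is correct end to end —
standardization collapses variant forms onto one InChIKey, averaging and
labeling are exact, stratification balances folds, models recover a
learnable signal (CV AUC ≥ 0.9, and ≈ 0.5 when labels are permuted), the
consensus enriches planted actives into the top of a ranked library, and
the curve fitter recovers its generator's parameters (median IC50 error
≈ 4% at 5% constant-CV noise with matched weighting; exact at zero noise).
What it does not show: performance on real medicinal-chemistry data, where
activity is not a single substructure, class boundaries are soft, and
near-duplicate analog series inflate cross-validation estimates — the
near-perfect synthetic metric tables should not be read as expected
real-data performance.

Problem sizes throughout the test suite (n = 244 datasets, 505-member
libraries, 100-curve simulation batches, 100-seed stratification sweeps)
are the package's chosen desk-scale study conditions; all are reproducible
from fixed seeds.

## Reference similarity computation

The analog-selection check encodes the transcribed structures of ABBV-744,
mivebresib (ABBV-075), and INCB-057643 — three BET bromodomain inhibitors
sharing the 6-methyl-7-oxo-6,7-dihydro-1H-pyrrolo[2,3-c]pyridine core —
and computes 166-key MACCS Tanimoto similarities of the latter two against
ABBV-744. With RDKit's MACCS definitions these are 0.65 (mivebresib) and
0.60 (INCB-057643) at two decimals; published values from other toolkits
place the second pair at 0.61, within the expected cross-implementation
spread of the MACCS keys.

## Known limitations

- Tautomers are not canonicalized, and deduplication ignores stereochemistry
  only to the extent the InChIKey does; stereoisomer-aware variants are out
  of scope.
- The neutralization rule is deliberately simple (protonation states only);
  exotic charged species beyond permanent quaternary cations are flagged
  rather than repaired.
- Hyperparameters are library defaults by design; no search is performed.
- The consensus is unweighted; no applicability-domain estimate accompanies
  the scores.
- Units are restricted to molar multiples (M, mM, µM, nM).
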