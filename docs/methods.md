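# Methods

## Turn assignment model

A window *i..i+3* is a candidate beta-turn when all four residues have
complete N/CA/C backbones with consecutive numbering, Cα(*i*)–Cα(*i+3*) < 7 Å,
and neither central residue is helical (helicity is an input mask; the
default mask is all-false, so callers may plug in any secondary-structure
source).  Candidate windows are typed from (φ<sub>i+1</sub>, ψ<sub>i+1</sub>,
φ<sub>i+2</sub>, ψ<sub>i+2</sub>) against a canonical table:

| type | φ<sub>i+1</sub> | ψ<sub>i+1</sub> | φ<sub>i+2</sub> | ψ<sub>i+2</sub> | cis-Pro at i+2 |
|------|------|------|------|------|----|
| I    | −60 | −30 | −90 | 0   | –  |
| I′   | 60  | 30  | 90  | 0   | –  |
| II   | −60 | 120 | 80  | 0   | –  |
| II′  | 60  | −120| −80 | 0   | –  |
| VIII | −60 | −30 | −120| 120 | –  |
| VIa1 | −60 | 120 | −90 | 0   | yes |
| VIa2 | −120| 120 | −60 | 0   | yes |
| VIb  | −135| 135 | −75 | 160 | –  |

These are the standard Hutchinson–Thornton values used by the PROMOTIF
assignment convention; the table is a parameter and can be replaced.  A
defined type matches when every deviation is ≤ 40° and at most one exceeds
30°, deviations measured on the circle to avoid ±180° artifacts.  Windows
matching no defined type are type IV.  When several types match, a fixed
precedence (I, I′, II, II′, VIII, VIa1, VIa2, VIb) decides; a best-fit
alternative (smallest total circular deviation) is available because the
original assignment programs do not document their tie-break.  The
cis-proline condition is classification-side only for VIa1/VIa2 (a
configurable flag can extend it to VIb); a peptide bond is cis when
|ω| < 30°.

Torsions follow the IUPAC sign convention, reported in degrees in
(−180, 180], with 1-based residue indexing.  Residues missing backbone
atoms break torsion continuity and no turn may span them.  Alternate
locations resolve to the highest-occupancy conformer.

## Feature encoding

Each residue is 25 input neurons: 20 logistic-squashed profile log-odds
(column order `ARNDCQEGHILKMFPSTWYV`), one out-of-chain indicator, three
secondary-structure probabilities and the relative accessibility.  The
squashing is the plain logistic 1/(1+e<sup>−x</sup>) — profile scores are
integer log-odds of magnitude ≲10, which the logistic maps into (0,1)
without additional scaling.  The indicator is our reading of the 25th
neuron: it is 1 exactly on virtual window positions beyond the termini,
where every other input is 0, so the network can distinguish "no residue"
from "residue with zero features".  Windows are odd-sized (5–13) and
centered; predictions are made for the central residue.

Second-layer inputs are composed per the lettered setups A..M (setup M =
four position scores + general score + helix/strand/coil + accessibility =
9 channels).  Windowing appends a per-position out-of-chain indicator; when
a setup includes the profile block the indicator sits directly after it, so
setup A reproduces the first-layer encoding bit for bit.

## Networks, training and ensembles

One hidden layer of logistic units and two logistic output neurons (one per
class); the reported score is the positive share o₊/(o₊+o₋).  Training is
online stochastic gradient descent on squared error against a one-hot
target, example order reshuffled each epoch from a seeded generator;
momentum and weight decay exist as configuration but default to 0.  Weights
initialize uniformly on ±0.1.  After each epoch the Matthews correlation on
the held-out fold at threshold 0.5 is recorded and the weights of the
best-MCC epoch are the ones kept (epochs where every call lands on one side
leave the MCC undefined and are never selected).  The library defaults are
learning rate 0.01 and 300 epochs; the reduced experiment protocol below
uses 0.05 and 10–12 epochs, which this data saturates quickly.

Cross-validation splits whole chains, never residues, into K folds by a
greedy residue-balancing rule (longest chain first into the lightest fold;
seeded shuffling breaks ties), which bounds the fold imbalance by the
longest chain.  The full protocol trains a 5-window × 4-hidden grid per
fold (20 architectures, 200 fold-networks at K=10).  First-layer ensembles
keep the top fold-networks ranked by leave-out MCC (ties: smaller window,
fewer hidden units, lower fold); the second layer keeps the best network
within each fold.  Ensemble output is the unweighted mean of member scores.
Cross-validated scores for a chain come only from ensemble members whose
held-out fold contains that chain; if top-k selection dropped a whole fold,
the best network of that fold substitutes, so no residue is ever scored by
a network that trained on it.  The same out-of-fold scores are the training
inputs of the second layer.  An audit helper re-verifies both properties on
every training result and is exercised by the test suite.

Decision thresholds: 0.50 by default; 0.61 as the accuracy-optimized
"tweak" preset, which trades sensitivity for precision on 25%-positive
data.

## Evaluation

Confusion counts call a residue positive when score ≥ threshold (boundary
inclusive).  MCC, Q_total, PPV, sensitivity and specificity use their
textbook forms; zero-denominator cases return NaN with a flag rather than
a silent 0.  ROC curves group tied scores; the AUC is the trapezoidal
integral, identical to the normalized Mann–Whitney U with half credit for
ties.  The AUC-difference test is a two-sided z-test with unpaired
Hanley–McNeil standard errors; it is a coarse instrument (it ignores the
pairing of scores on the same residues) but matches the cited methodology.
Percentages are reported to one decimal, MCC/AUC to three.

## Synthetic data generator

The generator is the package's stand-in for curated structure sets with
real profiles, and it defines the study conditions of the test suite.

Backbones are built from internal coordinates (N–CA 1.458 Å, CA–C 1.525 Å,
C–N 1.329 Å; angles N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°) by
sequential placement; recomputed torsions agree with the inputs to well
below 1e-4°, so the builder doubles as the geometry oracle.  Flanks are
extended (φ, ψ = −120°, 130°).  Each planted turn occupies a six-residue
torsion block: the type's canonical dihedrals plus uniform jitter
(default ±20°, capped below 25° so recovery stays inside the ±30° rule),
with the four neighbouring "buffer" dihedrals searched at random until,
inside an extended context, the turn's own window is the only one under
7 Å.  Because a window's Cα span depends only on the torsions between its
residues, validating a block inside a fragment is exact for any chain that
places it in an extended context; blocks are kept ≥9 starts apart so no
window touches two of them.  Jittered angle sets are resampled until the
planted type is the *unique* matching type, which excludes precedence
ambiguities by construction.  VIa1/VIa2 get proline at *i+2* with ω=0; VIb
is also built cis (its classical proline form — with a trans bond the
canonical VIb dihedrals do not close below 7 Å).  An overlapping-turn
builder plants VIII and VIa2 offset by one residue (their shared-residue
dihedrals coincide canonically), producing a five-residue turn whose shared
residues carry positions {1,2} and {3,4}.

Default conditions: 50 chains of 90–110 residues, six turns per chain
(≈24% of residues in turns, matching the ≈25% base rate of real data),
types sampled with type I most frequent.  Sequences draw turn residues from
the turn-favoring set Gly/Asp/Ser/Pro/Asn with probability 0.40 (uniform
background otherwise), reproducing the observed enrichment pattern (e.g.
Gly ≈11% in turns vs ≈6% overall in generated sets).  Profiles are integer
log-odds N(0, σ=1); on turn residues whose own identity is turn-favoring,
the five favoring columns shift by +δ (default 4).  Routing the effect size
through composition mirrors how real homology profiles carry the signal and
deliberately leaves a fraction of turn residues profile-silent, keeping the
task learnable but not trivial — single networks reach MCC ≈ 0.8, not 1.0,
leaving headroom that makes the ensemble and second-layer comparisons
informative.  Structure tracks: helix/strand/coil from Dirichlet(1,1,2.5)
inside turns vs Dirichlet(2,2,2) outside, accessibility Beta-distributed
with mean 0.45 inside vs 0.38 outside.  Everything derives from one seeded
generator; identical seeds give byte-identical fixtures.

What passing tests show, and what they do not: the generator has exact
block-isolated turns, no helices, no overlapping-type mixtures beyond the
constructed pair, and feature noise that is i.i.d. rather than
profile-correlated, so results quantify the correctness of the machinery
and the qualitative behavior of the two-layer design — not expected
accuracy on real structure sets.

## Reduced experiment protocol and problem sizes

The test suite and the acceptance script run the pipeline at a reduced
scale chosen as a representative slice of the full protocol: 5 folds, a
2×2 first-layer grid (windows 5 and 9; 50 and 75 hidden units), a single
7×50 architecture for the four position tracks, ensemble size 10,
learning rate 0.05, 10 epochs.  Five seeded replicates back the
second-layer-gain comparison.  Type-specific (β-turn-S) tracks are
implemented and optionally trained (`train_types=True` / `--types`); the
reduced protocol leaves them off and their prediction columns are NaN.

## Dataset utilities

Chain ranking uses the surrogate score resolution × sequence_length /
pdb_length (lower is better): it prefers high-resolution structures whose
deposited coordinates cover the whole sequence, and any scoring function
with the same monotonicity can be substituted.  Percent identity comes from
a BLOSUM62 global alignment (gap open 11, extend 1), counted as identities
over alignment columns.  Hobohm-1 visits records in rank order and accepts
those with ≤25% identity to everything already accepted; a length-corrected
cutoff (290.15·L^−0.562, floored at 25%) is available for short sequences.
The PISCES-style filter keeps records with resolution ≤3.0 Å, R-factor
≤0.2 and length 40–10,000.

## Known limitations

- The assignment reproduces the published tolerance rules but not any
  undocumented internals of the original assignment binaries (tie-breaks,
  helix definitions); both knobs are exposed instead.
- Networks are period-typical multilayer perceptrons; no momentum schedules,
  regularization or calibration are applied by default.
- The generator does not emulate helices, β-bulges, missing density or
  real profile correlation structure; benchmark-scale accuracy claims
  require real structure sets and full-scale training, which are outside
  this package's scope.
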