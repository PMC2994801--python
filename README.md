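# betaturn

Beta-turns are the most common non-repetitive protein secondary structure:
four consecutive residues *i..i+3* whose Cα(*i*)–Cα(*i+3*) distance is under
7 Å and whose two central residues are not helical, further divided into
nine types (I, I′, II, II′, VIII, VIa1, VIa2, VIb and the catch-all IV) by
the φ/ψ dihedrals of residues *i+1* and *i+2*.  Roughly a quarter of all
residues in globular proteins sit inside one, and because turns reverse the
chain direction at solvent-exposed surfaces they matter for folding studies,
epitope prediction and peptide design.

`betaturn` is a toolkit for structural bioinformaticians working on
residue-level turn prediction.  It provides:

- **Geometric turn assignment** from backbone coordinates (PDB): φ/ψ/ω
  torsions, the 7 Å Cα criterion, and type classification against the
  canonical dihedral table with the ±30° tolerance (one angle may deviate up
  to ±40°) and the cis-proline requirement for the VIa types.
- **Sequence-based prediction** with a two-layer feed-forward network
  ensemble.  Each residue is encoded by 25 inputs — 20 logistic-squashed
  PSSM log-odds, an out-of-chain indicator, predicted helix/strand/coil
  probabilities and relative surface accessibility — presented in sliding
  windows of 5–13 residues.  First-layer ensembles predict general turn
  membership (β-turn-G) and turn position 1–4 (β-turn-P); a second layer
  consumes their cross-validated outputs (setup M: position scores + general
  score + sec/rsa) to filter noise.  Networks are trained by online backprop
  on squared error with two output neurons, and weights are kept from the
  epoch with the best held-out Matthews correlation.
- **Evaluation**: MCC, Q_total, PPV, sensitivity, specificity, ROC/AUC with
  tie handling, threshold sweeps (default cutoff 0.50, Q_total-optimized
  "tweak" 0.61), and a Hanley–McNeil z-test for AUC differences.
- **Dataset tooling**: chain ranking, BLOSUM62 global-alignment percent
  identity, Hobohm-1 homology reduction, PISCES-style record filtering and
  amino-acid composition statistics.
- **A synthetic fixture generator** that builds backbone chains with turns
  of chosen types planted at known positions (internal-coordinate → Cartesian
  construction) plus label-correlated profiles and structure tracks, so the
  whole pipeline is testable without external downloads.

## Worked example

Generate a synthetic dataset, train the reduced two-layer model, predict a
chain and evaluate:

```bash
betaturn synth --out data --seed 5 --chains 12 --min-length 60 --max-length 70 --turns-per-chain 3
betaturn assign data/SYN000.pdb --chain A --out ann.tsv --instances inst.tsv
betaturn train --data data --out model --seed 5 --folds 3 --epochs 6
betaturn predict --model model --pssm data/SYN001.pssm --surf data/SYN001.surf --out pred.tsv
betaturn evaluate --pred pred.tsv --truth data/truth.tsv --out eval.tsv
```

The `assign` step prints the turns it found, e.g.

```
data/SYN000.pdb:A — 67 residues, 3 turn instances
```

and `inst.tsv` lists them with their geometric types:

```
chain	start	type	residues
A	19	I'	19,20,21,22
A	39	I	39,40,41,42
A	61	I	61,62,63,64
```

meaning three isolated four-residue turns were assigned (a type I′ at
residues 19–22 and two type I turns).  `pred.tsv` holds one row per residue
with the general turn score, the binary call at the 0.50 cutoff, the nine
type scores and the four position scores; `evaluate` condenses predictions
against truth into one metric row (MCC, Q_total, PPV, sensitivity,
specificity, AUC).  The same functionality is available from Python via
`betaturn.assign_turns`, `betaturn.train_layered` and
`betaturn.predict_chain`.

At the package's default study conditions (50 chains of ~100 residues,
profile effect size δ=4, noise σ=1, 5 folds, reduced 2×2 architecture
grid) a training run reports, for example:

```
single_network_best_leaveout_mcc: 0.8439
first_layer_cv_auc: 0.9494
second_layer_cv_auc: 0.9692
```

i.e. individual first-layer networks learn the planted signal well, and the
second layer adds a consistent AUC gain by smoothing the first-layer output
— the qualitative behavior the two-layer design exists for.

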