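# Methods

## The prediction problem

Given a wild-type protein (sequence; optionally a Cα structure and DSSP
output; a PSI-BLAST profile) and a set of simultaneous substitutions, predict
the change in folding free energy ΔΔG (kcal/mol, positive = stabilizing).
Because ΔΔG is a thermodynamic state function, the hypothetical reverse event
(mutant → wild type) has exactly the negated ΔΔG. The package exploits this
identity twice: as *training augmentation* (every forward record gets a
reverse partner, which balances the stabilizing/destabilizing classes
exactly whenever no record sits at ΔΔG = 0) and as a *robustness probe*
(metrics are reported separately for forward and reverse events; a model
that has merely memorised the forward sign convention shows a large gap).

## Feature construction

All 41 features are listed in `pipeline.FEATURE_NAMES_STRUCTURE`; the 34
sequence-mode features omit the seven Delaunay slots. Design notes on points
the construction had to fix:

- **Profile scores.** Point features are direct PSSM look-ups at the mutated
  position (wild-type and mutant columns, log-odds and weighted blocks).
  Window features aggregate each position as the *sum of its 20 log-odds
  (resp. weighted) entries* and average that aggregate over a w-residue
  window (w ∈ {5, 9, 15}) centred on the site, truncated at the termini.
  The per-position aggregation rule is one of several defensible choices; it
  is isolated in `evo.window_scores` and switchable to the wild-type-column
  variant. Tree ensembles are invariant under strictly increasing
  per-feature transforms, so this choice affects the printed scale of the
  feature, not the splits. Profile units are kept raw (no normalisation).
  For reverse records the wild type's profile is reused with swapped
  column look-ups; this is cheap, exactly realises the swap identity
  (Wtlo↔Mulo, Wtwt↔Muwt, windows unchanged), and avoids pretending a mutant
  profile exists when none was computed. A separately supplied mutant
  profile can be attached instead.
- **Annotation.** DSSP 8-state codes collapse as H,G,I→H; E,B→E; rest→C
  (the B→E grouping is configuration data, since conventions differ).
  Relative solvent accessibility = ASA / max-ASA with the Tien et al. (2013)
  theoretical scale (config-replaceable). Binary exposure threshold 25%;
  the three-state exposure used by state-conditional fragment features adds
  an intermediate band [0.25, 0.50). Values exactly at a threshold go to
  the higher-exposure class — a threshold needs a comparator, and one was
  fixed and is asserted in tests. Mutants inherit the wild type's
  annotation and coordinates (fixed-conformation assumption).
- **Relative differences.** All six are value(mutant) − value(wild type),
  hence exactly anti-symmetric. The "small residues" set is {T, D} —
  deliberately narrow, kept as configured data (`constants.RESIDUE_SETS`)
  with an override hook, because correcting it silently would change the
  feature's meaning.
- **Fragment potentials.** Occurrence potentials are additive-pseudocount
  log frequency ratios between two reference corpora,
  ln((c_A+κ)/(N_A+κK)) − ln((c_B+κ)/(N_B+κK)), with κ = 1 and K the key-space
  size (20⁴ sequential; C(23,4) = 8,855 unordered Delaunay compositions).
  Propensity potentials are the between-corpus difference of the
  state-conditional enrichment ln P(f|state) − ln P(f). A tetra-peptide's
  state is the majority state of its four residues; a 2–2 tie takes the
  third residue's state, then a fixed state order. Unseen fragments score
  the closed-form zero-count value, so tables are total functions. Because
  every fragment feature is a score *difference* at fixed annotation, only
  the ≤4 windows (or the tetrahedra) overlapping a substituted site can
  contribute; the implementation rescores only those, and a full-sequence
  rescore is kept as a cross-check path (they agree to 1e-12; bit-exact
  agreement is not expected because the two paths accumulate sums in
  different orders).
- **Delaunay features.** The Cα point set is tessellated (Qhull); cells
  with any edge over 10 Å are dropped as hull slivers (configurable).
  Tetrahedra are keyed by residue composition (sorted letters — spatial
  neighbours have no canonical order) and classed by sequence continuity:
  D43 (a run of ≥3 consecutive positions), D2 (an adjacent pair, no run),
  D1 (no adjacent pair). The "occurrence" Delaunay features use the same
  log-ratio form as the sequential ones for coherence; the functional form
  sits behind `PotentialTable` so alternatives drop in.

## Training and evaluation protocol

- Random forest regression, 2,000 trees by default, scikit-learn defaults
  otherwise (near-optimal without tuning for this kind of tabular data);
  prediction is the tree mean; classification threshold is zero predicted
  ΔΔG, with exactly-zero predictions called destabilizing (conservative
  tie-break). Records with experimental ΔΔG = 0 sit on the class boundary
  and are excluded from classification metrics but kept for regression.
- Fold assignment: single-linkage clusters of proteins sharing >30%
  global-alignment identity (match 1, mismatch 0, gap open −1, extend −0.5;
  identity = identical columns / alignment length), dealt to 5 folds
  largest-mutation-count first into the lightest fold. Reverse records
  inherit their forward partner's fold. No homologous pair ever straddles a
  split, and the hygiene is re-verified by recomputation in tests.
- Metrics: accuracy; ROC AUC via the Mann–Whitney midrank statistic
  (equal to the concordant-pair fraction with half-credit ties); Pearson R
  on pooled out-of-fold predictions across the five folds. Feature
  importance is impurity decrease, averaged across fold models with a
  standard error. The feature screen compares each feature's distribution
  in stabilizing vs destabilizing records with the two-sample
  Kolmogorov–Smirnov test (asymptotic p-values).

## The synthetic-data generator

Real curated ΔΔG collections require external downloads, so the test bed is
synthetic and fully self-contained. It emulates: background-frequency
sequences (Robinson–Robinson), ideal-helix or self-avoiding-walk Cα traces
(3.8 Å steps), Dirichlet profiles with the native residue elevated (weighted
rows sum to exactly 100, integer log-odds), random ss3/rsa annotations, and
two potential-table corpora distinguished by a charged-residue composition
bias. Planted ΔΔG is a linear combination of *difference-type* features only
(defaults: pIa, dASA, POSI, TINY, FBocc), so the ground truth is exactly
anti-symmetric; weights are rescaled so the noise-free signal has sd
1.5 kcal/mol — a realistic single-mutation scale — and Gaussian noise of sd
0.75 is added (signal:noise 2:1). The standard study is 500 single- +
200 double-point records over 12 length-120 proteins, cross-validated with
500 trees (the evaluation protocol is insensitive to ensemble size beyond a
few hundred trees, and this keeps the standard study fast).

What passing on this bed shows — and does not. It demonstrates that the
pipeline computes its features correctly (anti-symmetry and locality are
exact), that the clustered CV machinery leaks nothing, and that the forest
recovers a recoverable signal symmetrically in both mutation directions.
It does not show that real thermodynamic signal is this recoverable: real
ΔΔG is not a linear function of these features, real profiles and
annotations are correlated with structure in ways the generator does not
model, and real mutation collections are heavily destabilizing-biased
before augmentation.

## Numerical and degenerate-input choices

- Pseudocount κ = 1 everywhere; state tables with zero fragments in a state
  degrade to pseudocount-flat tables with a warning rather than failing.
- Tessellation rejects <4 points, duplicates and coplanar sets; residues
  with missing Cα (NaN rows) are excluded while keeping residue numbering.
- The KS null calibration check uses unequal sample sizes (500 vs 700):
  with equal sizes the discrete lattice of the D statistic visibly distorts
  the asymptotic p-value distribution.
- Midrank AUC returns NaN (reported as absent) when a direction has a
  single class; Pearson R returns NaN for degenerate variance.
- All report files are written with fixed float formatting, so identical
  config + inputs + seed reproduce them byte-for-byte.

## Known limitations

- The potential tables shipped by the generator are built from synthetic
  corpora; building from real thermophile/mesophile corpora is supported
  (`thermoforest build-potentials`) but the curation itself is out of scope.
- PSI-BLAST, PSIPRED and DSSP are consumed as files, never executed.
- Single-chain, first-model PDB reading; insertion codes are rejected
  rather than renumbered; mmCIF is not supported.
- ΔTm obeys the same sign identity and could replace ΔΔG as the label, but
  all modelling here uses ΔΔG.
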