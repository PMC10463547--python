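# Methods

## Model

One protein–ligand pair is represented by a 38-element vector: 20 amino-acid
composition counts of the target followed by 18 ligand descriptors.  A
gradient-boosted tree regressor (XGBoost, squared-error objective) maps this
vector to the affinity label pK = −log₁₀(K<sub>d</sub> or K<sub>i</sub> in
molar).  No spatial information about the complex enters the model; the
protein side is pure residue-type frequency, invariant to sequence order and
geometry.  The working hypothesis is that composition acts as a coarse
homology fingerprint — similar targets have similar pockets and similar
ligand preferences — rather than as an energetic model of the interface,
which is why counting the *full chain* instead of the pocket degrades
performance only marginally.

## Features

**Composition block.**  The 20 standard amino acids in fixed alphabetical
three-letter order (ALA … VAL).  Three sources are supported: a pocket PDB
file (counts of its standard residues), a pocket computed from coordinates
(all residues with a heavy atom within a cutoff, default 10 Å inclusive, of
any ligand atom), or a one-letter full-chain sequence.  Non-standard
residues, waters, ions and ligands are excluded from the counts but tallied,
so `sum(counts) + n_excluded == residues scanned` always holds.  When one
protein has several structures in a dataset the element-wise mean count is
used, which is why the vector holds floats.

**Descriptor block.**  An ordered, configurable registry of RDKit
descriptors.  The shipped default panel of 18 is this package's own choice
of standard physicochemical and topological properties: MolWt, MolLogP,
MolMR, TPSA, NumHDonors, NumHAcceptors, NumRotatableBonds, HeavyAtomCount,
NumHeteroatoms, RingCount, NumAromaticRings, NumSaturatedRings,
NumAliphaticRings, FractionCSP3, FormalCharge, BalabanJ, BertzCT, Kappa2.
All are 2-D (connection-table) properties; descriptors are computed on the
standardized form of the ligand whenever standardization succeeded.  The
feature ordering is frozen by a schema hash embedded in trained models;
prediction on a mismatched schema is refused rather than silently reindexed.

## Ligand standardization

Stages run strictly in order, each only after the previous failed:

1. **native_sanitize** — RDKit sanitization of the parsed molecule,
   followed by a canonical-SMILES round trip (idempotent: a standardized
   ligand re-standardizes to the same canonical form).
2. **remote_service** — an external standardization web service.  Disabled
   by default and never exercised by the test suite; it is a
   dataset-construction convenience, not a predict-time dependency.
3. **mol2_conversion** — conversion of the original record to SYBYL MOL2 via
   the `obabel` executable and a re-read.  SYBYL atom typing lets formal
   charges be reassigned (e.g. a four-coordinate neutral nitrogen becomes
   N⁺), which rescues a useful class of valence errors.

If every enabled stage fails the ligand is dropped, the per-stage messages
are kept, and batch builds emit a plain-text report of incompatible
structures.

## Dataset curation (activity tables)

Filters apply in a fixed order, each logging its drop count:

1. keep rows whose measurement type is Ki or Kd (IC50 etc. are excluded
   because they are assay-dependent and not comparable on the pK scale);
2. keep rows whose structure parses and whose molecular weight is below the
   small-molecule ceiling (default 700 Da);
3. keep-last deduplication per (target, ligand) pair — *last in source
   order*, which is why the table reader guarantees order preservation;
4. optionally drop every protein whose surviving ligand count exceeds a
   threshold.  The whole protein is removed rather than subsampled, so
   protein sets shrink monotonically as the threshold tightens and
   dataset(t₁) ⊆ dataset(t₂) for t₁ ≤ t₂.

The build log is conserved by construction (input = output + Σ drops) and
the filter pipeline is idempotent.  Affinities are converted with
pK = −log₁₀(value × unit-factor), units M through pM.

## Hyperparameter search and evaluation

The full grid is rounds {500, 1000, 1500, 2000} × depth {2, 4, 6, 8} ×
learning rate {0.001, 0.01, 0.1, 0.2, 0.3} (80 points); every other booster
setting stays at the library default and is pinned into the model artifact.
Selection maximizes the mean internal 5-fold-CV Pearson R on the training
partition only, with ties broken by lower mean RMSE, then smaller round
count, shallower depth, smaller learning rate — a total order, so selection
is exactly reproducible by exhaustive evaluation of the same folds.  A grid
point whose predictions are constant on a validation fold (vanishing
learning rate) scores −∞ rather than raising, so degenerate corners of the
grid are well-ordered; user-facing correlation on zero-variance input
remains a hard error.

Outer evaluation is a separate k-fold CV (random partitions, no
stratification, seeded): grid search + refit happen inside each outer
training partition, metrics come from the held-out fold, and the reported
mean R / RMSE are arithmetic means of per-fold values.  Grid search is run
once per outer training partition.  Ablations slice the feature matrix into
ligand-only (18 columns), protein-only (20 columns) and combined blocks and
reuse one fold assignment across blocks, so block comparisons are paired.
Benchmark-style evaluation (train/core-test splits) uses the same grid
search on the training split.

Everything is single-threaded and deterministic by default (`n_jobs=1`,
`tree_method="hist"`, seeded KFold); multithreading is opt-in.

## Synthetic study data

The generator stands in for licensed benchmark downloads.  Per protein it
draws a residue-type distribution from a symmetric Dirichlet (α = 2) over
the 20 amino acids and emits a pocket of 25–55 residues with random-walk
backbone-like coordinates (CA spacing 3.8 Å — enough geometry for distance
cutoffs, no physics implied).  Ligands come from a closed fragment grammar
(ring scaffolds plus chain units that only place monovalent atoms in
branches), which guarantees valid, natively sanitizable SMILES under
700 Da.

Affinities are a known sparse function of the features: with per-column
z-scores z(·) over the generated set,

    signal = 1.0·z(MolLogP) − 0.6·z(TPSA) + 0.9·z(aa_LEU)
             + 0.7·z(MolLogP)·z(aa_LEU)

scaled to SD 1.5, centred at pK 7, plus N(0, noise_sd) noise, clipped to
[0, 14].  Defaults: 50 proteins × 20 ligands (1000 pairs) and noise SD 0.3,
giving a noise ceiling of R ≈ 0.98.  The interaction term is deliberate:
it makes the combined block strictly more informative than either block
alone, so the ablation ordering seen on real data is reproducible in kind.
The same set can be written to disk as pocket PDBs, a SMILES file, an index
file and an activity table, and regenerates byte-identically from one seed.

What the generator does *not* emulate: real binding energetics, pocket
tailoring to the ligand, correlated assay noise, target family structure,
or the heavy skew of ligands per protein in bioactivity databases.  Passing
tests on synthetic data therefore demonstrate that the pipeline recovers a
recoverable signal and that its bookkeeping is exact — not that the method
attains any particular accuracy on real benchmarks.

## Desk-scale experiment sizes

Synthetic experiments use a reduced 2×2×2 grid — rounds {300, 600} × depth
{2, 4} × learning rate {0.1, 0.2} — chosen so the nested protocol (outer
5-fold × 8 points × inner 5-fold) remains exact in structure while each
booster fit stays sub-second at n = 1000 × 38 on one CPU.  The full 80-point
grid is the default for real datasets (`--grid default`).

## Numerical choices and edge cases

* Residue identity is (chain, residue number, insertion code); alternate
  locations collapse to the alphabetically first conformer (the first listed
  in essentially all deposited files) — counting, not geometry refinement.
* Pocket distance uses heavy atoms only; the cutoff is inclusive.
* Empty residue sets and sequences featurize to a zero vector with a logged
  warning rather than an error; empty structure *files* are an error.
* Malformed index/table lines are skipped, logged and counted; a missing
  required column is a hard schema error.
* Model persistence stores the raw booster plus a JSON sidecar (schema,
  hash, chosen grid point, pinned defaults); loading rebuilds the wrapper
  from the sidecar.

## Known limitations

* Composition features cannot distinguish targets with identical pocket
  composition; per-target applicability is not assessed.
* No 3-D ligand descriptors, interaction fingerprints or docking-power /
  ranking-power metrics — out of scope by design.
* mmCIF input and NMR multi-model handling (beyond first-model) are not
  supported.
* The remote standardization stage is implemented but unexercised by
  default; its behaviour depends on the external service's contract.
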