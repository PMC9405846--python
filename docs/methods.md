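# Methods

This note documents the models, numerical choices and known limitations of
`aptaselex`. It describes what the code computes and why; every number
quoted here is produced by the test suite or by `scripts/acceptance.py`.

## Candidate library

Candidates are i.i.d. uniform random strings over {A, C, G, U}. Uniformity
is an explicit modelling choice: nothing in the selection problem privileges
any base a priori, and the test suite checks the empirical composition
(0.25 ± 0.01 per base over 10⁵ 27-mers). Deduplication is exact — a
growing hash set with redraw on collision — so the library holds exactly
the requested number of distinct sequences. The default length of 27 nt
(~6 nm of ssRNA) reflects the Debye screening length of the electrochemical
sensor surfaces these aptamers are designed for: a longer tether would put
the conformational change outside the electrically sensitive zone.
Identifiers are zero-padded ordinals, which makes downstream tie-breaking
and merging deterministic.

At desk scale the package generates 10⁵–10⁶ candidates in seconds;
10⁸-scale pools are the same code path but are not exercised in the tests
(the test suite and the acceptance script use 10⁵, which is large enough to
estimate the filter survival fraction to three digits).

## Thermodynamic filter

Each candidate is folded to its MFE secondary structure. The default engine
is the ViennaRNA nearest-neighbor thermodynamic model at 37 °C with default
(Turner) parameters; the temperature is a parameter, fixed at the
physiological default because the sensing application is aqueous and
near-ambient and no other value is pinned by the problem.

The filter keeps a candidate iff

* MFE < −5 kcal/mol — the fold is stable enough to present a defined
  scaffold; and
* unpaired count ≤ 20 — enough nucleotides remain single-stranded to form
  a binding pocket, but the structure is not fully open.

"Unpaired" means every `'.'` position of the dot-bracket string — hairpin
loops, internal loops, bulges and dangling ends alike — because that is the
only definition computable from the dot-bracket alone. Both thresholds and
the inequality direction are configurable (`FilterPolicy`); the measured
survival fraction of uniform random 27-mers under the defaults is ~0.19
(n = 10⁵, reported by the acceptance script), and tightening ΔG to
−8.7 kcal/mol would be required to reach a 10⁻² survival rate.

A bundled Nussinov-style maximum-pairing engine (canonical Watson–Crick +
GU pairs, minimum hairpin loop 3, fixed pseudo-energy −1 kcal/mol per pair)
serves as a dependency-free fallback. Its dot-brackets are legal nested
structures but its energy scale is *not* thermodynamic; it exists so the
package imports, tests and demos run without the ViennaRNA bindings, and it
must not be used for real candidate triage. Both engines agree exactly on
the degenerate cases (poly-A/poly-U: open chain, 0.0 kcal/mol), which the
tests pin.

## Encodings

Aptamer sequences are one-hot encoded position-by-position (A→1000, C→0100,
G→0010, U→0001; rows = positions, columns = channels in that fixed order)
and padded to 100 positions with all-zero rows. The pad row is {0000}
rather than a fifth channel: it keeps the channel dimension at exactly
four and is inert under convolution, so padding carries no information.
Encoding is bijective on the non-pad prefix (property-tested).

Targets are encoded as MACCS structural keys: 166 fixed substructure
queries evaluated on the molecular graph, yielding a 166-bit binary vector.
SMILES are canonicalised before key generation so all notations of one
structure map to one fingerprint; the key generator's unused leading bit is
dropped, leaving exactly the 166 defined keys. The fingerprint length is
constant regardless of molecule size.

The labelled-pair table is split 80/20 train/test, stratified by label
(a deliberate choice where the split method was open: stratification
protects the minority class at small n) and reproducible from a seed.

## The binding model

A two-branch 1-D CNN. Branch A consumes the 100 × 4 sequence matrix,
branch B the 166 × 1 fingerprint; each applies three same-padded
convolution layers (32, 64, 96 filters; kernel 5) with ReLU and
max-pooling (window 2). The branch outputs are aggregated by a **global
max over the length axis** (96 features per branch), concatenated, and
passed through fully connected layers of 1050 and 1050 units (dropout 0.1
after each) and 512 units into a single sigmoid output. Binary
cross-entropy is minimised with Adam (lr 10⁻³, batch 32) for 25 epochs.
A probability ≥ 0.5 is called a binder; the tie-at-threshold goes positive
by convention, fixed and tested.

Design choices that were genuinely open:

* **Aggregation.** Global max pooling over positions is the standard
  aggregation in sequence-motif CNNs: a motif is a local pattern whose
  *presence*, not position, carries the signal. We evaluated the
  alternative — flattening the conv features into the FC stack — and found
  it memorises small training sets without generalising across motif
  positions (held-out accuracy ~0.78 on the planted-rule fixture versus
  0.99–1.00 for global max, seeds 1/2/11). Flattening remains available
  (`ModelConfig(aggregate="flatten")`).
* **Loss.** The task is binary (bind / no-bind), so the single-sigmoid
  binary cross-entropy head is the only consistent reading; the decision
  threshold converts the probability to a call.
* **Output initialisation.** The final layer starts at zero, so an
  untrained model answers exactly 0.5 for every input — a useful
  calibration anchor that costs nothing (gradients flow through the
  nonzero hidden activations).
* **Capped depth.** Three convolution and three FC layers; deeper stacks
  overfit at the corpus sizes this model targets, so the validated config
  space stays at three.

The layer stack is implemented directly on NumPy (im2col-free convolution
as a sum of k shifted matmuls, argmax-routed pooling gradients, inverted
dropout, Adam). Every random element — initialisation, shuffling, dropout
masks — derives from `ModelConfig.seed`, so loss histories are bit-for-bit
reproducible, which the tests assert.

Hyperparameters are tuned by exhaustive grid search with stratified k-fold
(default 5) cross-validation: folds are fixed across cells and seeded, the
selection criterion is mean validation accuracy, and ties go to the first
cell in sorted-key product order. Performance is reported as accuracy,
sensitivity, specificity and precision from the confusion counts; a
precision with an empty denominator (no positive calls) is reported as
undefined, never as zero.

## Synthetic training data

Real aptamer–small-molecule training corpora are not publicly deposited, so
the generator plants an analytic rule: **binder ⇔ (sequence contains a
fixed 6-mer motif) AND (target belongs to a binder pool)**. Positives carry
the motif at a uniform random position and a binder-pool target. Negatives
break exactly one arm, half-and-half: motif-free sequence with binder
target (the sequence branch must discriminate), or non-binder target with
the motif present half the time (the fingerprint branch must
discriminate). Motif-free sequences are rejection-sampled so no accidental
motif slips in, making the planted-truth oracle exact on noise-free data.
Label noise flips each label independently with probability
`label_noise` < 0.5.

Defaults mirror a realistic literature-corpus scale: 621 positives, 835
negatives (≈43 % positive), sequence lengths 20–100 nt, default binder pool
of small nitrogenous analytes (ammonium-like) versus methylated-amine and
alcohol interferents — thematically matched to the ammonium sensing
problem. The learning test trains on a 700-row fixture (300/400) at noise
0: the default model reaches ≥ 0.85 held-out accuracy (measured 0.97 at
seed 1) while permuted labels give 0.5 ± 0.1 (measured 0.49), which is the
parameter-recovery evidence — and its limit: passing says the architecture
can recover a planted motif-fingerprint association from ~560 examples,
not that it predicts real binding affinities. Real corpora carry
correlated motifs, family structure between targets, label noise from
heterogeneous assays, and no clean AND rule; none of that is emulated.

## Screening and selectivity ranking

The trained model scores every filtered candidate against the positive
target; candidates with p ≥ threshold are kept, sorted by probability
descending with lexicographic tie-break. The sort key is total, so
screening is embarrassingly parallel: any partition of the input, screened
separately and merged, reproduces the identical output (tested).

Docking energies enter as tables (candidate, target, mean energy, number
of replicate runs); replicate rows are merged by run-weighted averaging at
ingestion. The counter-selection rule keeps candidates with positive-target
energy ≤ −6.6 kcal/mol and every negative-target energy ≥ −5.5 kcal/mol,
then ranks by positive energy ascending. No published formula combines
positive and negative energies; the two-threshold rule with a
positive-energy sort is this package's design, with defaults read off the
published survivor energy range and interferent-energy spread, and it
reproduces the published five-candidate ranking exactly from their energy
triples (asserted in the acceptance tests). Tie-breaks: largest minimum
negative-target energy (least cross-reactive first), then sequence. A
deterministic hash-based pseudo-docking scorer (uniform on [−12, 0]
kcal/mol) exists for end-to-end plumbing tests only.

## Trajectory metrics

* **Rg**: mass-weighted RMS distance from the mass-weighted centroid.
  Invariant under rigid motions, linear under coordinate scaling (tested).
* **RMSD**: optional mass-weighted Kabsch superposition (SVD with
  reflection correction) before the weighted RMS deviation. Superposed
  RMSD never exceeds raw RMSD and is symmetric; cross-checked numerically
  against an independent MD-analysis implementation.
* **RMSF**: frames are fitted to frame 1, averaged into a mean structure,
  re-fitted to that mean (one iteration — the convention of standard MD
  toolchains), then RMSFᵢ = √⟨‖rᵢ(t) − ⟨rᵢ⟩‖²⟩. Residue grouping is the
  mass-weighted mean over the residue's atoms. Superposition can be
  disabled for lab-frame fluctuations; the closed-form and brute-force
  oracle tests pin both paths to 10⁻⁹.

Readers accept multi-model PDB and XYZ; masses come from the element/name
guesser with an explicit override table. The package computes metrics on
trajectories produced elsewhere — it does not run molecular dynamics.

## Problem sizes and tolerances

The shipped tests and the acceptance script use desk-scale sizes chosen to
estimate each quantity stably: 10⁵ candidates for the survival fraction
(three-digit stability), 700 labelled pairs for learning sanity, 2 × 10³
candidates for the screening pass rate. Closed-form trajectory cases are
asserted at 10⁻⁹ absolute; folding fixtures at the printed 0.01 kcal/mol;
statistical checks at tolerances stated inline with their sample sizes.

## Known limitations

* The filter's −5 kcal/mol / 20-unpaired defaults pass ~19 % of random
  27-mers, not the ~1 % a 10⁸→10⁶ funnel implies; matching that reduction
  empirically requires ΔG ≈ −8.7 kcal/mol. The thresholds are configurable
  precisely because the published operating point and the nearest-neighbor
  energies do not line up.
* MFE folding ignores the suboptimal ensemble, pseudoknots and
  G-quadruplexes; the unpaired count conflates loop types.
* The model is validated on planted-rule data only; no claim is made about
  accuracy on real binding corpora.
* Docking energies are consumed, never computed; the pseudo-scorer is
  noise, not physics.
* The synthetic generator does not emulate assay heterogeneity, motif
  degeneracy, or target-family structure.
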