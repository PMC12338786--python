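# Methods

This note documents the models, scoring rules, numerical choices and known
limitations behind `slimtriage`, and what its synthetic benchmarks do and
do not demonstrate.

## Motif model

Motif classes are fixed-length patterns over the 20 standard amino acids:
literals, character classes `[...]`, negated classes `[^...]`, wildcards
(`.`, with ELM's `x` normalized to `.`) and terminal anchors `^`/`$`.
Variable-length constructs are rejected — fixed length is what makes a
20×L substitution matrix well-defined.  A position is *flexible* iff it is
written as a wildcard or as `[^P]`; all other positions are *rigid*.  The
wildcard denotes the 20 standard residues, never ambiguity codes, so
sequences containing `X`/`B`/`Z` simply cannot match at those letters.
Scanning reports all overlapping occurrences, with 1-based inclusive
coordinates throughout (matching clinical `p.` notation); conversion to
0-based indices happens only at array boundaries.

## Variant evidence

Clinical classifications are restricted to the six pathogenic-/benign-side
labels; variants of uncertain significance are rejected at parse time and
never enter the pipeline.  The signed confidence score is
`±(stars + 0.1 × submissions)`.  Conflicting classifications for one
variant keep the row with most stars, then most submissions; an exact tie
across sides drops the variant.

Allele-frequency thresholds per gene: with ≥ 10 pathogenic variants
carrying frequencies, the maximum pathogenic AF; otherwise 10⁻⁴·¹ (AR or
no known disease) or 10⁻⁴·²⁸ (AD).  A variant at or above its gene
threshold and without a clinical classification is called benign with
score `−min(2, 1 + log₁₀(AF/threshold))`: −1 at the threshold, capped at
−2 one decade above.  This mapping (and the ΔΔG score below) is a
package default chosen for monotonicity and boundedness; both are
injectable via function arguments so an alternative calibration can be
dropped in without touching the pipeline.

## Substitution matrices

The ΔΔG layer is the cell-wise arithmetic mean over the structures that
report a cell; self-substitutions are ignored and the reference residue's
cell is fixed at 0.  Tolerance thresholds are 2.1 kcal/mol for crystal
structures and 1.6 kcal/mol for predicted models, applied strictly (a cell
exactly at the threshold is non-tolerated; the calibrations the thresholds
come from describe *tolerated* as strictly below).  The ΔΔG confidence
score is `clamp((ΔΔG − thr)/thr, −1, +1)`.  The final-score layer adds
clinical sums and ΔΔG confidences where both exist, passes single layers
through, and converts to verdicts with a symmetric cutoff τ (default 0.5,
about the weight of half a review star): > τ non-tolerated, < −τ
tolerated, otherwise uncertain.

Matrix comparison uses Spearman correlation over shared cells (the
relationship between two structures' ΔΔG estimates is monotone but not
linear at high destabilization) and the fraction of cells with identical
tolerance verdicts; fewer than three shared cells is an error because the
correlation is undefined.

## Model quality gate

A predicted motif–receptor model is accepted iff the mean pLDDT of the
motif residues (one value per residue, read from the Cα B-factor, the
convention AlphaFold2 uses when emitting PDB files) is strictly above 65
and the precomputed motif–receptor interaction energy is strictly below
−5 kcal/mol.  Whether the mean should be over all atoms or one value per
residue is not externally fixed; one-per-residue (Cα) was chosen and is
documented here.  Crystal structures skip the gate.  No energy function is
evaluated internally: interaction energies and ΔΔG values arrive as
numbers (AnalyseComplex-/PositionScan-style outputs or their simplified
TSV mirrors).

## Feature gates

* **Conservation** — per-column Jensen–Shannon divergence between the
  gap-free column distribution and a background (uniform by default, an
  amino-acid-frequency background injectable), mixing weight ½, log base
  2 (bounded in [0,1]), scaled by the column's non-gap fraction; no
  sliding window.  The motif score is the mean over its columns, mapped
  through the query's gapped row.  A candidate passes iff its mean reaches
  the minimum over the P0 instances (percentile configurable).
* **Secondary structure** — H/E/C fractions over the motif; the dominant
  state must occur among the P0 dominant states.
* **Exposure** — a residue is exposed iff its SASA exceeds a
  residue-type-specific threshold; the default table is a configurable
  fraction (0.25) of the theoretical maximum SASA values (Tien et al.
  2013).  SASA arrives per residue in a TSV, or is computed from raw
  coordinates with the Shrake–Rupley sphere-sampling algorithm (probe
  1.4 Å, configurable point count, via biotite) so fixtures need no
  external tool.  The motif's exposed fraction must reach the P0 minimum.
* **GO coherence** — is_a ancestor closures of candidate and P0
  cellular-component terms must intersect.  The namespace root is excluded
  from closures; with it, any two annotated proteins would trivially
  cohere.

A candidate with no feature data passes vacuously (no evidence against
it); a feature-gate failure is cached and final — a candidate that failed
the gates can never later become positive.

## Triage cycles

Cycle 1 evaluates S0 candidates' rigid-position calls against the clinical
matrix seeded by the validated P0 instances; cycle 2 evaluates the
survivors against the ΔΔG tolerance matrix (rigid positions); cycle 3 the
remainder at flexible positions.  A candidate is *contradicted* (negative)
iff any consulted call disagrees with its cell, *consistent* iff at least
one agrees and none disagrees, and *uninformative* otherwise.  Consistency
alone is not enough for acceptance — the feature gates must also pass —
and pure absence of informative calls leaves a candidate in the Remaining
set rather than accepting it vacuously.  Accepted candidates' calls are
folded into the clinical matrices and each cycle iterates until the
positive set stops growing (cap 20 iterations, a termination guard for
adversarial inputs; the cap's hit is flagged).  Candidates are evaluated
only against their own class's matrices; classes are independent.  P0
instances bypass evaluation and are reported inside the cycle-1 positive
set.  All orderings are sorted and the configuration seed is recorded, so
identical inputs give byte-identical results.

Per-variant verdicts are emitted only for variants inside final-positive
motifs; variants elsewhere are flagged out-of-scope rather than called.

## Evaluation conventions

Verdicts are three-way, truth is binary, so the confusion table is 2×3.
Accuracy counts uncertain verdicts as incorrect.  The F1 reported as the
headline is the support-weighted mean of the per-class F1 scores with
uncertain verdicts as misclassifications of the true class — the
convention that reproduces the published worked values from their
confusion cells, which single-class F1 does not; per-class values are also
emitted.  For MCC the verdicts must be binarized, and no single treatment
of uncertain verdicts reproduces the published values for both methods of
the worked comparison; both conventions (uncertain-as-benign, the default,
and uncertain-as-pathogenic) are therefore computed and reported, and
neither is asserted as canonical.  Strata with a single truth class flag
MCC undefined while still reporting accuracy.  Hold-out splits are
stratified by label, floor(n × fraction) per class, reproducible from the
seed, and held-out variants are excluded from all matrix building.

## Synthetic data

The generator emits every input the pipeline consumes, with planted
truth.  Its defaults define the benchmark conditions: 50 proteins of
80–200 residues, two motif classes (a 4-residue `NP.[YF]`-type and an
8-residue `W[^P][^P][^P][IL][^P][AGS][AT]`-type), and per class 3
validated instances, 3 true candidates (rotated across the three cycles'
decidability), 3 variant-contradicted decoys, and 4 undecidables carrying
only a sub-threshold-frequency variant.  ΔΔG cells draw from
N(0.5, 0.5) (tolerated) and N(4.0, 1.0) (non-tolerated), truncated below
at −2 kcal/mol, so both tolerance thresholds sit between the components.
Model quality draws use N(82.8, 10.0) / N(−12.1, 4.1) for correct poses
and N(40.9, 14.0) / N(−3.1, 6.6) for incorrect ones; a planted
correct-pose model is redrawn until it passes the gate and an incorrect
one until it fails, because the planted role is the QC outcome itself.
Gate-separation statistics are measured by direct Monte-Carlo sampling of
these distributions, not through the bundle, so the role enforcement
cannot bias them.

Candidate variants are placed on cells whose *realized* verdict — from the
averaged matrix over the correct-pose models the generator itself emitted
— matches the intended tolerance.  This bookkeeping, not any narrowing of
the distributions, is what makes noise-free recovery exact.  The
`variant_noise` rate flips planted labels (clinical side swapped; a benign
frequency record becomes a pathogenic clinical record), with the pre-noise
truth always in the manifest.

What passing these benchmarks shows: the plumbing, the decision rules and
the iteration logic are correct, and verdict accuracy degrades gracefully
rather than cliff-like under label noise.  What it does not show: real
proteomes have homologous motif instances, correlated variants, partial
feature data, wrong or missing inheritance annotations, and ΔΔG errors
correlated across cells — none of which the generator emulates.  Results
on synthetic bundles therefore validate the method's mechanics, not its
field performance.

## Problem sizes

The default test suite runs bundles of 50 proteins with 26 planted
matches, ten noise seeds of the same size, and 10,000-draw Monte-Carlo
gate checks; these sizes give stable statistics while keeping the whole
suite under a minute.

## Known limitations

* Only fixed-length, PTM-independent motif classes are supported.
* Variant coordinates are protein-level; no transcript/VCF lifting.
* No structure prediction, relaxation, docking or force-field evaluation;
  all energies are inputs.
* mmCIF models are not read (PDB format only).
* The gnomAD→score and ΔΔG→score mappings are package defaults (monotone,
  capped) rather than externally calibrated curves; both are injectable.
* Matches of different classes never interact; overlap between classes is
  not modeled.
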