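# Methods

## The problem

Relative solvent accessibility (RSA) is the accessible surface area of a
residue (as computed by DSSP from a 3D structure) divided by the residue's
maximum area in an extended Ala-X-Ala tripeptide, expressed in percent.
`rsapred` predicts real-valued RSA from sequence alone, and uses the
feature sets its predictors select to study a structural motif: chains of
exposed hydrophobic residues spaced 3-4 apart along one face of an
alpha-helix ("hydrophobic spines").

## The regression model

Every chain is cut into overlapping 11-residue windows; the window's
central residue is the prediction target.  Segments are grouped by central
residue and one epsilon-SVR with an RBF kernel is trained per amino acid
(20 models).  The input vector of a segment concatenates:

- **Physicochemical property (PCP) features** — for each selected AAindex
  entry, the mean of its values over the window's in-sequence residues,
  squashed into (0, 1) by the logistic x' = 1/(1 + exp(-x)).  Windows that
  cross a chain terminus average over the real residues only (the profile
  block, below, carries the terminal information instead).  Ambiguity
  codes (X/B/Z/U) contribute the property's 20-residue mean — a neutral
  imputation, since AAindex defines no values for them.
- **Profile features** — a PSI-BLAST position-specific scoring matrix per
  chain; each window position contributes its 20 logistic-squashed
  log-odds scores plus a terminal flag (1 outside the chain, where the 20
  values are logistic(0) = 0.5), giving 11 x 21 = 231 values.  The ASCII
  output's percentage block can be selected instead of the score block
  (`parse_pssm(..., block="frequencies")`); scores are the default because
  the logistic squashing suits unbounded values.
- **Sequence length** — logistic(L / 100), a single value commensurate in
  scale with the other features.  The encoding of this feature is a
  package choice; nothing hinges on it beyond keeping it inside (0, 1).

Model quality is reported as MAE = (1/n) sum |V - V'| in RSA percentage
points, and Pearson's correlation coefficient in the normalized-sum form
CC = 1/(n-1) sum ((X-Xbar)/S_x)((Y-Ybar)/S_y) with sample (ddof = 1)
standard deviations.  CC is reported as missing when either series has
zero variance.  Predictions are clamped to [0, 100].

ASA-to-RSA conversion uses bundled extended Ala-X-Ala reference areas;
observed ratios above 1 (possible in real structures) clamp to 100%.

## Informative-property selection (the GA)

For each residue group, an inheritable combinatorial GA selects exactly r
properties while co-tuning three 4-bit genes that decode to the SVR
hyperparameters on powers-of-two grids: C in 2^-5..2^10, gamma in
2^-12..2^3, epsilon in 2^-10..2^5 (the LIBSVM-conventional ranges; the
source material does not print its grids).  Fitness is 10-fold
cross-validated MAE with a fold assignment frozen per search, so fitness
is a pure function of the chromosome and can be memoised.

Defaults mirror the study conditions: population 50, crossover rate 0.8,
mutation rate 0.05, r swept from 40 down to 10, 30 independent runs, the
final answer being the minimal-MAE chromosome over all stages and runs.
Choices the source leaves open, fixed here:

- **Crossover** is orthogonal-experimental-design based: genes the parents
  share are copied; divergent genes are bucketed round-robin into at most
  7 two-level factors; each distinct row of the L8(2^7) array is
  assembled, repaired to popcount r by seeded random add/remove, and
  scored; child 1 is the best row and child 2 the main-effect-optimal
  level combination.  Full per-gene OED on hundreds of divergent genes
  would cost dozens of evaluations per crossover and is deliberately
  capped.
- **Mutation rate is per gene**: each active property gene swaps against a
  random inactive one with probability 0.05 (so Binomial(r, 0.05) swaps
  per individual), preserving popcount exactly; each 4-bit gene flips one
  random bit with probability 0.05.  A per-individual reading would give
  almost no exploration.
- **Selection** is tournament of size 2 with elitism of 1; 30 generations
  per stage with early stop after 10 stagnant generations.
- **Inheritance**: the next stage's population consists of copies of the
  stage best, each with one distinct active gene disabled.
- **Initialization** is "screened" by default: one univariate CV-MAE pass
  over the table is converted into soft sampling probabilities for the
  initial masks (temperature = one third of the median-to-best spread), so
  marginally informative properties appear in the initial population more
  often while every property keeps support.  Uniform initialization
  (`init="uniform"`) is available; on the synthetic selection benchmark it
  measurably tends to a local optimum in which correlated property sets
  imitate the planted signal.
- GA fitness relaxes the SMO stopping tolerance to 0.05 and caps
  iterations at 5000; the measured effect on CV MAE is below 0.01
  percentage points at about a third of the cost.  Final training and
  grid refinement use strict library defaults.

Hyperparameter refinement after selection ("grid refine") evaluates the
3x3x3 log2 neighborhood of the decoded genes by CV MAE and re-centres on
the best point while it sits on the searched cube's boundary, bounded by
the encoding's grid limits — a hill-climb rather than a 16^3 sweep, which
costs 4096 cross-validations per residue for no observed benefit on
separable fixtures.

## Spine analysis

Residues are classified on two axes: *hydrophobic* iff the Kyte-Doolittle
hydropathy index is strictly positive (exactly A, C, I, L, M, F, V) and
*exposed* iff RSA >= 25% (the threshold is inclusive by choice and
configurable).  Alpha-helices are maximal runs of DSSP code 'H' only
(3-10 and pi helices do not count).  The helix exposure degree is
AED = exposed residues / helix length.

The neighbor-ratio analysis tallies, for every exposed hydrophobic residue
i and offsets d = 1..6 within the same helix, the hydropathy class of the
neighbor at i + d when that neighbor is exposed, binned by helix AED
(10-point bins, last bin closed); the reported ratio is the
hydrophobic/hydrophilic tally quotient, missing on a zero denominator.

A **hydrophobic spine** is formalized as follows (the motif's verbal
description fixes neither length, interruption tolerance, nor maximality,
so these are package definitions, all configurable):

- members are exposed hydrophobic helix positions chained with successive
  gaps of 3 or 4 (one helical turn is ~3.6 residues, so such neighbours
  share a face);
- two members at gap 6, 7 or 8 may be linked through one bridging face
  position (the *interruption*) sitting at offset 3 or 4 from both; the
  bridge must not itself be exposed hydrophobic; for the ambiguous gap of
  7 an exposed bridge is preferred over a buried one (an exposed
  hydrophilic residue is the archetypal interrupter), ties breaking to the
  smaller offset;
- a call needs >= 3 members and allows <= 1 interruption by default (the
  known single-His interruption of the Trp-repressor helix motivates 1);
- calls are maximal: no other valid chain's member set strictly contains
  theirs.  *Perfect* means no interruptions.

Dataset scans filter helices by AED >= 90% by default before calling
spines, and report per-helix calls plus perfect/imperfect counts.

## Synthetic data: what it emulates, and what it does not

All fixtures are pure functions of (config, seed).

- `gen_chain` samples sequences from a uniform residue background, places
  non-adjacent helical runs of 10-22 residues to a target coverage, and
  draws helix RSA from a one-face exposure model
  rsa_i = 100 * sigmoid(a sin(2 pi i / 3.6 + phi)) + noise (coil RSA is
  uniform).  ASA is stored as integers so the DSSP-like writer round-trips
  exactly.  Profiles concentrate on the true residue (score ~7 vs ~-2).
  Because the exposure model is genuinely periodic, generated helices
  contain *natural* spines — planted-count assertions therefore use
  neutral hand-built fixtures.
- `plant_spine` rewrites one helix so that exactly the planted face chain
  is detectable: members become exposed Leu, listed interruptions exposed
  Ser, all other helix positions buried Ser.
- `gen_selection_benchmark` builds single-centre segments whose label is a
  smooth sinusoidal combination sum_j w_j sin(3 pi (f_j - 1/2)) of the
  informative properties' squashed window means, standardized to mean
  50 / sd 20, plus Gaussian noise (default sd 2 RSA points), clamped to
  [0, 100].  Two design points matter and were calibrated with pilot runs
  before the acceptance checks were frozen:
  1. the combination is *nonlinear* — window means of any ~20 independent
     properties span the window's 20-dim residue-composition space, so a
     linear target is predictable from generic property subsets and the
     planted set would not be identifiable;
  2. the synthetic property table is *correlated* (low-rank):
     `gen_property_table` draws each property as a shared rank-5
     component plus per-property jitter, emulating the strong
     collinearity of real amino-acid index collections.  With independent
     property vectors, generic 20-property masks can reconstruct the
     informative features almost exactly and the selection problem is
     deceptive by construction; with the realistic correlated table, the
     jitter component of an informative property carries signal no other
     property can express.
  The default benchmark size is 160 segments — enough for stable 10-fold
  cross-validation folds and for the nonlinear 5-property signal to be
  learnable near the label-noise floor.
- `gen_pcp_rsa_chains` produces chains whose RSA is a noiseless
  deterministic function of selected bundled properties, for end-to-end
  convergence checks of the regression stage.  That check trains the
  PCP+length feature stack: the profile block is uninformative for this
  particular target by construction and merely dilutes the RBF distance.

Passing tests on these fixtures demonstrate that the machinery — parsing,
feature assembly, selection, training, evaluation, spine calling — is
internally correct and recovers planted structure; they say nothing about
predictive accuracy on real proteins, which depends on real profiles,
real structures, and the full AAindex table (see docs/benchmark.md).

The bundled AAindex snapshot is synthetic apart from the real
Kyte-Doolittle entry; it exists so the package is self-contained, and its
version string and content hash are recorded in model archives (loading
verifies the hash).

## Numerical and degenerate-input choices

- logistic normalization is overflow-safe and rejects non-finite input;
- rsa_from_asa clamps to [0, 100] and rejects unknown residues;
- windows at chain termini pad with '-'; a window must keep its centre;
- groups with fewer than 10 labelled segments are skipped at training and
  fall back to the global-mean predictor at prediction time, as do
  residue letters without a model;
- CC is undefined (None) for n < 2 or zero variance rather than NaN;
- fold assignments are seeded and frozen per search/fit;
- all GA randomness flows from one seed via SeedSequence spawning, so
  equal seeds give bit-identical selections.

## Problem sizes used by the shipped checks

The acceptance checks run the selection benchmark at a reduced
configuration (population 20, r 20 -> 5, 2 runs) on 160 segments with 200
properties, train the end-to-end stack on 50 chains (10 held out), and
compare the spine detector against exhaustive enumeration on 500 random
helices of length <= 30.  These sizes are the package's chosen desk-scale
study conditions; the full-scale defaults (population 50, r 40 -> 10, 30
runs, 531 properties) are what `rsapred select-features` uses when given
real data.

## Known limitations

- The published benchmark numbers (test MAE 14.11%, CC 0.69) require the
  original dataset, its unpublished split, database-backed PSI-BLAST
  profiles and DSSP runs; they are out of desk-scale reach and the
  pipeline reproduces the procedure, not those constants.
- The GA operators are faithful to the printed rates and the
  popcount-r contract but the cited crossover/mutation internals are
  under-specified in the source material; ours are documented
  approximations.
- Only the classic DSSP text dialect is parsed (not mmCIF output), and
  only ASCII PSSMs (not binary checkpoints).
- The spine definition is a formalization of a verbal description; other
  reasonable formalizations (e.g. different bridge tie-breaks) yield
  slightly different call sets on ambiguous helices.
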