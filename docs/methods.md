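# Methods

## The character and its model

The analysed character is binary and orthogroup-level: "this hierarchical
orthogroup (HOG) contains at least one gene differentially expressed in
this species, in this direction".  Directions (up/down) are analysed
independently throughout; a HOG may be a DEOG in both.  Species with no
DEG in a HOG are coded 0 by default.  An alternative coding treats
species with *no gene at all* in the HOG as missing data (likelihood
vector (1, 1)); both are exposed because absence of a gene and absence of
regulation are genuinely different observations, and the default (0)
deliberately lets ancestral reconstruction absorb losses, lost
regulation, and uneven sampling into the same state.

Evolution of the character follows the two-state equal-rates Markov
model (Mk/ER): a single rate *q* per unit branch length for 0→1 and 1→0.
Its transition probabilities are closed-form,

    P(stay, t)   = (1 + exp(−2 q t)) / 2
    P(switch, t) = (1 − exp(−2 q t)) / 2,

verified in the tests against the matrix exponential of
Q = [[−q, q], [q, −q]] and against Chapman–Kolmogorov.  The stationary
distribution of ER is uniform, so the flat and "stationary" root priors
coincide; the equivalence is asserted in the tests rather than assumed.

Likelihoods use Felsenstein pruning with per-node rescaling; marginal
ancestral probabilities P(node = 1 | all tips) use an exact
inside–outside (up/down) pass — these are *marginal* reconstructions,
not joint ones.  Both are validated to < 1e−8 against brute-force
enumeration over all internal-state assignments on hundreds of random
trees.

## Rate estimation

*q* is estimated by bounded scalar maximum likelihood over log *q* in
[1e−8, 100] (scipy's bounded method, tolerance 1e−10 on log *q*);
estimates pinned at a bound, and likelihood-flat degenerate inputs, are
flagged `at_bound`.

`reconstruct_all` defaults to a **pooled** rate: one ML *q* over the
summed likelihood of all non-empty DEOG characters, then per-HOG
marginals at that rate.  The rationale: a single nine-tip binary
character carries almost no information about its own rate, and
per-character ML degenerates — homoplastic patterns push q̂ to
saturation, where every marginal collapses to 0.5 and the HOG becomes
unassignable.  On the standard planted fixture, per-HOG fitting recovers
62.8% of root-planted recruitments versus 82.6% for the pooled rate,
with the false-assignment rate staying at 2%.  `rate_mode="per_hog"`
(one fit per character, mirroring a per-trait call of a generic ASR
routine) and an explicit `pooled_q` remain available.

## Recruitment-node rule

Among internal nodes with marginal P(1) strictly above the threshold
(default 0.6; constrained to (0.5, 1)), the assigned node is the most
ancient — fewest edges from the root.  Ties are broken by larger
descendant-tip count, then lexicographic label; the convention matters
only when two disjoint clades pass simultaneously (convergent
recruitment), which the closest-to-root rule resolves deliberately
rather than reporting both.  If no internal node passes and exactly one
tip is observed in state 1, the DEOG is species-specific (assigned to
that tip); otherwise it is "unassigned".  All-zero rows are "not a
DEOG" and counted nowhere.

## Orthogroup origins and the permutation null

The origin (phylostratum) of a HOG is the MRCA of the tips possessing a
gene of it — the unique deepest node through which every single-gain
maximum-parsimony reconstruction passes.  Fitch scores are provided for
diagnostics and validated against exhaustive minimisation.  Origins are
computed on the analysis tree (the null's strata are defined per
analysis species).

The null preserves two nuisance margins exactly: each species' DEG
count, and the distribution of those DEGs over origin strata.  For every
(species, origin) stratum the observed number of DEGs is redrawn
uniformly **without replacement** (a gene is a DEG once) from that
species' genes residing in HOGs of that origin.  Replicates are re-coded
into DEOGs and each non-empty DEOG is assigned the MRCA of the species
carrying a resampled DEG (parsimony on the DEG-presence pattern).  Note
the deliberate asymmetry: observed counts come from the Mk pipeline
while null counts use the parsimony assignment; this mirrors the
method's published form and a same-method (`assignment_method="mk"`)
mode exists for sensitivity analysis.  Empirical p-values use the
add-one convention, p = (1 + #{replicates ≥ obs}) / (n_reps + 1), upper
and lower reported separately with no automatic two-siding; percent
change is 100·(obs − mean)/mean with a +∞ sentinel when the null mean is
zero.  Under self-null data the root-node p is uniform to Kolmogorov–
Smirnov precision (tested); the add-one convention and count ties make
it very slightly conservative.

## Enrichment statistics

Fisher's exact test uses the minimum-likelihood two-sided convention
(sum of hypergeometric point probabilities ≤ that of the observed
table, with the standard 1e−7 relative tie tolerance) — other
conventions (e.g. doubling) disagree on asymmetric tables.  The reported
odds ratio is the sample estimate ad/bc, not the conditional MLE; when
any cell is zero the Haldane–Anscombe +0.5 is applied to all cells for
the odds ratio only.  Stars encode raw p thresholds 0.05/0.01/0.001; no
multiple-testing correction is applied across nodes.  Trait modules are
the intersection of a trait gene set with the species' whole response,
so trait and background overlap by construction; the test is run on the
overlapping sets as-is, which is anti-conservative and documented rather
than corrected.  Node-by-node tables count DEOGs (not genes); a
gene-level variant can be built from the same primitives.

## Protein signatures

Protein features are computed after stripping one trailing stop symbol;
the alphabet is the 20 standard residues plus X, and residue proportions
sum to 1 per protein.  Signal peptides are *input* flags from an
external predictor.  The background for all release-module tests is the
supplied proteome minus the release set.  "Small" (≤ 150 aa),
"Cys-rich" (≥ 0.06) and "Pro-rich" (≥ 0.10) have no canonical values;
they are configuration parameters echoed into every report.  Welch's
t-test uses Satterthwaite degrees of freedom; two equal-mean constant
groups return t = 0, p = 1 by continuity, while constant groups with
different means are a hard error.

## Synthetic data: what it emulates, what it does not

Generators are pure functions of (parameters, seed) and their outputs
pass every reader's validation.  Defaults encode the study conditions:

| parameter | default | meaning |
|---|---|---|
| tree | 9 tips, uniform joins, Exp(1) branch lengths | small analysis tree in relative time units |
| n_hogs | 5 000 | orthogroup count at desk scale |
| gain weights | 0.4 root / 0.3 internal / 0.3 tips | mix of ancient and lineage-specific families |
| loss per branch | 0.05 | lineage-specific absence |
| genes per species | Poisson(2), min 1 | paralog multiplicity |
| recruit_fraction | 0.10, root-weighted | planted ancestral regulation |
| q_true | 0.3 | ER rate of regulation gain/loss below the recruitment node |
| DEG emission | logFC ~ N(3,1) clipped positive, FDR ~ U(0, 0.05) | significant rows |
| null rows | logFC ~ N(0, 0.5), FDR ~ U(0.05, 1) | background genes |
| fp_deg_rate | 0.01 | false-positive significant rows |
| planted proteins | 40–120 aa, rich-residue ≥ 0.10, signal peptide, one per new species-specific HOG | NCR-like / Pro-rich families |

Regulation is simulated under the *same* ER model the estimator fits
(the well-specified case), recruitment nodes are constrained to lie
within the clade where the family exists, and a DEG can only occur where
the species actually has a gene.  The generator does **not** emulate
read-level noise, expression-level correlation between paralogs,
between-contrast dependence, codon/GC structure, or rate heterogeneity
across branches (a misspecification study would need that extension), so
passing recovery tests demonstrate correctness of the inference
machinery under its own assumptions, not robustness to real-data
violations of them.

Recovery of planted root recruitments depends appreciably on the
realised tree: under Exp(1) branch lengths a 9-tip tree is often deep
enough (2q·depth ≈ 2) that tip states approach saturation, and measured
recovery ranged from ~31% to ~83% across tree seeds at identical
parameters.  The standard fixture (generator seed 11; recovery 82.6%,
false internal assignment 2.0%, both pinned in the tests) is therefore
treated as a fixed study condition.

## Problem sizes and numerics

Test and acceptance runs use: 200 random ≤ 6-tip trees for the
likelihood oracle, 100 ≤ 8-tip trees for parsimony, 2 000 characters on
64 tips for rate recovery, the 5 000-HOG fixture for recruitment
recovery, 100 datasets × 200 replicates for null calibration, and all
2 × 2 tables with margins ≤ 20 for the Fisher oracle — sizes chosen so
the whole suite runs on a laptop in a few minutes while keeping every
comparison exhaustive or statistically well-powered.  Identical DEOG tip
patterns share one reconstruction (the likelihood depends only on the
pattern), and the null model assigns nodes via cached species-bitmask →
MRCA lookups, which is what makes thousands of replicates cheap.  The
pipeline derives one child seed per stage from the global seed by
hashing the stage name, so adding a stage never perturbs earlier random
streams, and reruns are byte-identical.

## Known limitations

- Two states only; no rate heterogeneity across branches or characters
  (beyond the pooled/per-character choice); no joint reconstruction.
- The recruitment threshold 0.6 is a robustness heuristic, not a
  calibrated error rate; assignments near the threshold are unstable.
- The null's parsimony/Mk asymmetry (above) is faithful but means
  observed and null counts are not computed by the same estimator.
- The candidate presence/absence filter and species-specificity
  judgements are only as good as the orthogroup inference consumed.
- Missing branch lengths default to 1.0; the package does not estimate
  branch lengths.
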