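# Methods

This note documents the models, estimators and design choices behind
`cuprome`, in the spirit of the methods documentation that simulation and
statistics packages ship alongside their APIs.  Nothing stated here is an
empirical claim beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## Profile-HMM homolog search

### Scoring model

Remote homologs of copper-resistance proteins are found by scoring each
protein against position-specific profile HMMs.  The scorer is a
plan-7-style **local Viterbi** in log2-odds (bits):

* emission score of residue *a* at match state *k* is
  `log2(m_k(a) / bg(a))`; insert states likewise against their own
  emission rows; transitions score `log2(t)`;
* the alignment may enter at any match state and leave at any match
  state; flanking unaligned residues cost 0 bits, so a single-residue
  alignment is legal and the optimum is never driven negative by flanks;
* the ambiguity residue `X` scores 0 bits at any state; other
  non-standard residues are rejected rather than guessed at;
* one best alignment is reported per (model, protein) pair, with its
  1-based residue envelope.

This is a deliberate stand-in for a full hmmsearch pipeline: there is no
MSV filter, no forward-algorithm statistics, and no multi-domain
reporting.  Correctness is guaranteed not by matching any external tool
bit-for-bit but by exact agreement (to 1e-9) with an exhaustive
enumeration of every legal alignment path on small instances — the
brute-force oracle lives in the test suite and shares no code with the
dynamic-programming implementation.  Zero probabilities are floored at
`log2 p = -1e30` rather than `-inf` so the vectorised recurrences stay
NaN-free; no optimal path can traverse such a transition because a
finite-score single-residue alignment always exists.

### E-values

Bit scores convert to expectations under Gumbel statistics:
`E = N * (1 - exp(-exp(-lambda (s - mu))))`, with `N` the number of
proteins searched.  Calibration fixes `lambda = ln 2` (one bit halves the
tail probability, the classical slope for log2-odds local scores) and
fits `mu` by the method of moments on scores of 200 background-sampled
decoy sequences: `mu = mean(scores) - EulerGamma / lambda`.  The decoy
length defaults to `max(100, L)`.  This is a pragmatic calibration for
synthetic benchmarks, not a claim of HMMER-equivalent statistics; the
properties that matter downstream — monotone decreasing in score, linear
in `N` — are exact.  The hit threshold `evalue <= 1e-30` is inclusive.

Note one numerical corner: more than ~40 bits *below* `mu` the survival
function saturates to exactly 1.0 in double precision, so strict
monotonicity in the score holds only outside that saturated region.

### Profiles from alignments

So the engine is testable without downloading TIGRFAM/COG/Pfam models,
profiles can be estimated from a small alignment: columns with gap
fraction ≤ 0.5 become match states; emissions use Laplace pseudocounts
`(count + alpha) / (n + 20 alpha)` (default `alpha = 0.5` for fixture
construction; 0.3 where sharper profiles are wanted); the background is
the overall alignment residue frequency with the same pseudocount; and
transitions are counted from the observed per-sequence state paths
(plan-7-forbidden I↔D adjacencies are dropped).  One consequence of
estimating the background from the same counts: substituting a residue
that never occurs in the alignment produces an emission/background ratio
identical to a singly-observed residue's, so such a mutant *ties* the
generating sequence rather than scoring strictly below it.  Substitutions
to residues seen elsewhere in the alignment strictly lower the score.
The property tests assert exactly this.

### HMMER3 ASCII files

Models are read and written in the HMMER3 ASCII dialect (`HMMER3/f`
header family): probabilities stored as negative natural logs with `*`
for zero, optional `STATS LOCAL VITERBI mu lambda` line, 20-column
emission rows and 7-column transition rows per node.  Parsing errors name
the offending line.  Round-trips preserve probabilities to 1e-9 (the
writer emits 9 decimals), and a cross-check test parses a file written by
the HMMER toolkit itself (via pyhmmer) and compares every probability.
The final node's exit transitions are conventional (`M->E = 1`) and are
normalised on read.

## Resistome counting

A protein hit by several models is assigned to the model with the
smallest e-value (exact ties broken by lexicographically smallest
accession, for determinism).  Counting is per protein, post-dedup; a
protein's category is its retained model's category.  The shipped
catalog maps 17 accessions onto {Cue, Cus, CopPco, Multisystem}:
models whose reference proteins span multiple systems (the
CueO/PcoA/CopA oxidase model and the two-component sensor and regulator
models) are Multisystem; the Cu(I)-ATPase model sits under Cue, with a
one-call override (`ModelCatalog.with_category`) for analyses that
prefer it displayed separately.  The e-value sensitivity sweep applies
filter-then-dedup independently at each threshold; the number of
distinct hit proteins is non-decreasing as the threshold loosens, which
the suite asserts (per-category counts need not be monotone, since
dedup reassignments can move proteins between categories).

## Homolog retention filter

Candidates are retained when **similarity > 0.45 (strict)** and
**0.40 ≤ length ratio ≤ 1.50 (inclusive)**.  Similarity is the fraction
of alignment columns whose residue pair has a positive BLOSUM62 score,
with gap columns counted in the denominator, computed on an optimal
*global* alignment under affine gaps costing `open + k * extend`
(defaults 11 + k, the BLAST convention; realised in Biopython's
`PairwiseAligner` as open score −12, extend −1).  An independent Gotoh
dynamic program in the tests confirms the scores.

Two caveats are worth stating.  First, "% similar" as printed by BLASTP
is a local-alignment positives fraction; the global definition here is
self-contained and deterministic but will not numerically reproduce
BLASTP percentages (e.g. published pairwise values for specific protein
pairs).  Second, the two gates interact: under the global definition a
candidate at the 0.40 length-ratio boundary can reach at most 0.40
similarity (end gaps fill the denominator), so the boundary suites probe
the two gates separately.

## Core-cluster detection

The five cluster roles — merR regulator, copA ATPase, cupredoxin-domain
protein, DUF2933/hypothetical protein, isoprenylcysteine
carboxylmethyltransferase — are assigned from case-insensitive product
keywords.  A bare "hypothetical protein" earns the DUF2933 role only
when its immediate role-bearing neighbours are the cupredoxin and icmt
genes, which keeps the genome's many unrelated hypotheticals role-less.
A product matching two roles' keywords is an error (ambiguous rules)
rather than a silent choice.

Cluster calling walks each replicon's genes in coordinate order and
forms maximal runs of role-bearing genes, tolerating at most
`max_intervening` (default 1) consecutive role-less genes inside a run.
A run becomes a call when it contains a copA anchor and at least
`min_roles` (default 3) distinct roles; completeness is `full` iff all
five roles are present.  "Immediately upstream" is operationalised as
adjacency in gene order; orientation is recorded but not constrained.
Calls are invariant under whole-replicon coordinate translation.

Genomic-island annotation consumes precomputed interval sets (BED,
0-based half-open; GFF3 coordinates are 1-based inclusive and converted
at the boundary).  The strict default flags a cluster only when *every*
member gene's midpoint lies inside some island interval; a lenient
any-member mode sits behind a flag.  Replicon class (chromosome vs
plasmid) comes from a caller-supplied manifest, never inferred.

## qPCR analysis

Reference-gene screening uses the BestKeeper SD criterion: the sample
standard deviation (n−1 denominator) of all CT values for the candidate
across conditions and replicates, stable iff **SD < 1 cycle (strict)**.

Relative expression uses the ddCT method.  Per replicate,
`dCT = CT(target) − CT(reference)`; `ddCT = mean(dCT treated) −
mean(dCT control)`; `fold = 2^(−ddCT)`; results are reported as log2
fold changes.  The calibrator is the mean control dCT — replicate
pairing across conditions is not assumed.  Significance testing is
normality-gated: Shapiro-Wilk on each group, both `p ≥ 0.05` → two-sided
Welch t-test (unequal variances, the safer default when "t-test" is
unqualified), otherwise two-sided Mann-Whitney U.  Groups smaller than 3
cannot be normality-tested and fall back to Mann-Whitney with a warning
— note that with n = 3 per group the exact two-sided Mann-Whitney can
never reach p < 0.05, which makes the procedure conservative at the
study's replication level; the null calibration check (2000 seeded
replicates) measures the realised type-I rate at roughly 3–5%.
Significance is `p < 0.05`, with no multiple-testing correction by
default (a Benjamini–Hochberg option exists behind a flag).

## Synthetic data

The generators define the benchmark conditions:

* **Proteomes** — decoys sampled i.i.d. from a uniform 1/20 background
  (configurable); planted homologs are substitution-only mutants of
  reproducible per-accession seed proteins (default length 120, family
  identity fixed by a `family_seed` shared with the profile builder), so
  Hamming distances are exactly binomial and oracle checks stay exact.
  Default benchmark scale: 100 decoys of length 80–160, planted copies
  at 10% divergence.
* **Replicons** — genes of fixed length (900 bp) and spacing (150 bp)
  laid left to right; planted clusters inserted as contiguous
  role-product genes at deterministic positions; island intervals
  generated to exactly cover on-island clusters (plus one decoy island
  per replicon), never predicted.  Replicon lengths of 60–80 kb keep
  generation instant while leaving realistic coordinates.
* **CT tables** — reference CT ~ Normal(15, reference_sd 0.3); target CT
  = 20 − log2FC + Normal(0, noise_sd 0.2) with n = 3 biological
  replicates, mirroring a two-timepoint, three-concentration induction
  design.  The means are arbitrary and documented; only differences
  enter ddCT.

What the generators deliberately do **not** emulate: indels and
selection in sequence evolution, operon structure and strand biases,
amplification-efficiency differences between assays, and technical
(well-level) replication.  Passing the round-trip suites therefore
demonstrates algorithmic correctness against planted truth, not
robustness to every artefact of real survey data.  In particular, the
planted-homolog benchmark at 10% divergence is an easy recognition
problem by design — it validates the machinery, not remote-homology
sensitivity at the twilight zone.

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); per-accession streams are derived with a
stable string hash so outputs are independent of dictionary order and
platform.

## Problem sizes

The default suites use scales chosen to keep any single check under a
couple of minutes on one core: 200 random instances for the Viterbi
oracle, a 105-protein proteome against 5 calibrated models for recovery,
five thresholds for the sweep, a two-replicon genome with 5 planted
clusters, 250 simulation replicates per planted effect for ddCT bias and
2000 for null calibration.
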