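# Methods

This note documents the models, statistics and design choices behind
`tctransfer`, in the order data flows through the pipeline.

## Datasets and family labels

A dataset is one organism's set of transporter records: an amino-acid
sequence (20-letter alphabet plus `X`), a TC family id and zero or more
substrate-class labels. TC ids are truncated to the 3-part family
(`class.subclass.family`) for all comparisons, since annotation databases
commonly disagree on (or omit) the subfamily digit. Three label kinds are
supported: `tc`, `substrate`, and the combined `substrate_tc`
(`"<substrate>_<TCfamily>"`, split at the right-most underscore because
substrate names may themselves contain underscores). A record with several
substrate annotations appears under one label per substrate; the sequence
is stored once and the duplication is purely label-level.

Two datasets are reduced to their *shared* families before benchmarking: a
label is eligible in a dataset when at least `min_members` records carry it
(default 2 — transferring a label from a held-out family member requires at
least one other member; motif discovery uses 3, since a position-specific
model estimated from fewer sites is vacuous), and the shared set is the
intersection of the eligible sets.

## Homology engines and E-value normalization

The local engine is an affine-gap Smith–Waterman over an integer
substitution matrix (BLOSUM62 default; a gap of length L costs
`gap_open + L·gap_extend`, default −11/−1). Significance uses
Karlin–Altschul statistics, `E = K·m·n·e^(−λS)` with query length `m` and
database residue count `n`. Gapped λ and K are not computable in closed
form, so the published gapped constants for BLOSUM62/−11/−1 (λ = 0.267,
K = 0.041) are carried as configurable scheme fields; the ungapped λ is
available by numerically solving `Σ fᵢfⱼ e^(λ·sᵢⱼ) = 1` (bisection to
|f| < 1e-9). Only the scale behaviour of E matters to the benchmark — the
normalization and threshold sweep are invariant to a constant factor.

The global engine scores full-length pairs (Needleman–Wunsch) and derives
significance from a shuffle null: the partner sequence is shuffled
`n_shuffles` (≥ 30, default 50) times, the observed score standardized, and
the upper normal tail taken as p; the raw E-value is `p · db_sequences`, a
per-sequence statistic.

Normalization removes the database-size dependence so thresholds are
comparable across searches: alignment E-values are divided by the database
residue count, per-sequence statistics (the global engine, probabilistic
per-target tables) by the number of reported hits. The hit count is taken
per query — the natural reading when searches are run one query at a time —
with a switch for per-run counting. External tools are supported through
parsers only (12-column tabular alignment hits; whitespace-delimited
per-target tables in the HMMER3 `--tblout` column layout).

Determinism: hits are always ordered by (normalized E ascending, raw score
descending, target id); DP tracebacks prefer diagonal, then vertical, then
horizontal moves and report the first row-major optimum. The alignment
kernels are jit-compiled (numba) so the full-size synthetic benchmarks run
in seconds; correctness is pinned by brute-force enumeration oracles and an
independent cross-check against Biopython's `PairwiseAligner` in the tests.

## Motif discovery and scanning

Discovery fits the ZOOPS model ("zero or one occurrence per sequence") by
EM: a sequence contains a motif site with prior γ, uniformly located.
The E-step computes posterior site probabilities from the likelihood ratio
of PWM vs background over every window; the M-step re-estimates the PWM
from posterior-weighted counts with pseudocount `0.01·background` and γ
from the posterior site mass. Iteration stops when the log-likelihood
changes by less than 1e-6 (relative) or after 200 iterations; the EM
log-likelihood is non-decreasing by construction and asserted in tests.
Starting points are seeded from the W-mers present in the input (smoothed
one-hot PWMs, match probability 0.55), each scored by a single EM pass;
repeated W-mers are always kept and unique ones fill up to 150 candidates,
subsampled with the run seed when there are more — the only stochastic step.
After each motif, its best site per sequence (posterior mass ≥ 0.5) is
hard-masked, so successive motifs occupy disjoint sites. Width is fixed per
run (default 15); multi-width search is out of scope. ZOOPS rather than
OOPS because real families contain members lacking a motif.

Scanning scores every window by the log₂-odds sum. The site p-value is
exact: scores are integer-scaled (×100) and the null score distribution of
a background window obtained by dynamic-programming convolution of the
per-column distributions. The sequence p-value treats windows as
independent, `1 − (1 − p_site)^(L−W+1)`; a family's k sequence p-values are
combined by the product rule with correction
`P = p · Σ_{i<k} (−ln p)^i / i!` (exact for independent uniforms, and equal
to the single p-value at k = 1), and the combined E-value multiplies by the
number of test sequences. Tests verify calibration empirically: on pure
background the 0.05-level rejection rate is ≈ 0.05 (the window-independence
approximation and score discreteness cost at most a couple of percent).
PWMs export to bracket-notation regular expressions (per column, residues
with probability ≥ 0.2 in descending order; a column with no residue at
threshold falls back to its single best residue) and to MEME minimal
format.

## Classification and evaluation

A query is classified at threshold t when its best hit satisfies
normalized E ≤ t ("better than" read inclusively; configurable to strict).
If the best target carries several labels of the evaluated kind, the true
label wins when present (mirroring the label-level duplication), otherwise
the lexicographically smallest — a deterministic, documented tie-break.

Unclassified queries are excluded from the confusion cells entirely: they
carry no prediction, so they inflate neither false negatives nor any
denominator, and are reported as a separate percentage. This is what makes
the strict-threshold pattern possible (e.g. > 80% unclassified together
with > 80% recall). Precision, recall and F are computed **per family
first** and then averaged with family-member-count weights; weighting uses
the query-side (test-set) member counts, configurable to reference-side.
The per-family-then-average order matters: the aggregate F is generally not
the harmonic mean of the aggregate P and R. True negatives are kept in the
cells for completeness but enter no reported metric.

The cross-tab analysis bins, for every pair of `substrate_tc` labels across
the two organisms, the best normalized E-value over all member pairs:
`bin = max(0, #{t ∈ grid : E < t} − 1)`, i.e. 4 (black) for E < 1e-20 down
to 0 (white) for nothing better than 1e-8, written as TSV and a grayscale
heatmap.

## Synthetic benchmark generator

The generator emulates the structure the benchmark assumes, not transporter
biology: each family is an ancestor drawn i.i.d. from a background
composition (uniform by default; a hydrophobic-enriched "membrane-like"
preset exists), and every member in each organism is one independent
mutation pass from the ancestor — substitutions at a per-site rate with
replacements drawn from the background excluding the current residue, and
geometric-length indels at a per-site event rate (a deletion never consumes
the final residue). Two members are thus separated by two passes;
controllable divergence is the goal, so no within-organism phylogeny is
modelled. Defaults (6 families, 5 members per organism, 400 residues,
substitution rate 0.1, indel rate 0.01, geometric p 0.5) describe a
moderately diverged family set; the end-to-end analyses in the tests and
acceptance script use 4 families × 5 members at length 400 with rates
{0, 0.1, 0.3, 0.5}, sizes at which the full pipeline runs in seconds per
rate on one core.

Substrate labels cross-cut families: the default plan assigns each of the
four canonical substrate classes to two families, and a family listed under
k substrates has its members partitioned round-robin (by member index,
identically in both organisms) among them. This within-family substrate
diversity is what real TC families show — large families host transporters
of several substrates — and it is the mechanism behind the benchmark's
headline contrast: a query's best hit is typically a family sibling with,
roughly half the time, a different substrate, so substrate-kind precision
falls below TC-kind precision while the unclassified rows coincide.
Families outside the plan fall back to the `other` class. Optional motifs
are planted post-mutation at a random admissible position per member, each
motif position keeping the consensus residue with probability
`conservation` and otherwise drawn from the background, so conservation
alone controls motif divergence and the planted intervals are recorded in
the ground truth.

What passing synthetic tests does **not** show: real transporters are not
i.i.d. background sequences (transmembrane composition bias, repeats and
paralogy structure are absent), family divergence is not homogeneous, and
real substrate annotations are noisy and incomplete. The synthetic results
validate the machinery and its qualitative behaviour, not the absolute
threshold values one would quote for real organisms.

## Numerical and degenerate-input choices

* Raw E-values are floored at 1e-300 so reported values stay positive.
* A degenerate shuffle null (sd = 0, e.g. homopolymers) yields p = 1 with a
  warning rather than an error.
* Metric conventions: precision/recall/F are defined as 0 when their
  denominator is 0; the weighted average requires a positive total size.
* EM on degenerate input (all sequences identical) still converges and
  returns a motif; sequences shorter than the motif width are skipped
  during scanning with a log entry.
* All stochastic stages consume a single seeded generator per run;
  identical configurations reproduce outputs byte-for-byte.

## Known limitations

* Gapped λ/K are scheme constants, not estimated from the data; absolute
  E-values from the built-in engines are approximate (edge effects are
  ignored), though monotone in score and correctly scaled in m·n.
* The built-in engines are exact DPs without heuristic seeding; they are
  meant for benchmark-sized datasets, not genome-scale search.
* Motif discovery is fixed-width, ungapped, and searches a single best
  starting point per motif; it can lock onto a strong paralogy signal
  rather than a compact motif when families are highly redundant.
* The sequence p-value's window-independence approximation makes combined
  p-values slightly conservative for long sequences.
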