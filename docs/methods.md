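# Methods

## The evaluation problem

A peptide–TCR binder predictor maps a (peptide, CDR3) pair to a real score,
higher meaning more likely to bind.  Experimental data provide positives
only, so every benchmark must manufacture negatives, and the choice of
manufacture changes the answer:

- **Background-drawing** samples negatives uniformly without replacement from
  a large background repertoire, excluding the peptide's known binders.
  These negatives are antigen-irrelevant and easy; classifiers that merely
  memorize positive-labelled TCRs still look perfect.
- **Reshuffling** permutes the TCR column across the known positive pairs
  (rejecting permuted pairs that are themselves known positives).  Every
  negative TCR binds *some* peptide, so TCR-identity shortcuts fail and the
  false-positive rate of a memorizing model inflates.

Neither strategy can exclude *unknown* cross-reactive binders.  Background
draws exclude only each peptide's known positives (switchable); reshuffled
negatives may contain true cross-reactive pairs.  This is a documented bias
of the methodology, not something the framework resolves.

Balanced multi-fold evaluation holds the positives fixed and redraws the
negative set per fold (fold `i` seeds its draw with `seed XOR i`, masked to
31 bits).  This is deliberately *not* a partition of the positives: the point
of repeating folds is broader coverage of the negative space, and the
fold-to-fold spread of ROC-AUC / PR-AUC is itself a reported outcome.  The
sign-flip paired resampling test in `compare_scorers` operates on fold-wise
differences between two scorers on shared folds.

## Stratification

Peptides are grouped by their number of distinct known binders: majority
(≥ 100), few-shot (5–100), zero-shot (< 5).  The 100-binder boundary is
assigned to the majority group; `GroupThresholds(majority_min=101)` selects
the strict "more than 100" reading.  Exactly five binders is few-shot.
Duplicate (peptide, TCR, label) rows collapse before counting; a pair seen
with both labels is dropped entirely (no resolution rule exists, so the
conservative choice is to trust neither row).  Peptides with zero binders
cannot form a task and are skipped with a warning.

## Virtual screening and BEDROC

Screening scores a peptide against the entire candidate library, in chunks
(default 10,000 sequences; chunking is an execution detail and never changes
the scores — scorers must be pure functions of (peptide, TCR) identity).
Scores are materialized for one peptide at a time and reduced to binder ranks
before the next peptide is screened, so retained state is O(chunk + ranks),
never a peptides × library matrix.  Ties rank by library index (stable);
a mid-rank policy is available for BEDROC via `midrank_binder_ranks`.

With `N` candidates, `n` true binders at ranks `r_i`, and `R_i =
(r_i − 1)/(N − 1)`, the default BEDROC variant is

    BEDROC_α = α/(1 − e^(−α)) · (1/n) Σ e^(−α R_i)

Because `E[e^(−αR)] = (1 − e^(−α))/α` for uniform `R`, the expectation under
random ranking is exactly 1 and the maximum (all binders first) approaches
`α/(1 − e^(−α))`, ≈ 20.000000041 at the default α = 20.  This relative form
is the framework's default and is what all tests and reports use; the
conventional Truchon–Bayly form bounded to [0, 1] is offered as
`variant="truchon_bayly"` for comparability with the virtual-screening
literature and is never silently substituted.  The often-quoted heuristic
that α = 20 concentrates ~80 % of the weight on the top 1 % of ranks does not
hold for this weight function (the top 1 % carries `(1 − e^(−0.2))/(1 −
e^(−20))` ≈ 18 % of the weight; 80 % corresponds to roughly the top 8 %), so
no such statement is encoded in tests.

Hit rate at k is the fraction of a peptide's binders inside the top k.
Success rate at k — not a standardized quantity — is implemented with the
virtual-screening convention: the fraction of query peptides with at least
one binder in their top k.  The default top-k grid is {0.01 %, 0.1 %, 1 %,
5 %, 10 %} of N.  Group-level BEDROC is the unweighted mean over the group's
per-peptide screens; a pooled variant (all normalized binder ranks in one
summation) is available via `group_bedroc="pooled"` and weights peptides by
their binder counts instead.

The screening universe is the background library plus every task's known
binders: a binder's rank is undefined unless it is among the candidates.

## Classification metrics

ROC-AUC and PR-AUC are computed through scikit-learn (`roc_auc_score`,
`average_precision_score`), whose definitions coincide with the
pairwise-concordance (ties = ½) and step-wise average-precision forms the
framework specifies; tests verify this against a brute-force concordance
oracle.  Confusion matrices use a fixed 0.5 threshold on scorer outputs;
scorers whose outputs leave [0, 1] are min-max normalized per fold.  These
are pragmatic defaults for comparing scorers, not calibrated decision
thresholds.

## Synthetic benchmark generator

The generator emulates the *shape* of a curated multi-peptide binding table:
heavy-tailed binder counts spanning all three groups, plus a large disjoint
background repertoire.  Defaults (the study conditions used throughout the
tests and the acceptance script): 20 peptides split 4/10/6 into
majority/few-shot/zero-shot with binder counts drawn uniformly from 100–150,
5–100 and 1–4 respectively; a 100,000-sequence background; peptides of
length 8–12; CDR3s of length 10–18 framed C…F; motif length 4; binder
threshold 1.0 (exact motif containment).

Binding is a hidden per-peptide motif: affinity of (peptide, CDR3) is the
best ungapped window identity between the motif and the CDR3 (≤ 1), and a
pair is a binder iff affinity ≥ threshold.  Binders are generated by motif
implantation; candidate binders containing any *other* peptide's motif are
rejected, and background sequences are rejected against all motifs, so
emitted labels regenerate exactly from affinity + threshold and an oracle
scorer is genuinely perfect.  For paired α/β data the motif splits in half
across the chains and pair affinity is the mean of the per-chain affinities,
so both chains carry signal and score fusion is testable.

Built-in scorers: `oracle` (true affinity), `noisy_oracle` (affinity +
Gaussian noise, default sd 0.05), `random` (uniform), and
`tcr_memorization`, which scores by TCR identity alone — high iff the TCR
binds *any* peptide — operationalizing the memorization failure mode that
reshuffled negatives expose.  Scorer noise is derived by hashing
(seed, peptide, TCR) rather than drawn from a sequential stream; this keeps
scores independent of batch order and size, which the chunk-invariance
contract requires, at ~1 µs/pair cost.

What passing tests on this generator do **not** show: real CDR3s have
V/J-templated ends, position-dependent residue composition, length–locus
correlations and many-to-many cross-reactivity; real binding is not a single
contiguous motif.  The generator validates the *evaluation machinery*
(balance, leakage-freedom, calibration, enrichment arithmetic, strategy
gaps), not the biological difficulty of the prediction task.

## Numerical and design choices

- Reshuffling is implemented as permutation with bounded retries plus greedy
  swap repair; infeasible instances (e.g. a single peptide, or one peptide
  owning all but one positive) raise rather than silently under-deliver.
  Ratios > 1 run multiple permutation rounds with cross-round duplicate
  rejection.
- Sampling is without replacement within a fold, with replacement across
  folds; identical `SamplingSpec` reproduces folds byte-for-byte across
  process restarts.
- Validation defaults: peptides 8–15 aa, CDR3s 6–30 aa, uppercase 20-letter
  alphabet; all configurable (`ValidationRules`).
- Curation filter defaults (alphabet + length bounds) are an explicit
  reconstruction, labelled as such in logs and reports; exact-string dedup,
  no CDR3 trimming (a normalization hook exists but is off by default).
- Peptide-level fold splits (`make_peptide_folds`) are seeded round-robin
  after shuffling: sizes differ by at most one and no peptide spans folds.
- Aggregation reports mean, sd, min, max and fold count; both sd and range
  are given because "variance" claims in this literature are ambiguous
  between the two.
- Test and acceptance-script problem sizes (2,000–100,000-sequence
  libraries, 3–100 folds, 2,000 calibration replicates) were chosen so the
  statistical assertions have tight Monte-Carlo error while the full suite
  runs in about a minute; they are the package's own defaults, scaled from
  the methodology rather than from any particular dataset.

## Known limitations

- No similarity-aware ("hard negative") mining; negatives are exact-match
  exclusions only.
- No MHC/HLA modelling, V/J annotation, or nucleotide-level input.
- The paired sign-flip test is the only significance machinery; no
  multiple-testing correction across metric × group × strategy cells.
- Offline score tables must enumerate every (peptide, TCR) pair queried;
  missing entries fail that peptide's screen (collected in the failure
  report) rather than being imputed.
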