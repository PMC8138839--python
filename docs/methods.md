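# Methods

## Model

A transcript is modeled as a path through an explicit-duration (semi-Markov)
hidden Markov chain.  Two architectures share their emission models:

**Full-transcript architecture.**  `UTR5 → Start → fullCDS → Stop → UTR3`,
with `UTR5` the only initial state and `{UTR3, UTR5}` final.  The `UTR5`-only
ending gives every sequence an admissible *no-CDS* path, so non-coding input
can yield "no prediction" rather than a forced call.  Both UTRs may have
length zero (transcripts that begin at the ATG or end at the stop codon); a
zero-length UTR carries an explicit estimated probability.

**Partial-transcript architecture.**  Adds a generic `UTR` prefix state
(sharing the 5′UTR emission model, configurable) and three 5′-truncated
coding states `pCDS0/1/2`, one per codon phase of the fragment's first base.
Admissible beginnings are `UTR`, `Start` or any `pCDSf`; admissible endings
are `UTR3`, `UTR`, `fullCDS` or any `pCDSf` (a coding state ending the
sequence represents a missing stop codon).  Both architectures allow at most
one contiguous coding region per transcript.

### State types

* *Geometric states* (UTRs): segment length `d ≥ 1` contributes
  `log(1−p₀) + (d−1)·log q + log(1−q)`, with `p₀` the zero-length
  probability and `q` the self-loop probability; a segment censored by the
  sequence end omits the exit term.  Emissions are order-`k` Markov chains
  (default `k = 3`).
* *Fixed states* (`Start`, `Stop`): exactly 3 bases, hard-constrained to
  `ATG` / `{TAA, TAG, TGA}` (a codon containing `N` never matches).  A
  positional weight matrix scores a window anchored at the codon: the three
  owned bases contribute raw log-probability, flanking columns contribute
  log-odds against the trained overall base composition.  The log-odds form
  matters: flank columns re-score bases emitted by neighboring states, and
  raw re-scoring would attach a constant penalty (≈ −10 nats here) to every
  path through `Start`/`Stop`, which in the partial architecture — where
  `pCDSf` paths bypass `Start` — systematically biased decoding against
  start-bearing paths on short-5′UTR transcripts.
* *Explicit-duration states* (`fullCDS`, `pCDS0/1/2`): emissions are
  3-periodic Markov chains (default order 4) threaded through the segment
  from the state's phase; lengths follow a fitted duration law (below).
  `fullCDS` durations are quantized to codon multiples; `pCDS` durations are
  not.

### Hard translatability constraints

Inside any coding segment, complete in-frame codons may not be stop codons
(−∞, not merely disfavored), and a coding segment followed by `Stop` must
end on a codon boundary.  Together with the fixed-state constraints this
guarantees that every call carrying both completeness flags starts with
`ATG`, ends with a stop codon, has length ≡ 0 (mod 3) and translates without
internal stops — by construction, not post-filtering.

### Decoding

Exact explicit-duration Viterbi over segment boundaries.  The inter-state
graph is required to be acyclic (true of both architectures), so states are
processed in topological order; geometric states use an O(L) max-plus scan,
fixed states an O(L) shift, and explicit states a bounded duration search
over the positions where the state can be entered (after `ATG` anchors this
set is sparse, making decoding ~3 ms for a 600-nt transcript).  The duration
search horizon is the fitted support plus ten geometric-tail means.  All
arithmetic is in natural-log space.  Ties are broken deterministically:
coding endings are scanned before UTR-only endings, longer durations before
shorter, and the plus strand before the minus strand in strand-blind mode.
A brute-force enumeration oracle (`transcds.oracle`) shares the emission
primitives but not the dynamic program and verifies the decoder exactly on
toy problems.

"No prediction" (an inadmissible input, or a best path without a coding
segment, or a coding path that fails the score margin against the best
UTR-only path) is an outcome, not an exception.

## Training

Fully supervised counting from complete annotated transcripts — no
expectation-maximization.  Per GC bin:

* per-phase codon chains from in-frame CDS-interior positions (start and
  stop codons excluded), conditioning contexts taken from the sequence
  itself (they may cross segment boundaries, which makes chain scores
  additive over splits);
* UTR chains from the annotated UTR regions; start/stop positional matrices
  from aligned windows (start: offsets −6..+5, a Kozak-sized context; stop:
  the stop codon plus 3 downstream bases);
* `fullCDS` durations from CDS interior lengths (length − 6), `pCDS`
  durations from simulated uniform truncations of the training CDSs with a
  150-nt retained-sequence floor (no natural partial training data exist);
* zero-length-UTR probabilities and mean UTR lengths from region presence
  frequencies, Laplace-smoothed.

All count tables use pseudocount 1 per cell; chain contexts observed fewer
than 10 times back off recursively to their shorter suffix context.
Defaults: CDS order 4, UTR order 3, three GC bins `[0,0.45) [0.45,0.55)
[0.55,1]`, minimum 50 training transcripts overall and 30 per bin; sparse
bins borrow the nearest populated bin (recorded in the bundle metadata).
Emission orders and windows are configurable; they are this package's own
defaults, chosen as standard gene-finder practice.

**Duration estimator.**  Histogram on the step grid over the observed
support, Gaussian-smoothed (σ = 9 nt default), renormalized to `1 − t` where
the tail mass `t` defaults to the Laplace exceedance estimate `1/(n+1)`; the
geometric tail decay matches the mean excess of the upper decile.  An
earlier fixed tail mass demonstrably inflated the fitted mean on refits
(tail mass × maximum length dominates); the exceedance form makes
sample → refit approximately mean-consistent, which the parameter-recovery
check requires.

**Architecture probabilities without a supervised estimate.**  Which
completeness scenario a partial fragment is in has no training signal, so
the partial architecture uses flat priors: initial `{UTR, Start, pCDS0,
pCDS1, pCDS2}` at 0.2 each, and stop-codon-present probability 0.5 for
coding states.  Emissions and durations dominate decoding; these priors only
arbitrate near-ties.

**Bundles.**  Versioned JSON with a sha256 checksum over the canonical
payload; log-probabilities at full double precision.  Loading verifies
format, version, checksum, count non-negativity and distribution
normalization; decoding is bit-identical across a save/load round trip.

## Synthetic data

The generator emulates mature mRNA structure: 5′UTR + `ATG` (with a shaped
Kozak-like upstream context) + an in-frame run of sense codons (no internal
stops by construction) + a stop codon + 3′UTR, plus compositional negatives
drawn from the 3′UTR base distribution ("ncRNA-like", no secondary
structure).  Study conditions are presets: the *strong-signal* preset draws
one fixed, strongly non-uniform codon-usage table (sparse Dirichlet, fixed
internal seed so the table does not vary with the corpus seed) against
AT-rich UTRs; the *weak-signal* preset is near-uniform in both.  Default
lengths: CDS log-normal around 110 codons (minimum 40), 5′UTR geometric mean
60 nt, 3′UTR geometric mean 150 nt, zero allowed for both UTRs — round
numbers of the magnitude typical for compact eukaryotic mRNAs.  An optional
mean-GC target is enforced per sequence by bounded rejection.

What the generator does **not** emulate: sequencing/assembly error,
chimeras, heterogeneous codon usage within a corpus, structured ncRNA,
introns, multi-ORF transcripts.  Passing tests therefore demonstrate
correctness of the machinery and attainable accuracy *when the model family
matches the data*, not accuracy on real transcriptomes — on real data the
emission families are approximations and accuracy will be lower.

A second sampler draws transcripts directly from a fitted parameter set (the
model's own generative reading).  For parameter-recovery experiments it
disables the internal-stop rejection so that the sample law is exactly the
estimated model: the estimator, not the decoder, is under test.

## Evaluation protocol

Positive sets are scored under two criteria: *stop_match* (predicted stop
codon position and strand equal the reference; on the minus strand the stop
codon sits at the interval start) and *full_cds_match* (start, end and
strand all equal).  No call is a false negative; any other call is a false
positive.  Precision = TP/(TP+FP), Recall = TP/(TP+FN),
F1 = 2PR/(P+R), all with the 0-conventions for empty denominators.
Specificity on negative sets (where any call is a false positive) is
reported in two clearly-labeled forms that always sum to one: the
*printed form* FP/(FP+TN) — a false-positive rate — and the *standard form*
TN/(TN+FP).  Neither is silently "corrected" into the other.

Derived validation sets from a complete corpus (seeded, byte-reproducible):
strand-specific; strand-blind (a random half reverse-complemented);
*no-start* (5′ pruned at a uniform point inside the CDS, eliminating the
start codon), *no-stop* (3′ pruned), *no-start-no-stop* (both, retaining
only CDS interior) — truncation points are uniform over the admissible
range subject to a 150-nt minimum retained length, falling back to pruning
exactly at the codon when the source is too short; 3′UTR-only negatives; and
a mixed coding/non-coding run (full + partial transcripts shuffled among
≥200-nt negatives) with a truth table.

## Problem sizes used by the checks

Chosen to make every quantity statistically meaningful at desk scale:
decoder-vs-oracle on 200 random toy architectures (≤3 states, sequences
≤12 nt — enumeration is exponential); parameter recovery with 2000 sampled
transcripts against a model fitted on 400; end-to-end accuracy with 1000
training and 500 held-out transcripts (strand-specific, strand-blind and
the truncated sets all at n = 500); negatives at n ≈ 300–500.  The recovery
metric is the occupancy-weighted mean total-variation distance per context
(the expectation under the generating process); unweighted means over all
4^k contexts are dominated by contexts that essentially never occur and
measure nothing about recovery.

## Known limitations

* The *no-stop* scenario is intrinsically hard under this architecture: a
  CDS missing its stop codon ends mid-codon, but `fullCDS` durations are
  codon-quantized, so exact 3′ fragment ends are recovered only when the
  truncation happens to fall on a codon boundary.  Whole-fragment accuracy
  on no-stop sets is accordingly much lower than on the other partial sets
  (the stop-codon side of the protocol is unaffected).
* The partial architecture's flat scenario priors make it eager on pure
  compositional negatives: a `pCDSf` path needs no anchoring codon, so the
  partial model's false-positive rate on ncRNA-like sequences is far higher
  than the full model's.  Classification defaults to the full model for this
  reason; a positive score margin tightens both.
* One CDS per transcript by design; polycistronic or multi-ORF transcripts
  are out of scope.
* `N` bases are scored neutrally (log 1) and never satisfy the ATG/stop
  anchors, so calls never begin or end inside runs of `N`.
* Transition/initial probabilities of the partial architecture are priors,
  not estimates; see above.
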