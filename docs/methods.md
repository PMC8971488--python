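# Methods

This note documents the model behind `shapesearch`, the parameter choices
that matter, the numerical conventions, and what the synthetic benchmark
does and does not demonstrate.

## Signal model and assumptions

A reactivity profile is treated as a one-dimensional continuous signal
indexed by nucleotide position.  The working assumption is that local
secondary structure leaves a characteristic footprint on this signal
(runs of low reactivity inside helices, high-reactivity loops and
bulges), and that structurally homologous regions therefore exhibit
*shape-similar* profiles up to an affine transform of the measurement
scale and modest positional warping.  Two consequences drive the design:

* Comparisons are z-normalized (seeding) or capped (extension), so the
  method tolerates differences in probe chemistry and normalization
  between query and database.
* Local insertions/deletions between homologs are absorbed by affine-gap
  alignment rather than by resampling the signal.

Missing values (positions without usable signal) are first-class: they
never match in seeding and contribute zero to alignment columns.

## Seeding

K-mers of the query are filtered by the Gini coefficient of their capped
reactivities (cutoff 0.3 at k = 15; 0.4 for pairing-probability data).
The Gini statistic is scale-invariant and distinguishes windows that
straddle structure transitions (informative) from flat windows inside a
single paired or unpaired run (uninformative, and a source of spurious
matches).

Lookup uses MASS: with the entry spectrum computed once per
(entry, k), sliding dot products for all query k-mers come from one batch
of FFTs, and the z-normalized distance follows from window means and
standard deviations maintained with cumulative sums.  Windows containing
missing values, or whose standard deviation is below `1e-7 ·
max(1, |mean|)` (numerical guard for constant windows), are unmatchable.

**Match cutoff.** An offset is a match when the z-normalized distance is
at most `dist_coeff · √k`; √k makes the per-position discrepancy
length-independent, and `dist_coeff` is the package's main calibration
knob.  The default 0.6 corresponds to a window correlation of ≥ 0.82 and
was fixed once by a two-sided measurement on the synthetic profile family:
at 0.6, background offsets match at ~1/160 nt before the GC filter
(~1/280 nt after), safely below the promiscuity limit of one match per
200 nt, while planted homologs at reactivity noise sd 0.15 retain the
majority of their seed k-mers (median true-match distance ≈ 0.33 √k).
Looser cutoffs (≥ 0.8) are unusable on realistic autocorrelated profiles:
background matching becomes so frequent that the promiscuity filter
discards every k-mer.

The GC filter (default 10 percentage points at k = 15, disable with
`max_gc_diff=None`) reflects the limited local GC variation of
structurally related RNAs; N bases count toward neither the numerator nor
the denominator of a window's GC fraction.  The promiscuity limit is
`total database length / kmer_max_match_every_nt` with a floor of one so
that single matches in very small databases survive.

Matches on a common diagonal within `max_kmer_dist` (30 nt) chain into
HSGs of at least `min_kmers` (2) members.  Diagonals are exact; indels
are the extension stage's job.

## Extension

Scoring: for capped reactivities with difference d and boundary
t = `match_boundary_fraction` × `max_reactivity` (default t = 0.5):

    d ≤ t:  score = match_max − (d/t) · (match_max − match_min)
    d > t:  score = mismatch_max − ((d−t)/(max_reactivity−t)) · (mismatch_max − mismatch_min)

with the SHAPE defaults (match −0.5…2, mismatch −6…−0.5) this runs
continuously from +2 at d = 0 to −6 at d = 1.  Columns with a missing
value score 0.  Sequence mode adds +0.5 for identical A/C/G/U bases and
−2 otherwise (N never matches).  A gap run of length L costs
`gap_open + L · gap_ext`.

The DP is a three-state Gotoh recursion filled anti-diagonally from the
seed edge.  The band half-width at anti-diagonal s is
`max(10, ⌈band_fraction · s/2⌉)` (band_fraction default 0.1), capped at
`max(10, ⌈2 · band_fraction · n⌉)` for a query flank of length n — a cap
that cannot exclude a score-optimal endpoint, since reaching further off
the diagonal requires gap runs whose affine cost exceeds any attainable
pair reward.  Extension in a direction terminates when the best score of
the anti-diagonal has stayed below `max_dropoff_rate` × the global best
for more than `max_dropoff_bases` consecutive anti-diagonals, or at a
profile end; the alignment is the traceback from the global-best cell.
Traceback ties prefer pair > gap-in-db > gap-in-query, making output
deterministic.  The DP window is allocated lazily (doubling only when an
extension genuinely reaches its boundary without drop-off); this is an
allocation strategy, not a change of the explored cell set.

Seeds whose query and database spans both lie inside an
already-extended alignment of the same entry are skipped; the duplicates
they would produce are exactly those removed afterwards by the >50%
dual-overlap deduplication rule (best score kept).

## Significance

Decoy databases are built by permuting 10-nt blocks of each entry
(preserving local structural context), 100 shuffles per entry by default,
keeping a uniformly placed chunk of ≤ 1000 nt from each.  Per query
window, the best alignment score against each chunk — with 0 for chunks
yielding no HSG, so empty trials are not silently dropped — forms a
sample of maxima to which a Gumbel distribution is fitted by the method
of moments (β = s·√6/π, μ = x̄ − γβ; maximum likelihood available via
`method="ml"`).  At least 50 trials are required.

    p = P(S_null ≥ S) = 1 − exp(−exp(−(S−μ)/β))

**E-value multiplier.** Each null trial measures the best score over one
chunk-sized stretch, so E multiplies p by the number of chunk-sized
search units in the real database (total length / mean decoy length,
floored at the entry count).  Using the raw entry count would understate
E whenever entries are longer than the chunks: before this convention was
fixed, chance 50–140-nt alignments passed E ≤ 0.01 at roughly an order
of magnitude above the nominal rate on a 50-kb database of 5-kb entries.

Empirically (shuffled-vs-shuffled searches at 200 trials), null p-values
are close to uniform with Kolmogorov–Smirnov statistics of ~0.06–0.12
across seeds — the residual excess over the pure-sampling expectation
reflects the finite-sample Gumbel approximation to the true distribution
of banded-extension maxima.

## Pipeline

Long queries are cut into 200-nt windows with 100-nt overlap (a 1542-nt
query gives 15 windows).  Default reporting thresholds are E ≤ 0.01
(reactivity only) and E ≤ 0.005 (with sequence scoring).  Window matches
to the same entry merge when their query intervals touch and their
alignment diagonals agree within 20 nt (`require_diagonal=False` relaxes
the diagonal check); the merged region keeps the best E-value.
Benchmark labelling supports the relative-genomic-position rule (±2% of
genome length by default, 0% for exact) and, for synthetic fixtures,
exact planted-interval overlap.

## Consensus-structure evaluation

The folding engine is injected.  The production adapter writes the
alignment in Clustal format and shells out to RNAalifold with per-row
SHAPE restraint files under the Deigan conversion (slope/intercept per
reagent: 2A3 1.0/−0.4, NAI 1.1/0.0, NAI-N3 2.4/−0.6); shuffled
alignments are folded with the same restraints as the true alignment, so
the null reflects column order only.  Columns shuffle in 3-column blocks
(block order, then within-block order), rows and both tracks moving as a
unit.  Significance is the lower-tail normal probability of the true
consensus energy's Z-score against the shuffled-energy null (sd with
ddof = 1; a zero-variance null reports p = 1).  Retention requires
p < 0.05 and canonical (AU/GC/GU) base-pair support ≥ 0.75 *in every
row* — the strictest reading of per-sequence support; `support_mode=
"mean"` relaxes to the row average.

## Synthetic data

`random_profile` draws a two-state (paired/unpaired) Markov chain with
stationary unpaired fraction 0.4 and persistence 0.85 (mean run ≈ 6–7
nt), emitting from a low gamma mode (shape 0.8, scale 0.07) in paired
state and a truncated normal (0.85 ± 0.30) in unpaired state.  These
values were chosen once so that the generated profiles behave like real
probing data where it matters for this engine: 15-mer Gini coefficients
mostly above the 0.3 cutoff (median ≈ 0.55), realistic autocorrelation
(which is what makes the seeding calibration non-trivial), and block
shuffling that preserves local context.  What the generator does *not*
emulate: probe-specific reactivity scales, position-dependent coverage
and missing-value patterns, correlated noise between homologs, or true
thermodynamic consistency between sequence and signal.  Passing the
benchmark therefore demonstrates the engine's statistical machinery and
calibration on structured signals, not performance on any particular
real dataset.

`plant_homology` copies a query region into an entry, adds Gaussian
reactivity noise (truncated at 0) and substitutes bases independently to
hit a target sequence identity.  The benchmark plants 50 such 200-nt
queries (noise sd 0.15, identity 0.8) into a 50-kb database of ten 5-kb
entries — sized so a full two-mode run takes a few minutes on one CPU —
using 10 shuffles per entry (100 null trials per window, comfortably
above the 50-trial floor).  Against exact planted-interval truth the
engine reaches sensitivity 1.0 with FDR ≤ 2% at E ≤ 0.01, and sequence
scoring never worsens the E-value of a true match.

## Known limitations

* The MASS cutoff, band geometry, drop-off bookkeeping and E-value
  multiplier are this package's own documented conventions; other
  implementations of the same seed-and-extend idea may differ in these
  details, so scores and E-values are comparable within `shapesearch`
  runs, not across tools.
* Gumbel calibration rests on ~100–200 empirical maxima per window; far
  tails (p ≪ 1e−6) are extrapolations.
* The promiscuity filter can silence genuinely repetitive structural
  elements together with low-information k-mers.
* Fold evaluation requires ≥ 2 rows and treats the consensus energy as a
  black box from the engine; no covariation statistics are computed.
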