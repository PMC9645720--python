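# Methods

`oriscape` reimplements, as a tested library, a computational analysis of
mutagenesis at human DNA replication origins: origin-centered metagene
profiling of mutation rates and replication strand bias, positional
mutational-signature extraction and refitting, origin sequence statistics,
feature-anchored functional enrichment, and an in silico model of origin
sequence evolution. Every stage is exercised against a synthetic-data
generator with known ground truth, so the package is self-validating
without external downloads.

## The coordinate frame

All origin-centered analyses share one frame (`origins_io.OriginDomainSet`):
each origin midpoint anchors a domain of `2 * half_width` bases divided
into fixed windows. Defaults are `half_width = 10_000` and
`window_size = 100`, giving 200 windows over a 20-kb domain; the
DSB-style analyses use the same machinery with `half_width = 2_500`.
Coordinates are 0-based half-open internally; BED is read as-is and VCF's
1-based positions are converted at the I/O boundary. Window `w` covers
`[midpoint - half_width + w*window_size, ... + window_size)`, so the
origin midpoint itself falls in the first window right of center
(window 100 at defaults).

Isolated-origin selection drops any origin whose `half_width`
neighbourhood (closed interval) contains another midpoint of the same
class; the check is symmetric, so clustered origins remove each other.
Efficiency stratification splits the empirical efficiency distribution at
its tertiles, boundary values going to the lower bin.

## Profiles and normalization

A `ProfileMatrix` holds per-origin, per-window values (NaN = masked) plus
a per-window aggregate. Background normalization divides by the mean of
the first and last `n_edge_windows` (default 20) aggregate values — the
domain edges serve as the local background, so 1.0 means "no enrichment
over flanks" and the operation is invariant to overall scale.
Composition-corrected rates divide each pyrimidine substitution class by
the window's count of eligible bases (C+G for C-rooted, A+T for T-rooted
classes) before normalization; purine-reference SNVs fold into the
pyrimidine frame by complementing both alleles.

Replication strand bias for substitution type b→m is
`log2((n_fwd + c) / (n_rev + c))` per window, where `n_fwd` counts SNVs
whose written reference base is the pyrimidine and `n_rev` the purine
complement. The pseudocount `c = 0.5` keeps the log finite in empty
windows; its bias vanishes as counts grow, and raw counts are always
carried alongside. Loess smoothing (tricube local linear regression via
statsmodels, span 0.2) is display-only and never feeds statistics.

Quantile-bin association tests bin origins into covariate quantiles by
rank (so ties cannot empty a bin) and compare per-bin count totals to an
expectation proportional to bin sizes with a chi-square test,
`df = n_bins - 1`. All chi-square tests in the package omit the
continuity correction; the choice is configurable where it matters.

## Signature analysis

SNVs are classified into the 96 canonical channels (six pyrimidine
substitution types × 16 flanking contexts, channel order pinned and
written into every output header). Indels follow the 83-channel COSMIC
scheme: 1-bp events by affected base (pyrimidine-folded) and homopolymer
run length; longer events by adjacent tandem-repeat copies; repeat-free
deletions by microhomology length (longest shared prefix with the right
flank or suffix with the left flank, capped at `min(length-1, 5)`).
Events are left-aligned before classification and flank scanning is
capped at 50 bp, which is ample for channels capped at 5+/6+.

De novo extraction uses Kullback–Leibler multiplicative-update NMF,
implemented in-package so that per-run seeding, the monotone-descent
guarantee, and the consensus bookkeeping are all inspectable. Each
extraction runs `n_runs` factorizations (default 50; the stability survey
in rank selection uses 30; a flag raises this to 1000) from independent
random initializations spawned from one master seed, and reports the
best-divergence run with signatures normalized to probability rows and
exposures rescaled compensatingly.

Rank selection computes, per candidate rank, the cophenetic correlation
of a Brunet-style consensus matrix and returns the smallest rank before
the first drop (drops within 1e-6 count as ties, so a numerically flat
plateau is traversed). The consensus is built on the **channel** axis —
each channel is assigned to the signature giving it the highest
probability, per run — rather than on windows. With a flat background
process dominating most windows, window labels are identical across runs
at every rank and their cophenetic stays ≈1 monotonically, carrying no
rank information; channel assignments are stable up to the true rank and
fragment beyond it, producing the plateau-then-drop shape the selection
rule needs. Average linkage is used for the cophenetic computation.

Refitting is per-window non-negative least squares against a reference
catalog. Strict refitting backward-eliminates: repeatedly drop the
signature whose removal lowers the overall reconstruction cosine least,
while that drop stays within `max_delta` (default 0.004); ties break
toward the smaller total exposure, then name order, so results are
deterministic. Polymerase attribution is the same strict fit restricted
to a four-signature proofreading-deficiency catalog, with four-parameter
logistic fits of the per-window attributions against absolute distance
from the midpoint (multistart over midpoint/slope, since the 4PL surface
has flat local optima).

## Sequence features

AT skew `(A-T)/(A+T)` and GC skew `(G-C)/(G+C)` are computed per window
with N bases excluded from denominators. G-quadruplexes are maximal
greedy matches of `G{3+}(N{1-7}G{3+}){3}`; the minus strand is scanned by
applying the same motif to the reverse complement and mapping coordinates
back, which makes the two strands exactly symmetric (a literal C-motif
scan on the written strand is not reversal-symmetric under overlaps).
CpG islands follow the Gardiner–Garden rule (200-bp windows, GC ≥ 0.5,
observed/expected CpG ≥ 0.6), merged and then trimmed to the outermost
CpG so boundaries are sharp.

The Shannon diversity index pools the overlapping 6-mers of all sequences
per window and computes `-Σ p_i ln p_i` (positive convention, natural
log; the cap is ln 4096 ≈ 8.318). Because SDI depends on depth, the
rarefaction correction subsamples each window's k-mer multiset to a
common depth (the smallest window depth unless given) and averages over
20 seeded repetitions.

The Markov generator estimates order-k transitions from training k-mer
counts; observed rows are used exactly and unseen states fall back to a
uniform row (an optional pseudocount adds conventional smoothing), so
degenerate training text reproduces itself. Generation is vectorized
across sequences and fully determined by the seed.

## The evolution model

Three fitted rules drive the simulator:

* **PDF-1** (where): baseline plus a multipeak Gaussian profile fitted to
  the background-normalized mutation-rate profile; the number of peaks
  (1–4) is chosen by BIC and the curve is clipped at zero.
* **PDF-2** (what): a strict refit selects the operating signatures; each
  signature's relative per-window exposure is fitted with a Gaussian or
  sigmoid curve (lower weighted residual wins, windows weighted by their
  mutation totals). The substitution distribution at offset x and
  pyrimidine-frame context ctx is
  `P(alt) ∝ Σ_s exposure_s(x) · sig_s(channel(ctx, alt)) / freq(ctx)`,
  renormalized over the three alternates; `freq` is the target library's
  own trinucleotide composition, computed once at fit time, which is what
  corrects for compositional bias when mutating naive sequences.
* **PDF-3** (which strand): per substitution type, the raw per-window
  forward proportion `n_fwd/(n_fwd+n_rev)` is fitted with a
  Gaussian-or-sigmoid curve clipped to [0,1], weighted by window counts.
  Pseudocounted ratios are deliberately not used here: they bias sparse
  windows toward 1/2 and shift the recovered plateau probabilities.

Each round, every sequence draws `mutations_per_round` (default 100)
distinct positions with probability proportional to PDF-1 (Gumbel top-k;
sequence ends lacking a full context are excluded, and PDF-1 is
implicitly renormalized over the remaining positions). Each site's
context is read as written, folded to the pyrimidine frame, an alternate
is drawn from PDF-2, and with the PDF-3 probability the pyrimidine-frame
substitution is applied to the written strand, otherwise its complement.
The per-sequence interpretation of "100 bases to mutate" is the default;
a pool-level alternative is available behind a flag. Snapshots are stored
at dyadic rounds (1, 2, 4, …, 4096) up to `max_rounds` (default 5000);
the run stops early when mean library GC changes by less than 1e-4 over
three consecutive snapshots. Trajectory reports compute windowed GC,
skews, and SDI per snapshot and RMSE against observed target profiles.

Two analytic controls pin the engine down: with uniform substitutions and
strand probability 1/2 the stationary composition is uniform (each base
1/4), and with GC-forcing substitutions under uniform selection the GC
trajectory follows `1 - (1-GC_0)(1-q)^t` with `q` the per-site mutation
probability; both are asserted in the tests.

## Enrichment

PWM scanning extracts the 25-nt context (variant ± 12) and scores every
offset on both strands with natural-log odds against the context's own
smoothed base frequencies; "no strand information" is read as
strand-agnostic merging. Hits require relative score ≥ 0.95, raw
log-odds > 10 (the threshold unit is configurable since it is stated
without units), and the motif span covering the variant. Per-motif
enrichment contrasts (motif, variant) hit-pairs between feature groups in
2×2 chi-square tests and reports observed −log10 p against uniform
quantiles (QQ); an optional Benjamini–Hochberg column is available but
the headline call follows the QQ report.

cis-QTL load is significant QTLs per covered base within ±2.5 kb of
features, compared between origin-marked and origin-free groups with a
2×2 chi-square on counts versus base totals. Significance means
q ≤ 0.05; the source material prints the comparison the other way around,
which is almost certainly a typographical slip, so the direction is
configurable rather than silently fixed.

## The synthetic study

The generator (`synthetic_data`) emulates the study inputs with explicit
truth: a single 20-Mb chromosome (iid bases, GC 0.41), 400 origins on a
jittered grid with ≥25-kb spacing (so all are isolated by construction),
gamma-distributed efficiencies split into tertiles, and 2×10⁵ SNVs from
three components — a flat background (50%), a Gaussian center component
(25%, σ = 400 bp, origin choice proportional to efficiency), and a
flanking "volcano" component (25%, peaks at ±1.5 kb, σ = 600 bp) with a
central dip. Components carry distinct substitution preferences
(background C>T/T>C-rich like a clock-like process; center C>G/T>G-rich;
volcano C>A/T>A-rich), and the two origin components place variants with
written-pyrimidine probability 0.75 left of the midpoint and 0.25 right.

Because the written strand of a fixed reference base cannot be chosen,
strand bias is produced by orientation-constrained rejection sampling of
positions; with a complementary-symmetric genome the acceptance rate is
exactly 1/2 per orientation, so the realized orientation probability
equals the configured one. Truth signatures are defined as the effective
channel distributions — configured alternate-given-context probabilities
times the genome's pyrimidine-frame trinucleotide frequencies — so
channel marginals match them exactly by construction, and they are what
recovery is scored against.

Indels are planted before variants are drawn: 16,000 homopolymer runs
(5–8 bases) receive 1-bp slippage events, and 8,000 cassettes near origin
centers are edited so that deleting 6 bases leaves exactly ≥5 bp of
microhomology without a full tandem repeat. Coverage tracks (center,
volcano, flat control) have peak heights proportional to efficiency plus
Gaussian noise. Feature tables plant configurable fold-increases of
functional variants and significant QTLs at origin-marked TSSs, and a
GC-rich motif is written into the genome at marked features.

What the generator does **not** emulate: real human base composition
structure (isochores, repeats), linkage and allele frequencies,
chromatin, replication timing, or selection. Passing tests therefore
demonstrate that the algorithms recover planted structure under the
stated noise models — not that the biological conclusions replicate on
consortium data, whose headline numbers depend on inputs outside this
package's scope.

## Problem sizes and numerical choices

The default test-suite study uses a 2-Mb genome with 40 origins and
2×10⁴ SNVs; the signature-recovery and rank-selection checks run ten
repetitions at the full default configuration (20 Mb, 400 origins, 2×10⁵
SNVs, 30 NMF runs per rank over ranks 2–5). Evolution controls run at
100 sequences × 5 kb × 512 rounds. These sizes were chosen so the whole
suite completes in minutes on one core while keeping every recovery
margin comfortably away from its threshold.

Degenerate inputs are handled explicitly: all-equal efficiencies collapse
to a single bin with a warning; zero background means raise rather than
divide; windows with no eligible bases or no coverage are masked (NaN)
and excluded from background means; zero-count substitution types fit a
flat 1/2 strand curve; constant count matrices select rank 1 with a
warning. NNLS-based attributions can exceed observed totals by a small
least-squares overshoot; they are reported as fitted, not clipped.

## Known limitations

* Per-signature strand-bias attribution (which variants belong to which
  signature before computing bias) is not implemented; the attribution
  method is underdetermined and was excluded from scope.
* The ID83 homopolymer category for a run of five is the "5" class, not
  the 5+ cap — the cap is 6+ for deletion runs, following the 83-channel
  scheme exactly.
* The evolution engine mutates substitutions only (no indels) and models
  no selection or fixation dynamics.
* `merge_same_origin` matches nearest-first one-to-one; a different
  matching (e.g. maximum bipartite) could pair a handful more origins in
  dense clusters.
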