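# Methods

This note records the models, parameter choices, and numerical decisions
behind `sgatools`, in the package's own words. Interfaces are documented
in the README and docstrings; this file explains *why* things are the way
they are.

## Data model

A sample is a sorted stream of records `(chrom, feature, position,
strand, count)` — the SGA format. Every analysis assumes:

- each record stands for `count` identical tags at one 1-based position;
- strands `+`/`-` mark the 5′ end of the sequenced fragment on the
  respective strand; `0` marks unoriented or already-centered tags;
- sort order is byte order of the lines: chromosome lexicographic,
  then position, then strand `+` < `-` < `0`.

One-pass algorithms over this order are the design constraint: every
operation either consumes a sorted stream in a single sweep (correlation,
scoring, filtering, centering, compaction, peak calling, partitioning) or
is a k-way merge of sorted streams. The correlation engine locates each
reference's target window with binary search on per-chromosome position
arrays (O(N log N) overall); an explicitly two-pointer O(N) sweep would
save the log factor but not change any result, and the binary-search
form is simpler to verify against the brute-force oracle.

## Correlation and aggregation

For reference positions *p* (count *c_r*) and target positions *q*
(count *c_t*), the offset is *d = q − p*, negated when the reference is
on the − strand and `oriented` is set. Offsets fall in half-open bins:
bin *i* covers *[b + i·w, b + (i+1)·w)*, i.e. index ⌊(d − b)/w⌋ for
*b ≤ d < e*. Half-open bins were chosen so that every admissible offset
belongs to exactly one bin and profiles over adjacent ranges tile without
double counting; the mirror identity (swapping reference and target
reverses the profile) then holds exactly away from bin edges, which the
tests exercise with odd offsets.

Contributions are weighted by *c_r · c_t*: a record with count *k* is *k*
tags, for references as well as targets. The extraction matrix uses the
same weighting per cell so that its column sums equal the aggregate
profile exactly. The `score` operation, by contrast, appends the plain
target total in *[p + b, p + e]* without multiplying by the reference's
own count — the score annotates the reference record, it does not
aggregate over copies of it; the conserved quantity (tested) is
Σ *c_r · score_r* against the pair-weighted total.

## Fragment-length estimation and parameter recommendation

The 5′–3′ strand cross-correlation of a point-source ChIP sample peaks
at the mean fragment length L, because + and − tags from the same
binding event sit L apart. We fit

  h(d) = B + A·exp(−(d − µ)² / 2σ²)

by least squares (`scipy.optimize.curve_fit`, amplitude and σ bounded
positive), initialized from the profile itself: B₀ = median, A₀ = max −
B₀, µ₀ = argmax bin center, σ₀ = HWHM/√(2 ln 2).

**Flat-profile verdict.** The fit is declared non-converged when the
optimizer fails *or* when A ≤ max(2·RMSE, 10⁻⁸·scale) with scale =
max(|h|∞, 1). The 2·RMSE test is the substantive criterion — a peak must
beat the residual noise; the 10⁻⁸·scale floor exists because an exactly
constant profile fits with RMSE ≈ 0 and a vanishing positive amplitude,
which would otherwise pass the noise test on numerical dust.

Recommendations from a converged fit:

- centering distance = round(µ/2) — half the fragment length;
- window w = max(1, round(κσ)) with κ = 2√(2 ln 2), the full width at
  half maximum: the natural footprint of one binding event in the
  centered-tag autocorrelation;
- threshold T = smallest integer t ≥ 2 with P(Poisson(λ_bg·w) ≥ t) < α,
  α = 10⁻⁴ by default, λ_bg = total count / genome length. The floor of
  2 tags avoids degenerate single-tag "peaks" in very sparse samples.

## Peak calling

Candidates are the tag positions themselves. A candidate at *p* scores
W(p) = Σ counts at |q − p| ≤ ⌊w/2⌋ (an odd effective width of
2⌊w/2⌋ + 1 bases, symmetric around *p*). A candidate is suppressed if a
candidate within the vicinity *v* has a strictly higher score, or an
equal score at a smaller position — leftmost-wins makes the output
deterministic and order-independent. Optional refinement reports the
count-weighted mean position of the window, rounded half-up (⌊x + ½⌋),
a fixed convention chosen over banker's rounding so that refined
positions are reproducible across platforms and obvious by hand.

The fold-based threshold is T = max(2, ⌈f · λ · (2⌊w/2⌋ + 1)⌉): the
smallest integer count at least *f* times the expected background count
in one window.

## Partitioning

The segmentation maximizes Σ over chosen disjoint segments of
C(a, e) − ρ·(x_e − x_a) − p, where C is the total tag count in the
segment, x its end positions (segments start and end on tags), ρ a
density penalty per base, and p a fixed penalty per segment. The dynamic
program keeps, at tag k, the best total using tags ≤ k and a running
maximum of (best_{a−1} − P_{a−1} + ρ·x_a) over admissible segment starts
a (P = prefix counts), giving O(n) time. Two tie-breaks make the optimum
unique and tested: when extending ties with not extending, the shorter
(non-extending) choice wins; among equal-scoring starts, the earliest
start wins. Score comparisons use an absolute epsilon of 10⁻⁹ to keep
traceback decisions stable under floating-point noise. Strands are
pooled; output uses the regions dialect (`+` start line, `-` end line,
segment count on both). An independent re-scorer recomputes every
reported segment's score directly from the tag stream; tests require it
to match the DP total and, on small inputs, the exhaustive enumeration
over *all* disjoint segment sets.

ρ can be set from a fold *f* over the sample-average density λ as
ρ = f·λ; useful values sit between the background density (below which
everything merges) and the in-domain density (above which domains
fragment).

## Synthetic generators

Two generators provide ground truth for validation. Both are
deterministic functions of a single integer seed (`numpy`
`SeedSequence` spawned per chromosome, so outputs are stable under
chromosome-set changes), and both emit sorted, compacted SGA.

**Planted-site ChIP** models point-source binding: each site produces a
fixed number of reads; each read's fragment center is the site position
plus Gaussian jitter (sd `center_jitter_sd`); the tag is the fragment's
5′ end — `center − L//2` on `+` or `center + L//2` on `-`, strand chosen
fairly; tags falling off the chromosome are redrawn. Background tags are
Poisson-uniform at `background_rate` per base per strand. The model
deliberately omits mappability variation, duplicated reads, copy-number
structure, and fragment-length dispersion: it is the minimal model for
which fragment-length estimation and peak calling have exact expected
answers.

**Planted domains** draws tag counts per base from a piecewise-constant
Poisson density: given intervals at stated densities, background
elsewhere, strand `0`. It likewise omits any correlation structure
within domains.

## Validation choices and problem sizes

The end-to-end checks in `tests/test_acceptance.py` and the quantities
reported by `scripts/acceptance.py` use a transcription-factor scenario
of 200 sites spaced 10 kb on two 1.005 Mb chromosomes (fragment length
150 bp, jitter sd 20 bp, 50 reads per site, background 5·10⁻⁴ per base
per strand — a 10× signal:background density ratio) and a domain
scenario of twenty 5 kb domains at density 0.1 tags/bp on a 2 Mb
chromosome with 0.01 background. These sizes are the package's own
choice: large enough that the Gaussian fit and Poisson thresholds
operate in their intended regime (≈10⁴ tags), small enough that the full
suite runs in seconds.

Domain segmentation in those checks uses **ρ = 0.04 and p = 20**.
Rationale: ρ must separate the planted density (0.1) from background
(0.01); 0.04 ≈ 2.7× the sample-average density (~0.015) sits in that
gap. p = 20 exceeds the score any background noise run can accumulate
(a run of k background tags spanning ℓ bases scores ≈ k − ρℓ, and with
λ_bg/ρ = 0.25 such runs almost never reach 20) while costing only a
small fraction of a true domain's score (≈ 0.1·5000 − 0.04·5000 − 20 =
280). These values were fixed from pilot simulations on seeds disjoint
from the test seed, before the test was run.

**Boundary error definition.** Domain-boundary accuracy is measured
against each domain's *realized tag extent* — the first and last
simulated tag inside the planted interval — not against the planted
interval endpoints. Segments begin and end on tags, so the realized
extent is the best recoverable boundary; the gap between a planted
endpoint and the nearest tag inside is a property of the random sample
(mean ≈ 1/density ≈ 10 bp per side here), not of the segmenter. The
reported mean boundary error (≈6–9 bp across seeds) is therefore an
error of the algorithm, on top of which a user should expect the
sampling gap when interpreting boundaries biologically.

All five streaming engines (profile, matrix, scoring, region filtering,
peak calling) are additionally tested bin-for-bin against independent
brute-force O(R·T) reimplementations on hundreds of randomized fixtures,
and the partitioner against exhaustive enumeration of all disjoint
segment sets on inputs of up to 12 tags.

## Limitations

- Single-nucleotide positions only: analyses that need fragment overlap
  (e.g. coverage pileups) require conversion choices upstream.
- The Gaussian fit assumes a unimodal cross-correlation; samples with
  strong phantom peaks at the read length may need the fit range (`-b`,
  `-e`) restricted.
- The fold-based thresholds assume a globally uniform background; locally
  variable backgrounds (copy number, open chromatin bias) need external
  control samples via the `ratio` normalization or region filtering.
- The partitioner's segments start and end on tags; empty flanking
  regions of a biological domain are invisible to it by construction.
- Chromosome order is plain lexicographic byte order; inputs sorted
  "naturally" (chr2 before chr10) must be re-sorted with `sgatools sort`.
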