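# sgatools

Streaming analysis of ChIP-seq and related tag data in the SGA
single-position format: format conversion, correlation/aggregation plots,
Gaussian fragment-length estimation, peak calling, and genome
partitioning into enriched domains — plus synthetic data generators for
validation.

## The scientific problem

Chromatin immunoprecipitation sequencing (ChIP-seq) measures where a
protein binds DNA. Sequencing yields millions of short reads; after
mapping, the only information a downstream analysis needs from each read
is a single genomic coordinate — the 5′ end of the sequenced fragment —
plus its strand. Reducing mapped reads to counted single positions makes
genome-wide analyses both compact and fast: every operation in this
package is a one-pass algorithm over a sorted stream of such positions,
so whole-genome inputs are processed in essentially linear time and
constant-to-small memory.

Typical questions answered with these tools:

- *How long were the immunoprecipitated fragments?* The cross-correlation
  between 5′ ends on the + strand and 5′ ends on the − strand peaks at the
  average fragment length; a Gaussian fit estimates it.
- *Where are the binding sites?* After shifting each tag by half the
  fragment length toward its 3′ end ("centering"), binding sites appear as
  local concentrations of tags, called as peaks against a fold-over-
  background count threshold.
- *Where are the broad enriched domains?* Histone-mark-like signals form
  wide regions rather than point peaks; an optimal-scoring segmentation of
  the tag stream recovers them.
- *How does signal X distribute around features Y?* Aggregation profiles
  and per-feature extraction matrices answer this for any pair of
  annotated feature types.

## The SGA format

SGA (Simple Genome Annotation) is a tab-delimited text format with five
mandatory fields per line, plus optional extra fields:

```
chrom  feature  position  strand  count  [extras...]
```

- `position` is 1-based; `strand` is `+`, `-`, or `0` (unoriented);
  `count` is an integer ≥ 1 (one line represents `count` identical tags).
- Files are sorted by (`chrom` lexicographically, `position`, strand in
  the order `+` < `-` < `0`), which is plain byte order of the lines.
- A *regions* dialect represents an interval as a `+` line at its first
  base and a `-` line at its last base, both carrying the region's total
  count.

Lines beginning with `#` are ignored. Readers are lazy and track
sortedness while streaming; operations that require sorted input fail
fast on the first out-of-order record.

## Algorithms

All operations consume a sorted SGA stream in one pass.

**Correlation / aggregation** (`cor`, `extract`, `score`). Given
reference features *r* (positions *p*, counts *c_r*) and target features
*t* (positions *q*, counts *c_t*), each pair contributes the offset
*d = q − p* (negated when the reference is on the − strand and oriented
mode is on). Offsets with *b ≤ d < e* fall into half-open bins of width
*w* at index ⌊(d − b)/w⌋, weighted by *c_r · c_t*. Normalizations:
raw `count`, `density` = count/(w · N_ref) with N_ref = Σ c_r, and
`ratio` = density / (N_target / G) for genome length G. `extract`
produces the per-reference bin matrix (column sums reproduce the
profile); `score` appends to each reference the total target count in
[p+b, p+e].

**Fragment-length fit** (`fitgauss`). Least-squares fit of
*h(d) = B + A·exp(−(d−µ)²/2σ²)* to a correlation profile. On the 5′–3′
strand correlation, µ estimates the fragment length L and round(µ/2) is
the recommended centering distance; on an autocorrelation of centered
tags, the recommended window is the fitted full width at half maximum
(2√(2 ln 2)·σ) and a Poisson tail bound on the background density gives
a tag threshold. An essentially flat profile (e.g. from an input control)
is reported as non-converged.

**Centering** (`center`). Shift + tags by +δ and − tags by −δ, set strand
to `0`, re-sort, and merge coincident positions.

**Peak calling** (`peak`). A candidate at position *p* scores the total
count within |q − p| ≤ ⌊w/2⌋. A candidate is reported iff its score
reaches the threshold T and no higher-scoring (or equal-scoring, more
leftward) candidate lies within the vicinity v. With `--refine`, the
reported position is the count-weighted mean of tags in the window,
rounded half-up. T can be set directly or derived from a fold *f* over
the genome-average density λ: T = max(2, ⌈f·λ·(2⌊w/2⌋+1)⌉).

**Partitioning** (`part`). Finds the segmentation maximizing
Σ_segments (C − ρ·L − p) where C is the tag count in the segment, L its
length, ρ a density penalty, and p a per-segment penalty, via an O(n)
dynamic program over tag positions (segments begin and end on tags).
ρ can be derived from a fold over the average density.

**Conversion** (`convert`). BED/narrowPeak/GFF/BAM → SGA (5′ ends,
summits, or region pairs; BAM via pysam, CIGAR-aware 3′ ends) and
SGA → BED. Also `sort`, `merge` (k-way of sorted inputs), `compact`
(merge identical consecutive records), and `filter` (keep or exclude
tags inside a region set).

**Synthetic data** (`simulate`). A planted-site ChIP model (fragments of
length L around jittered site centers: + tags at center − L/2, − tags at
center + L/2, plus uniform Poisson background) and a planted-domain model
(piecewise-constant Poisson density), both deterministic per seed.

## Worked example

Simulate a transcription-factor sample (40 sites on a 500 kb chromosome,
fragment length 150 bp, center jitter sd 20 bp, 50 reads per site, plus
uniform background):

```
$ cat sim.json
{"genome": {"chr1": 500000}, "n_sites": 40, "fragment_length": 150,
 "center_jitter_sd": 20.0, "reads_per_site": 50, "background_rate": 0.0005}
$ sgatools simulate chip --config sim.json --seed 7 -o sample.sga --truth truth.tsv
$ head -2 sample.sga
chr1	CHIP	731	+	1
chr1	CHIP	2453	+	1
```

Estimate the fragment length from the 5′–3′ strand correlation:

```
$ sgatools cor --ref CHIP:+ --target CHIP:- -b -500 -e 500 -w 10 sample.sga > cor53.tsv
$ sort -t$'\t' -k2,2gr cor53.tsv | head -2
140	3501
150	3389
$ sgatools fitgauss cor53.tsv
mu=150.481
sigma=29.1295
amplitude=3462.23
baseline=28.8594
rmse=36.5515
converged=true
```

The fitted µ = 150.5 bp recovers the true fragment length of 150 bp, so
the centering distance is round(µ/2) = 75 bp. Center the tags and call
peaks at a 10-fold count-density threshold (here the 2237 tags on 500 kb
give a background mean of ~1.35 tags per 301 bp window, so the 10-fold
rule sets T = 14 tags):

```
$ sgatools center -d 75 sample.sga > centered.sga
$ printf 'chr1\t500000\n' > chrom.sizes
$ sgatools peak -w 300 -v 300 --fold 10 --genome chrom.sizes centered.sga > peaks.sga
$ head -3 peaks.sga
chr1	PEAK	11779	0	50
chr1	PEAK	23081	0	50
chr1	PEAK	38165	0	50
$ wc -l < peaks.sga
38
```

All 40 planted sites lie within 150 bp (half a window) of a reported
peak. Only 38 peaks are reported because two pairs of planted sites
happen to fall closer together than the 300 bp vicinity, so each pair is
reported as a single peak — exactly the behaviour the vicinity rule
specifies.

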