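"""Sliding-window peak calling on single-position tag data.

Tag counts are summed in a fixed-size window centered on each candidate
position, and peaks are the candidates that (i) reach the tag threshold and
(ii) are local maxima within the vicinity range.  For speed the search is
restricted to positions actually hit by at least one tag.  No control sample
is used: the caller takes a single feature type as input.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from itertools import groupby
from typing import Iterator, Optional

import numpy as np

from .sga import SgaRecord, SgaStream, by_chromosome, require_sorted


@dataclass(frozen=True)
class PeakParams:
    """Window width (bp), tag threshold (minimum tags in a window), vicinity
    range (bp within which a peak must dominate all other candidates)."""

    window: int
    threshold: int
    vicinity: int
    refine: bool = False
    oriented: bool = False
    count_ceiling: Optional[int] = None

    def __post_init__(self):
        if self.window < 1 or self.threshold < 1 or self.vicinity < 1:
            raise ValueError("window, threshold and vicinity must be >= 1")
        if self.count_ceiling is not None and self.count_ceiling < 1:
            raise ValueError("count_ceiling must be >= 1")

    @property
    def half_window(self) -> int:
        return self.window // 2

    @property
    def effective_width(self) -> int:
        """Inclusive window span 2*floor(w/2)+1 centered on the candidate."""
        return 2 * self.half_window + 1


@dataclass
class Peak:
    chrom: str
    position: int     # candidate position, or refined weighted average
    strand: str       # '0' unless called per strand (oriented mode)
    count: int        # total tags in the peak's window
    params: PeakParams


def threshold_from_fold(fold: float, params: PeakParams, total_count: int,
                        genome_length: int) -> int:
    """Translate a fold-change over the sample's average count density into
    an absolute tag threshold for the given window width.

    lambda = total_count / genome_length tags per bp; the expected window
    content is lambda * effective width; T = ceil(fold * expectation),
    floored at 1.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    if total_count < 1 or genome_length < 1:
        raise ValueError("total_count and genome_length must be >= 1")
    lam = total_count / genome_length
    return max(1, math.ceil(fold * lam * params.effective_width))


def _pool_positions(records: list, ceiling: Optional[int]):
    """Distinct sorted positions with summed (optionally capped) counts."""
    agg: dict = {}
    for rec in records:
        count = rec.count if ceiling is None else min(rec.count, ceiling)
        agg[rec.position] = agg.get(rec.position, 0) + count
    positions = np.fromiter(sorted(agg), dtype=np.int64, count=len(agg))
    counts = np.array([agg[p] for p in positions], dtype=np.int64)
    return positions, counts


def _call_on_arrays(positions: np.ndarray, counts: np.ndarray,
                    params: PeakParams):
    """Yield (position, window_count) peaks on one chromosome/strand."""
    if len(positions) == 0:
        return
    half = params.half_window
    prefix = np.concatenate(([0], np.cumsum(counts)))
    lo = np.searchsorted(positions, positions - half, side="left")
    hi = np.searchsorted(positions, positions + half, side="right")
    wc = prefix[hi] - prefix[lo]

    for i in range(len(positions)):
        c = wc[i]
        if c < params.threshold:
            continue
        p = positions[i]
        vlo = int(np.searchsorted(positions, p - params.vicinity, "left"))
        vhi = int(np.searchsorted(positions, p + params.vicinity, "right"))
        dominated = False
        for j in range(vlo, vhi):
            if j == i:
                continue
            if wc[j] > c or (wc[j] == c and positions[j] < p):
                dominated = True
                break
        if dominated:
            continue
        if params.refine:
            num = int((positions[lo[i]:hi[i]] * counts[lo[i]:hi[i]]).sum())
            den = int(c)
            position = math.floor(num / den + 0.5)  # round half up
        else:
            position = int(p)
        yield position, int(c)


def call_peaks(stream: SgaStream, params: PeakParams) -> list:
    """Call peaks on a sorted stream.

    In unoriented mode (default) strands are pooled and the strand field is
    ignored; in oriented mode '+' and '-' records are processed as
    independent streams (useful e.g. for clustering TSS tags in CAGE data).
    When ``refine`` is set, the reported position is the weighted average of
    tag positions within the peak's window; refinement relocates the peak
    but does not change which candidates are selected.
    """
    peaks: list = []
    for chrom, chrom_records in by_chromosome(require_sorted(stream)):
        records = list(chrom_records)
        if params.oriented:
            groups = [("+", [r for r in records if r.strand == "+"]),
                      ("-", [r for r in records if r.strand == "-"])]
        else:
            groups = [("0", records)]
        for strand, group in groups:
            positions, counts = _pool_positions(group, params.count_ceiling)
            for position, count in _call_on_arrays(positions, counts, params):
                peaks.append(Peak(chrom, position, strand, count, params))
    peaks.sort(key=lambda pk: (pk.chrom, pk.position,
                               {"+": 0, "-": 1, "0": 2}[pk.strand]))
    return peaks


def peaks_to_stream(peaks: list, feature: str = "PEAK") -> SgaStream:
    """Serialize peaks as an SGA stream."""
    records = [SgaRecord(pk.chrom, feature, pk.position, pk.strand, pk.count)
               for pk in peaks]
    return SgaStream(records, sorted=True)
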