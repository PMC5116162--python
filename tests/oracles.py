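"""Independent brute-force oracles for the streaming algorithms.

Every function here deliberately uses the naive O(N*M) / exhaustive
formulation of the operation it checks, with no shared code paths with the
package implementation beyond the record dataclass.
"""

from __future__ import annotations

import math

from sgatools import SgaRecord


def brute_profile(records, ref_sel, target_sel, begin, end, width,
                  oriented=False):
    """All-pairs binned target counts around references (count mode)."""
    n_bins = (end - begin) // width
    bins = [0] * n_bins
    refs = [r for r in records if ref_sel.matches(r)]
    targets = [t for t in records if target_sel.matches(t)]
    for r in refs:
        for t in targets:
            if t.chrom != r.chrom:
                continue
            d = t.position - r.position
            if oriented and r.strand == "-":
                d = -d
            if begin <= d < end:
                bins[(d - begin) // width] += t.count * r.count
    return bins


def brute_matrix(records, ref_sel, target_sel, begin, end, width,
                 oriented=False):
    """Per-reference rows of the same binning (cells weighted by ref count)."""
    n_bins = (end - begin) // width
    refs = [r for r in records if ref_sel.matches(r)]
    targets = [t for t in records if target_sel.matches(t)]
    rows = []
    for r in refs:
        row = [0] * n_bins
        for t in targets:
            if t.chrom != r.chrom:
                continue
            d = t.position - r.position
            if oriented and r.strand == "-":
                d = -d
            if begin <= d < end:
                row[(d - begin) // width] += t.count * r.count
        rows.append(row)
    return rows


def brute_scores(records, ref_sel, target_sel, begin, end, oriented=False):
    """Unbinned per-reference target totals in [begin, end)."""
    refs = [r for r in records if ref_sel.matches(r)]
    targets = [t for t in records if target_sel.matches(t)]
    totals = []
    for r in refs:
        total = 0
        for t in targets:
            if t.chrom != r.chrom:
                continue
            d = t.position - r.position
            if oriented and r.strand == "-":
                d = -d
            if begin <= d < end:
                total += t.count
        totals.append(total)
    return totals


def brute_filter(records, regions, invert=False):
    """Per-record inclusive interval membership test against every region."""
    kept = []
    for rec in records:
        inside = any(region.start <= rec.position <= region.end
                     for chrom, region in regions if chrom == rec.chrom)
        if inside == invert:
            kept.append(rec)
    return kept


def brute_peaks(records, window, threshold, vicinity, refine=False):
    """Exhaustive peak scan: candidates are tag positions; window counts and
    the local-maximum test are computed naively over all candidates.

    Strands are pooled.  Returns sorted (position, window_count) pairs.
    """
    half = window // 2
    by_chrom: dict = {}
    for rec in records:
        agg = by_chrom.setdefault(rec.chrom, {})
        agg[rec.position] = agg.get(rec.position, 0) + rec.count
    peaks = []
    for chrom in sorted(by_chrom):
        agg = by_chrom[chrom]
        candidates = sorted(agg)

        def window_count(p):
            return sum(c for q, c in agg.items() if abs(q - p) <= half)

        for p in candidates:
            c = window_count(p)
            if c < threshold:
                continue
            ok = True
            for q in candidates:
                if q == p or abs(q - p) > vicinity:
                    continue
                cq = window_count(q)
                if cq > c or (cq == c and q < p):
                    ok = False
                    break
            if not ok:
                continue
            if refine:
                num = sum(q * c2 for q, c2 in agg.items() if abs(q - p) <= half)
                pos = math.floor(num / c + 0.5)
            else:
                pos = p
            peaks.append((chrom, pos, c))
    return peaks


def enumerate_segmentations(positions, counts, rho, penalty):
    """Score of the best segmentation by explicit exhaustive enumeration of
    every set of disjoint index intervals (non-memoized recursion)."""
    n = len(positions)
    prefix = [0]
    for c in counts:
        prefix.append(prefix[-1] + c)

    def seg_score(a, k):   # inclusive indices
        total = prefix[k + 1] - prefix[a]
        return total - rho * (positions[k] - positions[a] + 1) - penalty

    def best_from(i):
        if i >= n:
            return 0.0
        best = best_from(i + 1)          # position i in no segment
        for j in range(i, n):            # segment [i, j]
            cand = seg_score(i, j) + best_from(j + 1)
            if cand > best:
                best = cand
        return best

    return best_from(0)
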