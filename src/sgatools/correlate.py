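"""Feature-correlation engines: aggregation profiles, per-reference count
matrices and reference scoring/selection.

All three operations take a single merged, sorted SGA stream containing two
feature types — a "reference" (e.g. TSSs or peak centers) and a "target"
(e.g. mapped ChIP-seq tags) — and measure target abundance at binned
distances around each reference position.

In oriented mode target offsets are processed reverse-complementarily for
minus-strand references: a target 100 bp upstream of a '-' reference is
treated like one 100 bp downstream of a '+' reference.  A reference record
with count k counts as k references; N_ref is the sum of reference counts.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np

from .sga import (GenomeTable, SgaError, SgaRecord, SgaStream, by_chromosome,
                  estimate_genome_length, require_sorted)

NORMALIZATIONS = ("count", "density", "ratio")


class MissingFeatureError(SgaError):
    """The merged stream does not contain a selected feature."""


@dataclass(frozen=True)
class FeatureSelector:
    """Select records by feature name and optionally by strand."""

    feature: str
    strand: str = "any"   # '+', '-' or 'any'

    def __post_init__(self):
        if self.strand not in ("+", "-", "any"):
            raise ValueError(f"invalid strand filter {self.strand!r}")

    def matches(self, rec: SgaRecord) -> bool:
        return (rec.feature == self.feature
                and (self.strand == "any" or rec.strand == self.strand))

    @classmethod
    def parse(cls, text: str) -> "FeatureSelector":
        """Parse ``FEAT`` or ``FEAT:STRAND`` CLI syntax."""
        if ":" in text:
            feature, strand = text.rsplit(":", 1)
            return cls(feature, strand)
        return cls(text)


@dataclass(frozen=True)
class CorrelationParams:
    """Distance range [begin, end) in bp around the reference, bin width,
    orientation flag and normalization mode."""

    begin: int
    end: int
    width: int = 1
    oriented: bool = False
    normalization: str = "count"

    def __post_init__(self):
        if self.begin >= self.end:
            raise ValueError("range begin must be < end")
        if self.width < 1:
            raise ValueError("bin width must be >= 1")
        if (self.end - self.begin) % self.width:
            raise ValueError("(end - begin) must be divisible by bin width")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def n_bins(self) -> int:
        return (self.end - self.begin) // self.width

    def bin_edges(self) -> np.ndarray:
        """Left edges (offsets) of the bins."""
        return self.begin + self.width * np.arange(self.n_bins)


@dataclass
class CorrelationProfile:
    """Binned target abundance around reference positions."""

    offsets: np.ndarray        # bin left edges
    values: np.ndarray
    n_ref: int                 # sum of reference counts used
    total_target: int          # total target count genome-wide
    normalization: str
    width: int

    def bin_centers(self) -> np.ndarray:
        return self.offsets + self.width / 2.0


@dataclass
class ExtractMatrix:
    """Per-reference binned target counts; rows in reference stream order."""

    row_labels: list           # (chrom, position, strand) per reference record
    offsets: np.ndarray
    counts: np.ndarray         # shape (n_rows, n_bins), integer


def _split_by_feature(stream: SgaStream, ref: FeatureSelector,
                      target: FeatureSelector):
    """One pass over the merged stream -> per-chromosome ref/target arrays.

    Returns (chrom_data, ref_records, n_ref, total_target) where chrom_data
    maps chrom -> (target positions array, target counts array) and
    ref_records is the list of matching reference records in stream order.
    """
    chrom_targets: dict = {}
    ref_records: list = []
    seen_ref_feature = False
    seen_target_feature = False
    for rec in require_sorted(stream):
        if rec.feature == ref.feature:
            seen_ref_feature = True
        if rec.feature == target.feature:
            seen_target_feature = True
        if target.matches(rec):
            pos_list, cnt_list = chrom_targets.setdefault(rec.chrom, ([], []))
            pos_list.append(rec.position)
            cnt_list.append(rec.count)
        if ref.matches(rec):
            ref_records.append(rec)
    if not seen_ref_feature:
        raise MissingFeatureError(
            f"reference feature {ref.feature!r} not present in stream")
    if not seen_target_feature:
        raise MissingFeatureError(
            f"target feature {target.feature!r} not present in stream")
    chrom_data = {
        chrom: (np.asarray(p, dtype=np.int64), np.asarray(c, dtype=np.int64))
        for chrom, (p, c) in chrom_targets.items()}
    n_ref = sum(r.count for r in ref_records)
    total_target = int(sum(c.sum() for _, c in chrom_data.values()))
    return chrom_data, ref_records, n_ref, total_target


def _target_window(positions: np.ndarray, ref_pos: int, begin: int, end: int,
                   flip: bool):
    """Index slice of targets whose (possibly flipped) offset lies in
    [begin, end), plus the offsets themselves."""
    if not flip:
        lo = int(np.searchsorted(positions, ref_pos + begin, side="left"))
        hi = int(np.searchsorted(positions, ref_pos + end, side="left"))
        offsets = positions[lo:hi] - ref_pos
    else:
        # offset d = ref_pos - t must satisfy begin <= d < end
        lo = int(np.searchsorted(positions, ref_pos - end, side="right"))
        hi = int(np.searchsorted(positions, ref_pos - begin, side="right"))
        offsets = ref_pos - positions[lo:hi]
    return lo, hi, offsets


def correlate_profile(merged: SgaStream, ref: FeatureSelector,
                      target: FeatureSelector, params: CorrelationParams,
                      genome: Optional[GenomeTable] = None,
                      allow_estimated_genome: bool = True
                      ) -> CorrelationProfile:
    """Aggregation profile: binned average abundance of the target feature
    at distances [begin, end) around the reference positions.

    Normalization modes: ``count`` — raw weighted sums; ``density`` —
    count / (width * N_ref), i.e. target tags per base pair per reference;
    ``ratio`` — density divided by the genome-wide average target density
    (fold enrichment over background).
    """
    chrom_data, ref_records, n_ref, total_target = _split_by_feature(
        merged, ref, target)
    values = np.zeros(params.n_bins, dtype=np.float64)
    for rec in ref_records:
        data = chrom_data.get(rec.chrom)
        if data is None:
            continue
        positions, counts = data
        flip = params.oriented and rec.strand == "-"
        lo, hi, offsets = _target_window(positions, rec.position,
                                         params.begin, params.end, flip)
        if hi > lo:
            bins = (offsets - params.begin) // params.width
            np.add.at(values, bins, counts[lo:hi] * rec.count)

    if params.normalization == "density":
        if n_ref > 0:
            values = values / (params.width * n_ref)
    elif params.normalization == "ratio":
        if genome is not None:
            genome_length = genome.total_length
        elif allow_estimated_genome:
            genome_length = _estimate_length_from(chrom_data, ref_records)
        else:
            raise SgaError("ratio normalization requires a genome table")
        density = values / (params.width * n_ref) if n_ref else values
        mean_density = total_target / genome_length
        values = density / mean_density if mean_density > 0 else density
    return CorrelationProfile(params.bin_edges(), values, n_ref,
                              total_target, params.normalization,
                              params.width)


def _estimate_length_from(chrom_data, ref_records) -> int:
    maxima: dict = {}
    for chrom, (positions, _) in chrom_data.items():
        if len(positions):
            maxima[chrom] = int(positions[-1])
    for rec in ref_records:
        if rec.position > maxima.get(rec.chrom, 0):
            maxima[rec.chrom] = rec.position
    return sum(maxima.values())


def extract_matrix(merged: SgaStream, ref: FeatureSelector,
                   target: FeatureSelector,
                   params: CorrelationParams) -> ExtractMatrix:
    """Per-reference binned target counts (one row per reference record,
    count mode only).  Cells are weighted by the reference record's count so
    that column sums reproduce the count-mode aggregation profile."""
    chrom_data, ref_records, _, _ = _split_by_feature(merged, ref, target)
    counts = np.zeros((len(ref_records), params.n_bins), dtype=np.int64)
    labels = []
    for row, rec in enumerate(ref_records):
        labels.append((rec.chrom, rec.position, rec.strand))
        data = chrom_data.get(rec.chrom)
        if data is None:
            continue
        positions, tcounts = data
        flip = params.oriented and rec.strand == "-"
        lo, hi, offsets = _target_window(positions, rec.position,
                                         params.begin, params.end, flip)
        if hi > lo:
            bins = (offsets - params.begin) // params.width
            np.add.at(counts[row], bins, tcounts[lo:hi] * rec.count)
    return ExtractMatrix(labels, params.bin_edges(), counts)


def score_references(merged: SgaStream, ref: FeatureSelector,
                     target: FeatureSelector, begin: int, end: int,
                     threshold: Optional[int] = None,
                     oriented: bool = False) -> SgaStream:
    """Annotate each reference record with the total target count in the
    window [begin, end) around it (appended as an extra field), optionally
    keeping only references with at least ``threshold`` target tags.

    All optional fields of the reference lines are transferred to the
    output, so the same reference set can be annotated with tag counts from
    several experiments in succession.
    """
    if begin >= end:
        raise ValueError("range begin must be < end")
    chrom_data, ref_records, _, _ = _split_by_feature(merged, ref, target)

    def gen() -> Iterator[SgaRecord]:
        for rec in ref_records:
            data = chrom_data.get(rec.chrom)
            if data is None:
                total = 0
            else:
                positions, counts = data
                flip = oriented and rec.strand == "-"
                lo, hi, _ = _target_window(positions, rec.position,
                                           begin, end, flip)
                total = int(counts[lo:hi].sum())
            if threshold is not None and total < threshold:
                continue
            yield replace(rec, extras=rec.extras + (str(total),))

    return SgaStream(gen(), sorted=True)
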