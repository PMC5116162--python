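"""SGA (Simple Genome Annotation) data model, I/O and format conversion.

SGA is a tab-delimited single-position text format with five obligatory
fields per line: chromosome identifier, feature name, 1-based position,
strand ('+', '-' or '0' for unoriented features) and a positive read count.
Additional fields may follow and are carried through by operations that
declare they preserve them.  The mission-critical property of the format is
sortedness: lines must be ordered by chromosome (lexicographic), position
(ascending) and strand ('+' < '-' < '0', i.e. plain byte order), which lets
every downstream algorithm run in a single pass with per-chromosome memory.

A "regions SGA" file is a dialect in which a '+' line marks the first base
of a genomic region and the matching '-' line marks its last base; the count
field on both lines carries the region's total count.
"""

from __future__ import annotations

import heapq
from bisect import bisect_left
from dataclasses import dataclass, field, replace
from itertools import groupby
from typing import Iterable, Iterator, Optional, TextIO, Union

STRANDS = ("+", "-", "0")
#: collation order of the strand field in a sorted SGA file (byte order)
STRAND_ORDER = {"+": 0, "-": 1, "0": 2}


class SgaError(Exception):
    """Base class for SGA format errors."""


class SgaParseError(SgaError):
    """A line could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class SgaValidationError(SgaError):
    """A record violates SGA invariants (position/count/strand/feature)."""


class SortednessError(SgaError):
    """A stream declared or required sorted is out of order."""


@dataclass
class SgaRecord:
    """One genome position with a feature label and a positive count."""

    chrom: str
    feature: str
    position: int
    strand: str
    count: int
    extras: tuple = ()

    def validate(self) -> "SgaRecord":
        if not self.feature:
            raise SgaValidationError("feature name must be non-empty")
        for f in (self.chrom, self.feature, *self.extras):
            if "\t" in f:
                raise SgaValidationError(f"tab character inside field {f!r}")
        if self.strand not in STRANDS:
            raise SgaValidationError(f"invalid strand {self.strand!r}")
        if self.position < 1:
            raise SgaValidationError(f"position {self.position} < 1")
        if self.count < 1:
            raise SgaValidationError(f"count {self.count} < 1")
        return self

    def sort_key(self) -> tuple:
        return (self.chrom, self.position, STRAND_ORDER[self.strand])

    def group_key(self) -> tuple:
        """Identity key used by :func:`compact`."""
        return (self.chrom, self.feature, self.position, self.strand)

    def to_line(self) -> str:
        fields = (self.chrom, self.feature, str(self.position),
                  self.strand, str(self.count), *self.extras)
        return "\t".join(fields)


class SgaStream:
    """An iterable-once sequence of :class:`SgaRecord` with a sortedness flag.

    ``sorted`` is True/False when known, None while a lazy stream is still
    being consumed.  Iterating a stream created from a lazy source updates
    the flag as records pass through.
    """

    def __init__(self, records: Iterable[SgaRecord],
                 sorted: Optional[bool] = None):
        self._records = records
        self.sorted = sorted

    def __iter__(self) -> Iterator[SgaRecord]:
        return iter(self._records)

    @classmethod
    def from_records(cls, records, sorted: Optional[bool] = None) -> "SgaStream":
        return cls(list(records), sorted=sorted)

    def to_list(self) -> list:
        lst = list(self._records)
        self._records = lst
        return lst


def _tracking_sorted(records: Iterable[SgaRecord], stream_box: list
                     ) -> Iterator[SgaRecord]:
    """Yield records, recording in ``stream_box`` whether order held."""
    last = None
    ok = True
    for rec in records:
        key = rec.sort_key()
        if last is not None and key < last:
            ok = False
        last = key
        yield rec
    stream_box[0].sorted = ok


def require_sorted(stream: SgaStream) -> Iterator[SgaRecord]:
    """Yield records from a stream, failing fast on any order violation."""
    if stream.sorted is False:
        raise SortednessError("input stream is not sorted")
    last = None
    for rec in stream:
        key = rec.sort_key()
        if last is not None and key < last:
            raise SortednessError(
                f"out of order at {rec.chrom}:{rec.position}:{rec.strand}")
        last = key
        yield rec


def by_chromosome(records: Iterable[SgaRecord]):
    """Group a sorted record iterator by chromosome (single pass)."""
    return groupby(records, key=lambda r: r.chrom)


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def parse_sga_line(line: str, line_number: Optional[int] = None) -> SgaRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 5:
        raise SgaParseError(
            f"expected >= 5 tab-delimited fields, got {len(fields)}",
            line_number)
    chrom, feature, pos_s, strand, count_s = fields[:5]
    try:
        position = int(pos_s)
        count = int(count_s)
    except ValueError:
        raise SgaParseError(
            f"non-integer position/count: {pos_s!r}/{count_s!r}", line_number)
    if strand not in STRANDS:
        raise SgaParseError(f"invalid strand {strand!r}", line_number)
    rec = SgaRecord(chrom, feature, position, strand, count,
                    tuple(fields[5:]))
    try:
        rec.validate()
    except SgaValidationError as exc:
        raise SgaValidationError(f"line {line_number}: {exc}") from None
    return rec


def read_sga(source: Union[TextIO, Iterable[str]],
             count_ceiling: Optional[int] = None) -> SgaStream:
    """Parse an SGA text stream lazily.

    Counts are capped at ``count_ceiling`` when given (the -c "count
    cut-off" option; a ceiling of 1 has the same effect as removing
    duplicate reads).  Lines starting with '#' are skipped.  Sortedness is
    verified while streaming; the returned stream's ``sorted`` flag is set
    once iteration completes.
    """
    if count_ceiling is not None and count_ceiling < 1:
        raise ValueError("count_ceiling must be >= 1")

    def records():
        for i, line in enumerate(source, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            rec = parse_sga_line(line, i)
            if count_ceiling is not None and rec.count > count_ceiling:
                rec = replace(rec, count=count_ceiling)
            yield rec

    box = [None]
    stream = SgaStream(_tracking_sorted(records(), box))
    box[0] = stream
    return stream


def write_sga(stream: Iterable[SgaRecord], sink: TextIO) -> int:
    """Write records as SGA lines; returns the number of lines written."""
    n = 0
    for rec in stream:
        sink.write(rec.to_line() + "\n")
        n += 1
    return n


# ---------------------------------------------------------------------------
# Sorting, merging, compacting
# ---------------------------------------------------------------------------

def sort_records(stream: SgaStream) -> SgaStream:
    """Sort by (chromosome, position, strand); stable for tied keys."""
    records = sorted(stream, key=SgaRecord.sort_key)
    return SgaStream(records, sorted=True)


def sort_merge(streams: list) -> SgaStream:
    """K-way merge of sorted streams into one sorted stream.

    Counts are never combined here (see :func:`compact`); extras are
    preserved.  Raises :class:`SortednessError` before yielding anything
    past an order violation in any input.
    """
    checked = [require_sorted(s) for s in streams]
    merged = heapq.merge(*checked, key=SgaRecord.sort_key)
    return SgaStream(merged, sorted=True)


def compact(stream: SgaStream) -> SgaStream:
    """Merge consecutive records identical in (chrom, feature, position,
    strand), summing counts; extras of the first record are kept."""
    def gen():
        for _, group in groupby(require_sorted(stream),
                                key=SgaRecord.group_key):
            first = next(group)
            total = first.count + sum(r.count for r in group)
            yield replace(first, count=total)
    return SgaStream(gen(), sorted=True)


# ---------------------------------------------------------------------------
# Genome table / chromosome aliases
# ---------------------------------------------------------------------------

@dataclass
class GenomeTable:
    """Chromosome lengths; total genome length = sum of values."""

    lengths: dict = field(default_factory=dict)

    def __post_init__(self):
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"non-positive length for {chrom}")

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def __contains__(self, chrom):
        return chrom in self.lengths

    def __getitem__(self, chrom):
        return self.lengths[chrom]

    @classmethod
    def read(cls, source: Iterable[str]) -> "GenomeTable":
        lengths = {}
        for i, line in enumerate(source, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise SgaParseError("expected 'chrom<TAB>length'", i)
            lengths[parts[0]] = int(parts[1])
        return cls(lengths)


def estimate_genome_length(records: Iterable[SgaRecord]) -> int:
    """Fallback genome length: sum of per-chromosome max observed position."""
    maxima: dict = {}
    for rec in records:
        if rec.position > maxima.get(rec.chrom, 0):
            maxima[rec.chrom] = rec.position
    return sum(maxima.values())


class ChromAlias:
    """One-to-one map between UCSC chromosome names and versioned RefSeq
    accessions (e.g. chr1 <-> NC_000001.10) for a single assembly."""

    def __init__(self, pairs: Iterable[tuple]):
        self.ucsc_to_refseq: dict = {}
        self.refseq_to_ucsc: dict = {}
        for ucsc, refseq in pairs:
            if ucsc in self.ucsc_to_refseq or refseq in self.refseq_to_ucsc:
                raise ValueError(f"alias mapping not one-to-one: {ucsc}/{refseq}")
            self.ucsc_to_refseq[ucsc] = refseq
            self.refseq_to_ucsc[refseq] = ucsc

    @classmethod
    def read(cls, source: Iterable[str]) -> "ChromAlias":
        pairs = []
        for line in source:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            pairs.append((parts[0], parts[1]))
        return cls(pairs)

    def rename(self, stream: SgaStream, to: str = "refseq") -> SgaStream:
        """Rename chromosomes; output is NOT resorted (renaming can change
        lexicographic order — sort afterwards if order matters)."""
        table = self.ucsc_to_refseq if to == "refseq" else self.refseq_to_ucsc

        def gen():
            for rec in stream:
                yield replace(rec, chrom=table.get(rec.chrom, rec.chrom))
        return SgaStream(gen(), sorted=None)


# ---------------------------------------------------------------------------
# Regions SGA
# ---------------------------------------------------------------------------

@dataclass
class Region:
    start: int   # 1-based inclusive
    end: int     # 1-based inclusive
    count: int
    feature: str

    def __post_init__(self):
        if self.start > self.end:
            raise SgaValidationError(
                f"region start {self.start} > end {self.end}")


class RegionSet:
    """Per-chromosome ordered, disjoint regions; serialized as a regions
    SGA file with a '+' line at the first base and a '-' line at the last."""

    def __init__(self, regions: Optional[dict] = None):
        self.regions = regions if regions is not None else {}

    def add(self, chrom: str, region: Region) -> None:
        self.regions.setdefault(chrom, []).append(region)

    def chromosomes(self):
        return sorted(self.regions)

    def __iter__(self):
        for chrom in self.chromosomes():
            for region in self.regions[chrom]:
                yield chrom, region

    def total_regions(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def validate(self) -> "RegionSet":
        for chrom, regions in self.regions.items():
            prev_end = 0
            for region in regions:
                if region.start <= prev_end:
                    raise SgaValidationError(
                        f"{chrom}: overlapping/unsorted region at "
                        f"{region.start}")
                prev_end = region.end
        return self

    @classmethod
    def from_stream(cls, stream: SgaStream) -> "RegionSet":
        """Parse a regions-SGA stream: strictly alternating '+'/'-' lines
        per chromosome and feature."""
        rs = cls()
        open_plus: dict = {}
        for rec in require_sorted(stream):
            key = (rec.chrom, rec.feature)
            if rec.strand == "+":
                if key in open_plus:
                    raise SgaValidationError(
                        f"unpaired '+' boundary before {rec.chrom}:"
                        f"{rec.position}")
                open_plus[key] = rec
            elif rec.strand == "-":
                start = open_plus.pop(key, None)
                if start is None:
                    raise SgaValidationError(
                        f"'-' boundary without matching '+' at {rec.chrom}:"
                        f"{rec.position}")
                rs.add(rec.chrom,
                       Region(start.position, rec.position, rec.count,
                              rec.feature))
            else:
                raise SgaValidationError(
                    f"strand '0' not allowed in a regions SGA at "
                    f"{rec.chrom}:{rec.position}")
        if open_plus:
            (chrom, _), rec = next(iter(open_plus.items()))
            raise SgaValidationError(
                f"unclosed region starting at {chrom}:{rec.position}")
        return rs.validate()

    def to_stream(self) -> SgaStream:
        def gen():
            for chrom in self.chromosomes():
                for region in self.regions[chrom]:
                    yield SgaRecord(chrom, region.feature, region.start, "+",
                                    region.count)
                    yield SgaRecord(chrom, region.feature, region.end, "-",
                                    region.count)
        return SgaStream(gen(), sorted=True)


# ---------------------------------------------------------------------------
# Format conversion
# ---------------------------------------------------------------------------

def _split_bed(line: str, line_number: int) -> list:
    fields = line.rstrip("\n").split("\t")
    if len(fields) == 1:
        fields = line.split()
    if len(fields) < 3:
        raise SgaParseError("BED line with fewer than 3 fields", line_number)
    return fields


def bed_to_sga(source: Iterable[str], feature: str,
               mode: str = "five_prime") -> SgaStream:
    """Convert BED (0-based half-open) lines to SGA.

    Modes:

    ``five_prime``
        each interval becomes the single base of its 5' end: '+' (or
        strandless) -> start+1 with strand '+' ('0' when strandless);
        '-' -> end with strand '-'; count 1 per line.
    ``narrowpeak_summit``
        ENCODE narrowPeak (10 columns); position = start + 1 + summit
        offset (column 10); offset -1 (no summit called) falls back to the
        interval midpoint; strand '0'.
    ``region_pair``
        each interval becomes a regions-SGA boundary pair
        ('+' at start+1, '-' at end).

    Output is sorted and compacted.
    """
    if mode not in ("five_prime", "narrowpeak_summit", "region_pair"):
        raise ValueError(f"unknown mode {mode!r}")
    records = []
    for i, line in enumerate(source, start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = _split_bed(line, i)
        chrom = fields[0]
        start, end = int(fields[1]), int(fields[2])
        if end <= start:
            raise SgaParseError(f"end {end} <= start {start}", i)
        strand = fields[5] if len(fields) >= 6 else "."
        if mode == "five_prime":
            if strand == "-":
                records.append(SgaRecord(chrom, feature, end, "-", 1))
            elif strand == "+":
                records.append(SgaRecord(chrom, feature, start + 1, "+", 1))
            else:
                records.append(SgaRecord(chrom, feature, start + 1, "0", 1))
        elif mode == "narrowpeak_summit":
            if len(fields) < 10:
                raise SgaParseError(
                    "narrowPeak requires 10 fields in summit mode", i)
            offset = int(fields[9])
            if offset >= 0:
                position = start + 1 + offset
            else:
                position = (start + end + 1) // 2
            records.append(SgaRecord(chrom, feature, position, "0", 1))
        else:  # region_pair
            records.append(SgaRecord(chrom, feature, start + 1, "+", 1))
            records.append(SgaRecord(chrom, feature, end, "-", 1))
    if mode == "region_pair":
        return sort_records(SgaStream(records))
    return compact(sort_records(SgaStream(records)))


def bam_to_sga(alignments, feature: str, min_mapq: int = 0) -> SgaStream:
    """Convert mapped alignments (a pysam AlignmentFile or an iterable of
    pysam AlignedSegment) to 5'-end tag records.

    Unmapped, secondary and supplementary alignments are skipped, as are
    alignments below ``min_mapq``.  Forward reads map to their leftmost
    reference base; reverse reads map to the CIGAR-aware rightmost aligned
    reference base (deletions and skips included), i.e. the 5' end of the
    read in reference coordinates.  Output is sorted and compacted.
    """
    records = []
    for aln in alignments:
        if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
            continue
        if aln.mapping_quality < min_mapq:
            continue
        if aln.is_reverse:
            # pysam reference_end is one past the last aligned base (0-based)
            records.append(SgaRecord(aln.reference_name, feature,
                                     aln.reference_end, "-", 1))
        else:
            records.append(SgaRecord(aln.reference_name, feature,
                                     aln.reference_start + 1, "+", 1))
    return compact(sort_records(SgaStream(records)))


def gff_to_sga(source: Iterable[str],
               feature: Optional[str] = None) -> SgaStream:
    """Convert GFF lines (1-based inclusive) to single-position SGA.

    The GFF type column becomes the feature label unless ``feature``
    overrides it.  Oriented features map to their 5' end ('+' -> start,
    '-' -> end); unoriented features map to start with strand '0'.
    """
    records = []
    for i, line in enumerate(source, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 7:
            raise SgaParseError("GFF line with fewer than 7 fields", i)
        chrom, _, gff_type, start_s, end_s, _, strand = fields[:7]
        start, end = int(start_s), int(end_s)
        if end < start:
            raise SgaParseError(f"end {end} < start {start}", i)
        label = feature if feature is not None else gff_type
        if strand == "-":
            records.append(SgaRecord(chrom, label, end, "-", 1))
        elif strand == "+":
            records.append(SgaRecord(chrom, label, start, "+", 1))
        else:
            records.append(SgaRecord(chrom, label, start, "0", 1))
    return compact(sort_records(SgaStream(records)))


def sga_to_bed(stream: SgaStream, mode: str = "single_base"
               ) -> Iterator[str]:
    """Serialize SGA to BED lines.

    ``single_base``: each record -> ``chrom  pos-1  pos  feature  count
    strand`` (strand '0' written as '.').  ``region_pairs``: each
    alternating '+'/'-' boundary pair -> one interval ``[start-1, end)``
    with score = region count.
    """
    if mode == "single_base":
        for rec in require_sorted(stream):
            strand = "." if rec.strand == "0" else rec.strand
            yield (f"{rec.chrom}\t{rec.position - 1}\t{rec.position}\t"
                   f"{rec.feature}\t{rec.count}\t{strand}")
    elif mode == "region_pairs":
        rs = RegionSet.from_stream(stream)
        for chrom, region in rs:
            yield (f"{chrom}\t{region.start - 1}\t{region.end}\t"
                   f"{region.feature}\t{region.count}\t.")
    else:
        raise ValueError(f"unknown mode {mode!r}")
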