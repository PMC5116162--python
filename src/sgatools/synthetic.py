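"""Synthetic ChIP-seq data with known ground truth.

Two generators cover the package's analysis surface without any download:

* :func:`simulate_chip` emulates the read geometry of a transcription-factor
  ChIP-seq experiment: fragments of length L centered (with Gaussian jitter)
  on planted binding sites are sequenced from their ends, so '+'-strand tags
  cluster L/2 upstream and '-'-strand tags L/2 downstream of each site, on a
  uniform Poisson background.

* :func:`simulate_domains` emulates broad enrichment domains (histone-mark
  style): planted intervals with elevated Poisson read density over a low
  background, all tags unoriented.

All randomness flows from a single integer seed, split deterministically per
chromosome, so identical parameters always produce byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .sga import GenomeTable, SgaRecord, SgaStream, compact, sort_records


@dataclass
class ChipSimParams:
    """Planted-binding-site simulation parameters.

    fragment_length is the immunoprecipitated fragment size L (bp): '+'
    tags are placed at center - floor(L/2), '-' tags at center + floor(L/2).
    center_jitter_sd is the standard deviation (bp) of the fragment center
    around the site.  background_rate is in reads per bp of genome.
    """

    genome: GenomeTable
    n_sites: int = 200
    fragment_length: int = 150
    center_jitter_sd: float = 20.0
    reads_per_site: int = 50
    background_rate: float = 0.0
    seed: int = 0
    feature: str = "CHIP"
    site_positions: Optional[Sequence[Tuple[str, int]]] = None

    def __post_init__(self):
        if self.fragment_length < 1:
            raise ValueError("fragment_length must be >= 1")
        if self.center_jitter_sd < 0 or self.background_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.n_sites < 0 or self.reads_per_site < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class DomainSimParams:
    """Planted-domain simulation parameters.

    intervals: list of (chrom, start, end, density) with 1-based inclusive
    coordinates and density in reads per bp; background_density applies to
    the rest of the genome.
    """

    genome: GenomeTable
    intervals: List[Tuple[str, int, int, float]] = field(default_factory=list)
    background_density: float = 0.0
    seed: int = 0
    feature: str = "DOM"

    def __post_init__(self):
        by_chrom: dict = {}
        for chrom, start, end, density in self.intervals:
            if chrom not in self.genome:
                raise ValueError(f"interval on unknown chromosome {chrom}")
            if not (1 <= start <= end <= self.genome[chrom]):
                raise ValueError(f"interval {chrom}:{start}-{end} outside genome")
            if density < 0:
                raise ValueError("densities must be >= 0")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping intervals on {chrom}")
        if self.background_density < 0:
            raise ValueError("background_density must be >= 0")


def _chrom_rngs(seed: int, chroms: Sequence[str]) -> dict:
    """Deterministic per-chromosome generators split from one seed."""
    seq = np.random.SeedSequence(seed)
    children = seq.spawn(len(chroms))
    return {chrom: np.random.default_rng(child)
            for chrom, child in zip(sorted(chroms), children)}


def simulate_chip(params: ChipSimParams
                  ) -> Tuple[SgaStream, List[Tuple[str, int, int]]]:
    """Generate a sorted, compacted tag stream with planted binding sites.

    Returns (stream, truth) where truth lists (chrom, site_position,
    n_signal_reads) per site.  Signal reads draw a fragment center from
    Normal(site, jitter_sd), a strand with probability 1/2 each, and place
    the 5' tag a half fragment length away from the center; reads whose tag
    would fall off the chromosome are redrawn (not clamped, to avoid
    artificial boundary pile-ups).  Background reads are uniform with random
    strand, Poisson-distributed in number per chromosome.
    """
    genome = params.genome
    chroms = sorted(genome.lengths)
    rngs = _chrom_rngs(params.seed, chroms)
    master = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))

    # plant sites
    if params.site_positions is not None:
        sites = list(params.site_positions)
        for chrom, pos in sites:
            if chrom not in genome or not (1 <= pos <= genome[chrom]):
                raise ValueError(f"site {chrom}:{pos} outside genome")
    else:
        margin = params.fragment_length + int(6 * params.center_jitter_sd) + 1
        sites = []
        lengths = np.array([genome[c] for c in chroms], dtype=float)
        probs = lengths / lengths.sum()
        for _ in range(params.n_sites):
            chrom = chroms[int(master.choice(len(chroms), p=probs))]
            lo, hi = 1 + margin, genome[chrom] - margin
            if hi <= lo:
                raise ValueError(f"chromosome {chrom} too short for sites")
            sites.append((chrom, int(master.integers(lo, hi + 1))))
        sites.sort()

    half = params.fragment_length // 2
    records: list = []
    truth: list = []
    for chrom, site in sites:
        rng = rngs[chrom]
        length = genome[chrom]
        placed = 0
        while placed < params.reads_per_site:
            center = site + (int(round(rng.normal(0.0, params.center_jitter_sd)))
                             if params.center_jitter_sd > 0 else 0)
            if rng.random() < 0.5:
                pos, strand = center - half, "+"
            else:
                pos, strand = center + half, "-"
            if 1 <= pos <= length:
                records.append(SgaRecord(chrom, params.feature, pos, strand, 1))
                placed += 1
        truth.append((chrom, site, params.reads_per_site))

    # background
    for chrom in chroms:
        rng = rngs[chrom]
        length = genome[chrom]
        n_bg = int(rng.poisson(params.background_rate * length))
        if n_bg:
            positions = rng.integers(1, length + 1, size=n_bg)
            strands = rng.choice(["+", "-"], size=n_bg)
            for pos, strand in zip(positions, strands):
                records.append(SgaRecord(chrom, params.feature, int(pos),
                                         str(strand), 1))

    stream = SgaStream(compact(sort_records(SgaStream(records))).to_list(),
                       sorted=True)
    return stream, truth


def simulate_domains(params: DomainSimParams
                     ) -> Tuple[SgaStream, List[Tuple[str, int, int, float]]]:
    """Generate unoriented tags with planted high-density intervals.

    Read counts are Poisson(density * interval length) per planted interval
    and Poisson(background_density * remaining length) outside, with uniform
    positions; all strands '0'.  Returns (stream, truth) with truth equal to
    the planted interval list.
    """
    genome = params.genome
    chroms = sorted(genome.lengths)
    rngs = _chrom_rngs(params.seed, chroms)
    by_chrom: dict = {c: [] for c in chroms}
    for chrom, start, end, density in params.intervals:
        by_chrom[chrom].append((start, end, density))

    records: list = []
    for chrom in chroms:
        rng = rngs[chrom]
        length = genome[chrom]
        intervals = sorted(by_chrom[chrom])
        # planted intervals
        for start, end, density in intervals:
            n = int(rng.poisson(density * (end - start + 1)))
            if n:
                positions = rng.integers(start, end + 1, size=n)
                records.extend(
                    SgaRecord(chrom, params.feature, int(p), "0", 1)
                    for p in positions)
        # background over the complement
        gaps = []
        cursor = 1
        for start, end, _ in intervals:
            if start > cursor:
                gaps.append((cursor, start - 1))
            cursor = end + 1
        if cursor <= length:
            gaps.append((cursor, length))
        for start, end in gaps:
            n = int(rng.poisson(params.background_density
                                * (end - start + 1)))
            if n:
                positions = rng.integers(start, end + 1, size=n)
                records.extend(
                    SgaRecord(chrom, params.feature, int(p), "0", 1)
                    for p in positions)

    stream = SgaStream(compact(sort_records(SgaStream(records))).to_list(),
                       sorted=True)
    return stream, list(params.intervals)
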