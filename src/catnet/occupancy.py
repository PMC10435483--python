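"""From aligned reads to artifact-filtered Pol II occupancy tracks.

The processing chain is: collapse PCR duplicates on exact (position, UMI)
keys; drop reverse-transcription mispriming artifacts whose UMI reproduces
the genomic sequence adjacent to the read; extract the single-nucleotide
5'-position of each read (the 3'-end of the nascent RNA) onto the opposite
strand ("flip" convention); mask RNA-processing intermediate positions
(3'-most base of annotated exons/introns and polyA sites); and mask
annotated non-Pol-II / blacklisted regions. Every step conserves or
reduces the total count; none ever adds signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .model import AlignedRead, GeneModel, opposite
from .track import OccupancyTrack

__all__ = [
    "MaskSet",
    "collapse_duplicates",
    "filter_mispriming",
    "extract_occupancy",
    "intermediate_positions",
    "mask_intermediates",
    "mask_regions",
    "split_species",
    "reads_to_track",
]

log = logging.getLogger(__name__)

MASK_CLASSES = ("ncRNA", "blacklist", "intermediate")

_COMPLEMENT = str.maketrans("ACGTacgtN", "TGCAtgcaN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MaskSet:
    """Intervals (and single positions) removed from occupancy tracks.

    ``intervals`` maps chrom -> list of (start, end, cls, strand) with
    strand "." meaning both strands; ``cls`` is one of ``MASK_CLASSES``.
    """

    intervals: dict = field(default_factory=dict)

    def add(self, chrom: str, start: int, end: int, cls: str, strand: str = ".") -> None:
        if cls not in MASK_CLASSES:
            raise ValueError(f"unknown mask class {cls!r}")
        if start >= end:
            raise ValueError("empty mask interval")
        self.intervals.setdefault(chrom, []).append((start, end, cls, strand))

    def __len__(self) -> int:
        return sum(len(v) for v in self.intervals.values())


def collapse_duplicates(reads: Iterable[AlignedRead]) -> list[AlignedRead]:
    """Collapse reads sharing (chrom, start, end, strand, UMI) to one.

    Mirrors exact-key UMI deduplication (no edit-distance clustering): a
    PCR duplicate is an identical fragment carrying an identical UMI. The
    result is independent of input order; the representative read is the
    one sorting first on (sample, label, element) so that collapsing is
    deterministic even with heterogeneous truth annotations.
    """
    def rank(read):
        # non-duplicates win so truth annotations survive collapsing
        return (read.label == "duplicate", read.sample, read.label, read.element)

    by_key: dict[tuple, AlignedRead] = {}
    for read in reads:
        key = (read.chrom, read.start, read.end, read.strand, read.umi)
        prev = by_key.get(key)
        if prev is None or rank(read) < rank(prev):
            by_key[key] = read
    return [by_key[k] for k in sorted(by_key)]


def filter_mispriming(
    reads: Sequence[AlignedRead],
    genome: Mapping[str, str],
    side: str = "3prime",
) -> tuple[list[AlignedRead], int]:
    """Remove reads whose UMI matches the adjacent genomic sequence.

    During reverse transcription the RT primer can anneal to genomic
    sequence instead of the ligated adapter; such reads carry a "UMI" that
    is in fact the genomic k-mer adjacent to the alignment. A read is
    removed iff its UMI equals (case-insensitively) the genomic k-mer
    immediately adjacent to its 3' end in read orientation (``side`` may
    be set to "5prime" or "either" for other chemistries); k is the UMI
    length. Reads whose adjacent window runs off the chromosome are kept
    with a warning.
    """
    if side not in ("3prime", "5prime", "either"):
        raise ValueError(f"invalid side {side!r}")
    kept: list[AlignedRead] = []
    removed = 0
    for read in reads:
        seq = genome.get(read.chrom)
        if seq is None:
            raise KeyError(f"no genome sequence for {read.chrom}")
        k = len(read.umi)
        matches = []
        for s in (("3prime", "5prime") if side == "either" else (side,)):
            kmer = _adjacent_kmer(seq, read, k, s)
            if kmer is None:
                log.warning("adjacent window off chromosome end for read at "
                            "%s:%d-%d; kept", read.chrom, read.start, read.end)
                matches.append(False)
            else:
                matches.append(kmer.upper() == read.umi.upper())
        if any(matches):
            removed += 1
        else:
            kept.append(read)
    return kept, removed


def _adjacent_kmer(seq: str, read: AlignedRead, k: int, side: str) -> str | None:
    """Genomic k-mer adjacent to the read on the given side, in read orientation."""
    # 3' side in read orientation: downstream of `end` for +, upstream of
    # `start` (reverse-complemented) for -. The 5' side mirrors this.
    want_right = (read.strand == "+") == (side == "3prime")
    if want_right:
        if read.end + k > len(seq):
            return None
        kmer = seq[read.end:read.end + k]
    else:
        if read.start - k < 0:
            return None
        kmer = seq[read.start - k:read.start]
    return kmer if read.strand == "+" else revcomp(kmer)


def extract_occupancy(reads: Iterable[AlignedRead], flip: bool = True) -> OccupancyTrack:
    """Project each read to the single nucleotide occupied by polymerase.

    The 5'-most aligned base of the read (in read orientation) corresponds
    to the 3'-end of the purified nascent RNA fragment, i.e. the position
    of the engaged polymerase. Because the library is sequenced from the
    RNA 3'-end, the alignment strand is the reverse complement of the
    nascent RNA: with ``flip=True`` (default) the count is assigned to the
    strand opposite the alignment.
    """
    track = OccupancyTrack()
    for read in reads:
        strand = opposite(read.strand) if flip else read.strand
        track.add(read.chrom, strand, read.five_prime, 1)
    return track


def intermediate_positions(genes: Iterable[GeneModel]) -> dict[tuple[str, str], set[int]]:
    """(chrom, strand) -> 3'-most positions of annotated exons/introns + polyA sites."""
    out: dict[tuple[str, str], set[int]] = {}
    for gene in genes:
        positions = out.setdefault((gene.chrom, gene.strand), set())
        for iso in gene.isoforms:
            for s, e in iso.exons + iso.introns:
                # 3'-most base in transcript orientation
                positions.add(e - 1 if gene.strand == "+" else s)
            positions.add(iso.polya)
    return out


def mask_intermediates(
    track: OccupancyTrack,
    genes: Iterable[GeneModel],
    maskset: MaskSet | None = None,
) -> OccupancyTrack:
    """Delete RNA-processing intermediate positions from the track.

    Splicing and 3'-end cleavage leave RNA fragments whose 3'-ends sit at
    the last nucleotide of exons/introns and at polyA sites; those single
    positions (on the annotation's strand) are removed and recorded in the
    MaskSet (class "intermediate") so downstream metaprofiles skip them.
    """
    out = track.copy()
    for (chrom, strand), positions in intermediate_positions(genes).items():
        out.delete_positions(chrom, positions, strand)
        if maskset is not None:
            for pos in sorted(positions):
                maskset.add(chrom, pos, pos + 1, "intermediate", strand)
    return out


def mask_regions(track: OccupancyTrack, masks: MaskSet) -> OccupancyTrack:
    """Delete all positions inside mask intervals (both strands unless set)."""
    out = track.copy()
    for chrom, entries in masks.intervals.items():
        for start, end, _cls, strand in entries:
            out.delete_positions(
                chrom, range(start, end), None if strand == "." else strand
            )
    return out


def split_species(
    reads: Iterable[AlignedRead], spike_prefix: str = "spike_"
) -> tuple[list[AlignedRead], list[AlignedRead]]:
    """Partition reads into (primary, spike-in) by reference-name prefix.

    Spike-in material from a second species is carried on reference
    sequences named with a reserved prefix; the split is exhaustive and
    disjoint, so read counts are conserved.
    """
    primary: list[AlignedRead] = []
    spike: list[AlignedRead] = []
    for read in reads:
        (spike if read.chrom.startswith(spike_prefix) else primary).append(read)
    return primary, spike


def reads_to_track(
    reads: Sequence[AlignedRead],
    genome: Mapping[str, str],
    genes: Iterable[GeneModel] = (),
    masks: MaskSet | None = None,
    flip: bool = True,
    mispriming_side: str = "3prime",
) -> OccupancyTrack:
    """Full chain: collapse -> mispriming filter -> extract -> masks."""
    reads = collapse_duplicates(reads)
    reads, _ = filter_mispriming(reads, genome, side=mispriming_side)
    track = extract_occupancy(reads, flip=flip)
    genes = list(genes)
    if genes:
        track = mask_intermediates(track, genes)
    if masks is not None and len(masks):
        track = mask_regions(track, masks)
    return track
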