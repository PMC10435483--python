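"""De-novo transcription-unit calling from stranded occupancy tracks.

A transparent gap-merge caller: per (chrom, strand), covered positions
(count >= a per-base threshold, default 1) are merged into maximal runs
where consecutive covered positions lie at most ``max_gap`` apart; runs
shorter than ``min_body`` or with fewer than ``min_count`` reads are
dropped. Runs longer than ``max_init_body`` are kept whole — the caller
never splits a unit at internal dips. The behaviour is deliberately
simple enough to check against exhaustive run enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import TranscriptionUnit
from .track import OccupancyTrack

__all__ = ["TUParams", "call_transcription_units"]


@dataclass(frozen=True)
class TUParams:
    max_gap: int = 250        # bp; larger gaps split runs
    min_count: int = 10       # reads; runs below are dropped
    min_body: int = 150       # bp; shorter runs are dropped
    max_init_body: int = 500  # bp; longer runs are kept whole (no splitting)
    min_cov: int = 1          # per-base count for a position to be "covered"

    def __post_init__(self):
        for name in ("max_gap", "min_count", "min_body", "max_init_body", "min_cov"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def call_transcription_units(
    track: OccupancyTrack, params: TUParams | None = None
) -> list[TranscriptionUnit]:
    """Call TUs on every (chrom, strand) of the track.

    Returns units sorted by (chrom, strand, start); units on one strand
    never overlap each other by construction.
    """
    params = params or TUParams()
    units: list[TranscriptionUnit] = []
    serial = 0
    for chrom, strand in track.keys():
        counter = track.counter(chrom, strand)
        covered = sorted(p for p, n in counter.items() if n >= params.min_cov)
        if not covered:
            continue
        run_start = covered[0]
        prev = covered[0]
        run_count = counter[covered[0]]
        for pos in covered[1:]:
            if pos - prev > params.max_gap:
                serial += _emit(units, chrom, strand, run_start, prev, run_count,
                                params, serial)
                run_start = pos
                run_count = 0
            run_count += counter[pos]
            prev = pos
        serial += _emit(units, chrom, strand, run_start, prev, run_count,
                        params, serial)
    units.sort(key=lambda u: (u.chrom, u.strand, u.start))
    return units


def _emit(units, chrom, strand, start, last, count, params, serial) -> int:
    length = last + 1 - start
    if length < params.min_body or count < params.min_count:
        return 0
    units.append(TranscriptionUnit(
        chrom=chrom, strand=strand, start=start, end=last + 1,
        total_count=count, tu_id=f"TU{serial:05d}_{chrom}{strand}",
    ))
    return 1
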