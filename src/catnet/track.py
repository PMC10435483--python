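"""Stranded sparse single-nucleotide occupancy tracks.

An :class:`OccupancyTrack` maps ``(chrom, strand)`` to a sparse
``position -> count`` table. It is the central currency of the pipeline:
every base with engaged polymerase signal carries a nonnegative integer
count; masked positions are *absent*, not zero, so metaprofiles can skip
them rather than average in artificial dips.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = ["OccupancyTrack"]


class OccupancyTrack:
    """Sparse per-base counts keyed by (chrom, strand)."""

    def __init__(self):
        self._data: dict[tuple[str, str], Counter] = {}

    # -- construction -------------------------------------------------
    @classmethod
    def from_positions(
        cls, items: Iterable[tuple[str, str, int, int]]
    ) -> "OccupancyTrack":
        """Build from ``(chrom, strand, position, count)`` tuples."""
        t = cls()
        for chrom, strand, pos, count in items:
            t.add(chrom, strand, pos, count)
        return t

    @classmethod
    def from_arrays(
        cls, chrom: str, strand: str, positions: np.ndarray, counts: np.ndarray
    ) -> "OccupancyTrack":
        t = cls()
        t.add_arrays(chrom, strand, positions, counts)
        return t

    def add(self, chrom: str, strand: str, pos: int, count: int = 1) -> None:
        if count < 0:
            raise ValueError("negative count")
        if count == 0:
            return
        self._data.setdefault((chrom, strand), Counter())[int(pos)] += int(count)

    def add_arrays(
        self, chrom: str, strand: str, positions: np.ndarray, counts: np.ndarray
    ) -> None:
        nz = counts > 0
        if (counts < 0).any():
            raise ValueError("negative count")
        c = self._data.setdefault((chrom, strand), Counter())
        for p, k in zip(positions[nz].tolist(), counts[nz].tolist()):
            c[int(p)] += int(k)

    # -- access -------------------------------------------------------
    def keys(self) -> list[tuple[str, str]]:
        return sorted(self._data)

    def chroms(self) -> list[str]:
        return sorted({c for c, _ in self._data})

    def counter(self, chrom: str, strand: str) -> Counter:
        return self._data.get((chrom, strand), Counter())

    def get(self, chrom: str, strand: str, pos: int) -> int:
        return self._data.get((chrom, strand), {}).get(pos, 0)

    def items(self) -> Iterator[tuple[str, str, int, int]]:
        for (chrom, strand), counter in sorted(self._data.items()):
            for pos in sorted(counter):
                yield chrom, strand, pos, counter[pos]

    def total(self) -> int:
        return sum(sum(c.values()) for c in self._data.values())

    def n_positions(self) -> int:
        return sum(len(c) for c in self._data.values())

    def region_sum(self, chrom: str, start: int, end: int, strand: str | None = None) -> int:
        """Sum of counts over ``[start, end)`` on one strand, or both if None."""
        strands = ("+", "-") if strand is None else (strand,)
        total = 0
        for s in strands:
            counter = self._data.get((chrom, s))
            if not counter:
                continue
            if end - start < len(counter):
                total += sum(counter.get(p, 0) for p in range(start, end))
            else:
                total += sum(k for p, k in counter.items() if start <= p < end)
        return total

    # -- transforms ---------------------------------------------------
    def copy(self) -> "OccupancyTrack":
        t = OccupancyTrack()
        for key, counter in self._data.items():
            t._data[key] = Counter(counter)
        return t

    def delete_positions(
        self, chrom: str, positions: Iterable[int], strand: str | None = None
    ) -> int:
        """Delete positions (on one or both strands); return count removed."""
        strands = ("+", "-") if strand is None else (strand,)
        removed = 0
        for s in strands:
            counter = self._data.get((chrom, s))
            if not counter:
                continue
            for pos in positions:
                removed += counter.pop(pos, 0)
        return removed

    def __eq__(self, other) -> bool:
        if not isinstance(other, OccupancyTrack):
            return NotImplemented
        a = {k: {p: n for p, n in c.items() if n} for k, c in self._data.items()}
        b = {k: {p: n for p, n in c.items() if n} for k, c in other._data.items()}
        a = {k: v for k, v in a.items() if v}
        b = {k: v for k, v in b.items() if v}
        return a == b

    # -- IO -----------------------------------------------------------
    def to_bedgraph(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write one bedGraph per strand (``<prefix>.plus/.minus.bedgraph``)."""
        prefix = Path(prefix)
        paths = []
        for strand, tag in (("+", "plus"), ("-", "minus")):
            path = prefix.with_name(prefix.name + f".{tag}.bedgraph")
            rows = []
            for (chrom, s), counter in sorted(self._data.items()):
                if s != strand:
                    continue
                for pos in sorted(counter):
                    if counter[pos]:
                        rows.append((chrom, pos, pos + 1, counter[pos]))
            pd.DataFrame(rows, columns=["chrom", "start", "end", "count"]).to_csv(
                path, sep="\t", header=False, index=False
            )
            paths.append(path)
        return tuple(paths)

    @classmethod
    def from_bedgraph(cls, plus: str | Path, minus: str | Path) -> "OccupancyTrack":
        t = cls()
        for path, strand in ((plus, "+"), (minus, "-")):
            path = Path(path)
            if path.stat().st_size == 0:
                continue
            df = pd.read_csv(path, sep="\t", header=None,
                             names=["chrom", "start", "end", "count"])
            for row in df.itertuples(index=False):
                for pos in range(row.start, row.end):
                    t.add(row.chrom, strand, pos, int(row.count))
        return t

    def __repr__(self) -> str:
        return (f"OccupancyTrack({len(self._data)} chrom/strand tables, "
                f"{self.n_positions()} positions, total={self.total()})")
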