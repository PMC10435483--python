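"""Core domain objects shared across the pipeline.

Coordinates are 0-based, half-open throughout the package; GTF (1-based,
closed) is converted at the IO boundary. ``tss`` and ``polya`` are single
0-based positions: the first and last transcribed base of an isoform in its
own orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "AlignedRead",
    "Isoform",
    "GeneModel",
    "TranscriptionUnit",
    "ATUCall",
    "EnhancerCall",
    "Contact",
]

STRANDS = ("+", "-")


def opposite(strand: str) -> str:
    if strand == "+":
        return "-"
    if strand == "-":
        return "+"
    raise ValueError(f"invalid strand {strand!r}")


@dataclass(frozen=True)
class AlignedRead:
    """A uniquely aligned sequencing read with its UMI.

    ``start``/``end`` follow BED semantics (0-based, half-open). ``label``
    and ``element`` are simulation-truth annotations and are ignored by the
    processing code; real input leaves them at their defaults.
    """

    chrom: str
    start: int
    end: int
    strand: str
    umi: str
    sample: str = "sample"
    label: str = "genuine"
    element: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty read interval [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def five_prime(self) -> int:
        """5'-most aligned base in read orientation."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class Isoform:
    isoform_id: str
    exons: tuple[tuple[int, int], ...]  # sorted by coordinate, half-open
    strand: str
    tpm: float = 0.0

    def __post_init__(self):
        if not self.exons:
            raise ValueError("isoform without exons")
        for s, e in self.exons:
            if s >= e:
                raise ValueError("empty exon")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """First transcribed base (0-based) in isoform orientation."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def polya(self) -> int:
        """Last transcribed base (0-based) in isoform orientation."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )


@dataclass
class GeneModel:
    """A gene with its isoforms, activity call and refined TSS/polyA sets."""

    gene_id: str
    chrom: str
    strand: str
    isoforms: list[Isoform] = field(default_factory=list)
    active: bool = False
    active_tss: frozenset = frozenset()
    active_polya: frozenset = frozenset()

    @property
    def start(self) -> int:
        return min(i.start for i in self.isoforms)

    @property
    def end(self) -> int:
        return max(i.end for i in self.isoforms)

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end

    @property
    def tpm(self) -> float:
        """Overall gene activity: sum of isoform TPMs."""
        return sum(i.tpm for i in self.isoforms)

    @property
    def tss(self) -> int:
        """5'-most annotated TSS in gene orientation."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def first_active_tss(self) -> int:
        if not self.active_tss:
            raise ValueError(f"{self.gene_id}: no active TSS")
        return min(self.active_tss) if self.strand == "+" else max(self.active_tss)

    @property
    def last_active_polya(self) -> int:
        if not self.active_polya:
            raise ValueError(f"{self.gene_id}: no active polyA")
        return max(self.active_polya) if self.strand == "+" else min(self.active_polya)

    @property
    def effective_span(self) -> tuple[int, int]:
        """[first active TSS, last active polyA] as a half-open interval."""
        if self.strand == "+":
            return self.first_active_tss, self.last_active_polya + 1
        return self.last_active_polya, self.first_active_tss + 1

    def all_tss(self) -> frozenset:
        return frozenset(i.tss for i in self.isoforms)

    def copy(self) -> "GeneModel":
        return replace(self, isoforms=list(self.isoforms))


@dataclass(frozen=True)
class TranscriptionUnit:
    """A contiguous nascently transcribed segment called from a track."""

    chrom: str
    strand: str
    start: int
    end: int
    total_count: int
    tu_id: str = ""

    @property
    def origin(self) -> int:
        """5'-most position in TU orientation."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


# Antisense classification outcomes.
CLS_CAT = "CAT"
CLS_DAT = "DAT"
CLS_DISCARDED = "discarded"

REASON_NONE = "none"
REASON_OVERLAPPING_GENE = "overlapping_gene"
REASON_COVERS_ANTISENSE_GENE = "covers_antisense_gene"
REASON_ALT_PROMOTER = "alt_promoter"


@dataclass(frozen=True)
class ATUCall:
    """Classification of one antisense transcription unit."""

    tu: TranscriptionUnit
    host_gene: str
    cls: str = ""
    discard_reason: str = REASON_NONE


@dataclass(frozen=True)
class EnhancerCall:
    """A putative transcribed enhancer (intragenic or extragenic)."""

    enh_id: str
    kind: str  # intragenic | extragenic
    directionality: str  # bidirectional | unidirectional
    chrom: str
    start: int
    end: int
    center: int
    member_tus: tuple[TranscriptionUnit, ...]
    host_gene: str = ""
    marks_present: frozenset = frozenset()


@dataclass(frozen=True)
class Contact:
    """One significant 3D interaction between two anchor bins."""

    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int
    padj: float
    log2fc: float = float("nan")
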