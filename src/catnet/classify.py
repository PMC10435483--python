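"""Antisense classification (CAT/DAT) and putative-enhancer calling.

Gene-associated antisense transcription comes in two flavours with very
different interpretations: divergent antisense transcription (DAT)
originates within 1 kb *upstream* of a gene's TSS on the opposite strand
and reflects ordinary bidirectional promoter activity, while convergent
antisense transcription (CAT) originates *downstream* of the TSS inside
the gene and — when it co-localizes with the enhancer chromatin marks
H3K27ac and H3K4me1 — is the signature of an intragenic enhancer.
Extragenic enhancers are called from transcription units distal to all
active genes, away from annotated promoters and termination zones, with
divergent pairs originating within 500 bp merged into bidirectional
calls. All distance rules use strict inequalities at their stated bounds.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Mapping, Sequence

from .model import (
    ATUCall,
    CLS_CAT,
    CLS_DAT,
    CLS_DISCARDED,
    EnhancerCall,
    GeneModel,
    REASON_ALT_PROMOTER,
    REASON_COVERS_ANTISENSE_GENE,
    REASON_NONE,
    REASON_OVERLAPPING_GENE,
    TranscriptionUnit,
    opposite,
)

__all__ = [
    "ClassifyParams",
    "find_antisense_units",
    "filter_overlapping_gene_atus",
    "classify_atu",
    "classify_antisense",
    "call_intragenic_enhancers",
    "call_extragenic_enhancers",
]


from dataclasses import dataclass


@dataclass(frozen=True)
class ClassifyParams:
    dat_window: int = 1000          # bp; DAT origin strictly < this upstream of a TSS
    overlap_tu_frac: float = 0.50   # discard if >= this fraction of the TU overlaps a same-strand gene
    overlap_gene_frac: float = 0.90  # ... or the TU covers >= this fraction of that gene
    bidirectional_dist: int = 500   # bp; origin pairs strictly closer merge
    promoter_halfwidth: int = 500   # bp each side of every annotated isoform TSS
    termination_zone: int = 2000    # bp downstream of active polyA sites
    require_cat_in_span: bool = True


def _ovl(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def find_antisense_units(
    tus: Iterable[TranscriptionUnit], genes: Sequence[GeneModel]
) -> list[ATUCall]:
    """Candidate ATUs: TUs overlapping an active gene on the opposite strand.

    The host is the overlapped active gene with the greatest overlap;
    ties break to the gene whose first active TSS is nearest the TU
    origin, then to gene id.
    """
    active = [g for g in genes if g.active]
    calls = []
    for tu in tus:
        best = None
        for g in active:
            if g.chrom != tu.chrom or g.strand != opposite(tu.strand):
                continue
            ovl = _ovl(tu.start, tu.end, g.start, g.end)
            if ovl <= 0:
                continue
            key = (-ovl, abs(tu.origin - g.first_active_tss), g.gene_id)
            if best is None or key < best[0]:
                best = (key, g)
        if best is not None:
            calls.append(ATUCall(tu=tu, host_gene=best[1].gene_id))
    return calls


def filter_overlapping_gene_atus(
    candidate: ATUCall,
    genes: Sequence[GeneModel],
    genes_by_id: Mapping[str, GeneModel],
    params: ClassifyParams | None = None,
) -> ATUCall:
    """Discard ATUs that plausibly originate from a neighbouring gene.

    Spill-over control: a transcript originates from an overlapping
    same-strand gene if at least half the TU lies inside that gene, or
    the TU covers at least 90% of it. Separately, a TU blanketing the
    entire antisense host gene (common over very short genes) is
    discarded as uninformative.
    """
    params = params or ClassifyParams()
    tu = candidate.tu
    for g in genes:
        if g.chrom != tu.chrom or g.strand != tu.strand:
            continue  # same-strand relative to the TU, i.e. not the antisense host
        ovl = _ovl(tu.start, tu.end, g.start, g.end)
        if ovl <= 0:
            continue
        if ovl / tu.length >= params.overlap_tu_frac or ovl / (g.end - g.start) >= params.overlap_gene_frac:
            return replace(candidate, cls=CLS_DISCARDED,
                           discard_reason=REASON_OVERLAPPING_GENE)
    host = genes_by_id[candidate.host_gene]
    if tu.start <= host.start and tu.end >= host.end:
        return replace(candidate, cls=CLS_DISCARDED,
                       discard_reason=REASON_COVERS_ANTISENSE_GENE)
    return candidate


def classify_atu(
    candidate: ATUCall,
    host: GeneModel,
    params: ClassifyParams | None = None,
) -> ATUCall:
    """Assign CAT or DAT relative to the host's *active* TSS set.

    DAT: the TU origin lies strictly within ``dat_window`` upstream of
    any active TSS of the host in host orientation — including
    downstream alternative TSSs, so convergent-looking units that are in
    fact the divergent partner of an internal promoter are reassigned to
    DAT. Otherwise CAT if the origin lies downstream of the first active
    TSS (inside the host span by default). Anything else is discarded as
    promoter-ambiguous.
    """
    params = params or ClassifyParams()
    if not host.active_tss:
        raise ValueError(f"host {host.gene_id} has no active TSS")
    origin = candidate.tu.origin
    sign = 1 if host.strand == "+" else -1
    for tss in host.active_tss:
        upstream = (tss - origin) * sign  # >0: origin upstream of this TSS
        if 0 < upstream < params.dat_window:
            return replace(candidate, cls=CLS_DAT, discard_reason=REASON_NONE)
    first_tss = host.first_active_tss
    downstream = (origin - first_tss) * sign
    in_span = host.start <= origin < host.end
    if downstream > 0 and (in_span or not params.require_cat_in_span):
        return replace(candidate, cls=CLS_CAT, discard_reason=REASON_NONE)
    return replace(candidate, cls=CLS_DISCARDED, discard_reason=REASON_ALT_PROMOTER)


def classify_antisense(
    tus: Iterable[TranscriptionUnit],
    genes: Sequence[GeneModel],
    params: ClassifyParams | None = None,
) -> list[ATUCall]:
    """Full antisense chain: find candidates, filter spill-over, classify."""
    params = params or ClassifyParams()
    genes_by_id = {g.gene_id: g for g in genes}
    out = []
    for cand in find_antisense_units(tus, genes):
        cand = filter_overlapping_gene_atus(cand, genes, genes_by_id, params)
        if cand.cls != CLS_DISCARDED:
            cand = classify_atu(cand, genes_by_id[cand.host_gene], params)
        out.append(cand)
    return out


def _has_both_marks(
    chrom: str, start: int, end: int, peaks: Mapping[str, Mapping[str, list]]
) -> frozenset:
    """Marks whose peak list intersects [start, end) by >= 1 bp."""
    present = set()
    for mark, by_chrom in peaks.items():
        for ps, pe in by_chrom.get(chrom, ()):
            if _ovl(start, end, ps, pe) > 0:
                present.add(mark)
                break
    return frozenset(present)


def _check_peaks(peaks) -> None:
    missing = {"H3K27ac", "H3K4me1"} - set(peaks)
    if missing:
        raise ValueError(f"missing peak set(s): {sorted(missing)}")


def call_intragenic_enhancers(
    cats: Sequence[ATUCall],
    peaks: Mapping[str, Mapping[str, list]],
    params: ClassifyParams | None = None,
) -> list[EnhancerCall]:
    """Intragenic enhancers: CAT units co-localizing with both enhancer marks.

    ``peaks`` maps mark name ("H3K27ac", "H3K4me1") -> chrom -> interval
    list. One call per qualifying CAT; the center is the CAT origin.
    """
    _check_peaks(peaks)
    calls = []
    for cand in cats:
        if cand.cls != CLS_CAT:
            raise ValueError("call_intragenic_enhancers expects CAT units")
        tu = cand.tu
        marks = _has_both_marks(tu.chrom, tu.start, tu.end, peaks)
        if {"H3K27ac", "H3K4me1"} <= marks:
            calls.append(EnhancerCall(
                enh_id=f"intra_{tu.tu_id or tu.origin}",
                kind="intragenic",
                directionality="unidirectional",
                chrom=tu.chrom, start=tu.start, end=tu.end,
                center=tu.origin,
                member_tus=(tu,),
                host_gene=cand.host_gene,
                marks_present=marks,
            ))
    return calls


def extragenic_eligible(
    tus: Iterable[TranscriptionUnit],
    genes: Sequence[GeneModel],
    params: ClassifyParams | None = None,
) -> list[TranscriptionUnit]:
    """TUs distal to active genes, outside promoter windows and termination zones.

    Eligibility (all genome-wide, both strands for the gene-overlap rule):
    the TU must not overlap any active gene's effective span; its origin
    must not fall inside any annotated isoform TSS +/- promoter_halfwidth
    (active or not); and its origin must not lie in any active gene's
    termination zone [polyA, polyA + termination_zone) in gene orientation.
    """
    params = params or ClassifyParams()
    eligible = []
    for tu in tus:
        ok = True
        for g in genes:
            if g.chrom != tu.chrom:
                continue
            if g.active:
                es, ee = g.effective_span
                if _ovl(tu.start, tu.end, es, ee) > 0:
                    ok = False
                    break
                for pa in g.active_polya:
                    lo, hi = (pa, pa + params.termination_zone + 1) if g.strand == "+" \
                        else (pa - params.termination_zone, pa + 1)
                    if lo <= tu.origin < hi:
                        ok = False
                        break
                if not ok:
                    break
            for iso in g.isoforms:
                if abs(tu.origin - iso.tss) <= params.promoter_halfwidth:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            eligible.append(tu)
    return eligible


def pair_bidirectional(
    tus: Sequence[TranscriptionUnit], max_dist: int = 500
) -> tuple[list[tuple[TranscriptionUnit, TranscriptionUnit]], list[TranscriptionUnit]]:
    """Greedy nearest-origin pairing of opposite-strand TUs (< max_dist, strict).

    Candidate pairs are sorted by origin distance then coordinates; each
    TU is used at most once, so the result is deterministic and
    order-independent.
    """
    tus = list(tus)
    cand = []
    for i, a in enumerate(tus):
        for j in range(i + 1, len(tus)):
            b = tus[j]
            if a.chrom != b.chrom or a.strand == b.strand:
                continue
            d = abs(a.origin - b.origin)
            if d < max_dist:
                ka = (a.chrom, a.start, a.end, a.strand)
                kb = (b.chrom, b.start, b.end, b.strand)
                if kb < ka:
                    ka, kb, ii, jj = kb, ka, j, i
                else:
                    ii, jj = i, j
                cand.append((d, ka, kb, ii, jj))
    cand.sort()
    used: set[int] = set()
    pairs = []
    for _d, _ka, _kb, i, j in cand:
        if i in used or j in used:
            continue
        used.update((i, j))
        a, b = tus[i], tus[j]
        if (b.start, b.end, b.strand) < (a.start, a.end, a.strand):
            a, b = b, a
        pairs.append((a, b))
    singles = [tu for k, tu in enumerate(tus) if k not in used]
    return pairs, singles


def call_extragenic_enhancers(
    tus: Iterable[TranscriptionUnit],
    genes: Sequence[GeneModel],
    peaks: Mapping[str, Mapping[str, list]],
    params: ClassifyParams | None = None,
) -> list[EnhancerCall]:
    """Extragenic enhancers: distal divergent (or unpaired) TUs with both marks.

    Eligible TUs (see :func:`extragenic_eligible`) are first paired into
    bidirectional candidates where opposite-strand origins lie strictly
    within ``bidirectional_dist`` of each other; leftovers are
    unidirectional candidates. Every emitted call must overlap at least
    1 bp of an H3K27ac peak and of an H3K4me1 peak. Bidirectional centers
    are the midpoint of the two origins; unidirectional centers the
    origin itself.
    """
    params = params or ClassifyParams()
    _check_peaks(peaks)
    eligible = extragenic_eligible(tus, genes, params)
    pairs, singles = pair_bidirectional(eligible, params.bidirectional_dist)
    calls = []
    for a, b in pairs:
        start, end = min(a.start, b.start), max(a.end, b.end)
        marks = _has_both_marks(a.chrom, start, end, peaks)
        if {"H3K27ac", "H3K4me1"} <= marks:
            center = (a.origin + b.origin) // 2
            calls.append(EnhancerCall(
                enh_id=f"extra_bi_{a.chrom}_{center}",
                kind="extragenic", directionality="bidirectional",
                chrom=a.chrom, start=start, end=end, center=center,
                member_tus=(a, b), marks_present=marks,
            ))
    for tu in singles:
        marks = _has_both_marks(tu.chrom, tu.start, tu.end, peaks)
        if {"H3K27ac", "H3K4me1"} <= marks:
            calls.append(EnhancerCall(
                enh_id=f"extra_uni_{tu.chrom}_{tu.origin}",
                kind="extragenic", directionality="unidirectional",
                chrom=tu.chrom, start=tu.start, end=tu.end, center=tu.origin,
                member_tus=(tu,), marks_present=marks,
            ))
    calls.sort(key=lambda c: (c.chrom, c.start, c.end))
    return calls
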