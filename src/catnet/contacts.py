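"""Enhancer -> target-gene assignment via significant 3D contacts.

Chromosome-conformation (HiChIP-style) anchor pairs link an enhancer to a
gene when one anchor overlaps the enhancer interval and the other the
gene's effective span extended by a promoter window (contact bins cannot
separate the promoter from the promoter-proximal region, so the window is
included on the TSS side). Responsive enhancers — those with a
significant *loss* of Pol II occupancy under perturbation — are then
counted per target gene.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import pandas as pd

from .model import Contact, EnhancerCall, GeneModel

__all__ = ["assign_targets", "count_responsive_enhancers", "responsive_strata"]

log = logging.getLogger(__name__)


def _ovl(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def _gene_anchor_span(gene: GeneModel, promoter_halfwidth: int) -> tuple[int, int]:
    es, ee = gene.effective_span if gene.active_tss else gene.span
    if gene.strand == "+":
        return es - promoter_halfwidth, ee
    return es, ee + promoter_halfwidth


def assign_targets(
    enhancers: Sequence[EnhancerCall],
    genes: Sequence[GeneModel],
    contacts: Sequence[Contact],
    sig_threshold: float = 0.01,
    promoter_halfwidth: int = 500,
) -> pd.DataFrame:
    """Assign each enhancer the genes it touches through significant contacts.

    An assignment requires at least one contact with padj < sig_threshold
    where one anchor overlaps the enhancer interval and the other anchor
    overlaps the gene span (promoter window included); anchor order is
    irrelevant. Returns a tidy frame (enhancer_id, gene_id, n_contacts,
    min_padj).
    """
    gene_spans = [
        (g.gene_id, g.chrom, *_gene_anchor_span(g, promoter_halfwidth))
        for g in genes
    ]
    rows: dict[tuple[str, str], list[float]] = {}
    for c in contacts:
        if not (c.padj < sig_threshold):
            continue
        anchors = ((c.chrom1, c.start1, c.end1), (c.chrom2, c.start2, c.end2))
        for ea, ga in ((0, 1), (1, 0)):
            ec, es, ee = anchors[ea]
            gc, gs, ge = anchors[ga]
            for enh in enhancers:
                if enh.chrom != ec or _ovl(enh.start, enh.end, es, ee) <= 0:
                    continue
                for gid, gchrom, g_s, g_e in gene_spans:
                    if gchrom == gc and _ovl(g_s, g_e, gs, ge) > 0:
                        rows.setdefault((enh.enh_id, gid), []).append(c.padj)
    records = [
        (eid, gid, len(padjs), min(padjs))
        for (eid, gid), padjs in sorted(rows.items())
    ]
    return pd.DataFrame(records,
                        columns=["enhancer_id", "gene_id", "n_contacts", "min_padj"])


def count_responsive_enhancers(
    assignment: pd.DataFrame,
    enhancer_results: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.Series:
    """Per gene, count assigned enhancers with a significant occupancy loss.

    Responsive: padj < alpha AND log2fc < 0 in ``enhancer_results``
    (indexed by enhancer id with columns log2fc, padj). Enhancers missing
    from the results are counted as non-responsive with a warning.
    """
    if assignment.empty:
        return pd.Series(dtype=int)
    responsive_ids = set(
        enhancer_results.index[
            (enhancer_results["padj"] < alpha) & (enhancer_results["log2fc"] < 0)
        ]
    )
    missing = set(assignment["enhancer_id"]) - set(enhancer_results.index)
    if missing:
        log.warning("%d assigned enhancer(s) missing from differential results; "
                    "counted as non-responsive", len(missing))
    counts: dict[str, int] = {}
    for gid, grp in assignment.groupby("gene_id"):
        counts[gid] = sum(1 for e in set(grp["enhancer_id"]) if e in responsive_ids)
    return pd.Series(counts, dtype=int).sort_index()


def responsive_strata(counts: Mapping[str, int]) -> pd.Series:
    """Map per-gene responsive-enhancer counts onto the strata 0 / 1 / >=2."""
    return pd.Series(
        {g: ("0" if n == 0 else "1" if n == 1 else ">=2") for g, n in counts.items()}
    )
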