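"""Active-gene calling and isoform-level TSS/polyA refinement.

A gene is considered actively transcribed when steady-state expression
(TPM from an external quantification) reaches a threshold AND nascent
transcription is observed over the gene on its own strand. Active genes
then get a refined coordinate model: only isoforms contributing at least
a minimum share of the gene's overall activity define the active TSS and
polyA sets, and the gene's effective span runs from the first active TSS
to the last active polyA in gene orientation.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

from dataclasses import replace

from .model import GeneModel, TranscriptionUnit

__all__ = ["apply_expression", "call_active_genes", "refine_active_isoforms"]

log = logging.getLogger(__name__)


def apply_expression(
    genes: Sequence[GeneModel], expression: Mapping[str, Mapping[str, float]]
) -> list[GeneModel]:
    """Attach isoform TPM values from a {gene_id: {isoform_id: tpm}} table.

    Isoforms absent from the table get TPM 0; table rows referencing
    unknown genes or isoforms are ignored with a warning.
    """
    known = {g.gene_id for g in genes}
    for gid in expression:
        if gid not in known:
            log.warning("expression row for unknown gene %s ignored", gid)
    out = []
    for gene in genes:
        iso_tpm = expression.get(gene.gene_id, {})
        unknown = set(iso_tpm) - {i.isoform_id for i in gene.isoforms}
        if unknown:
            log.warning("unknown isoforms %s for gene %s ignored", unknown, gene.gene_id)
        isoforms = [
            replace(iso, tpm=float(iso_tpm.get(iso.isoform_id, 0.0)))
            for iso in gene.isoforms
        ]
        g = gene.copy()
        g.isoforms = isoforms
        out.append(g)
    return out


def call_active_genes(
    genes: Sequence[GeneModel],
    tus: Iterable[TranscriptionUnit],
    tpm_threshold: float = 1.0,
) -> list[GeneModel]:
    """Flag genes as active: TPM >= threshold and a sense TU overlapping.

    ``tus`` are de-novo nascent transcription units; a gene without any
    same-strand TU overlapping its annotated span shows no nascent
    transcription and stays inactive regardless of its TPM.
    """
    tu_by_key: dict[tuple[str, str], list[TranscriptionUnit]] = {}
    for tu in tus:
        tu_by_key.setdefault((tu.chrom, tu.strand), []).append(tu)
    out = []
    for gene in genes:
        g = gene.copy()
        expressed = g.tpm >= tpm_threshold
        transcribed = any(
            tu.start < g.end and g.start < tu.end
            for tu in tu_by_key.get((g.chrom, g.strand), ())
        )
        g.active = bool(expressed and transcribed)
        if g.active:
            g = refine_active_isoforms(g)
        else:
            g.active_tss = frozenset()
            g.active_polya = frozenset()
        out.append(g)
    return out


def refine_active_isoforms(gene: GeneModel, min_share: float = 0.10) -> GeneModel:
    """Restrict the gene's TSS/polyA sets to isoforms carrying >= min_share.

    An isoform is active iff its TPM is at least ``min_share`` of the
    gene's overall activity (sum of isoform TPMs). Ties at identical
    coordinates collapse into the position sets.
    """
    total = gene.tpm
    if total <= 0:
        raise ValueError(f"{gene.gene_id}: active gene with zero total TPM")
    active_isoforms = [i for i in gene.isoforms if i.tpm / total >= min_share]
    g = gene.copy()
    g.active_tss = frozenset(i.tss for i in active_isoforms)
    g.active_polya = frozenset(i.polya for i in active_isoforms)
    return g
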