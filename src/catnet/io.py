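"""Readers and writers for the standard formats at the package boundary.

Internal coordinates are 0-based half-open; GTF (1-based, closed) is
converted here and nowhere else. SAM carries the UMI in a tag (default
``RX``); species is implicit in the reference name (spike-in references
use a reserved prefix).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
import pysam
from pyfaidx import Fasta

from .model import AlignedRead, Contact, EnhancerCall, GeneModel, Isoform
from .occupancy import MaskSet

__all__ = [
    "write_fasta", "read_fasta",
    "write_gtf", "read_gtf",
    "write_sam", "read_sam",
    "write_bed", "read_bed",
    "write_mask_bed", "read_mask_bed",
    "read_expression_tsv", "write_expression_tsv",
    "read_contacts", "write_contacts",
    "write_enhancer_bed",
]


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    return path


def read_fasta(path: str | Path) -> dict:
    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_gtf(genes: Sequence[GeneModel], path: str | Path) -> Path:
    """GTF out: gene/transcript/exon features, 1-based closed coordinates."""
    path = Path(path)
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            attrs = f'gene_id "{g.gene_id}";'
            fh.write("\t".join([g.chrom, "catnet", "gene", str(g.start + 1),
                                str(g.end), ".", g.strand, ".", attrs]) + "\n")
            for iso in g.isoforms:
                tattrs = (f'gene_id "{g.gene_id}"; '
                          f'transcript_id "{iso.isoform_id}";')
                fh.write("\t".join([g.chrom, "catnet", "transcript",
                                    str(iso.start + 1), str(iso.end), ".",
                                    g.strand, ".", tattrs]) + "\n")
                for s, e in iso.exons:
                    fh.write("\t".join([g.chrom, "catnet", "exon", str(s + 1),
                                        str(e), ".", g.strand, ".", tattrs]) + "\n")
    return path


def read_gtf(path: str | Path) -> list[GeneModel]:
    """GTF in: rebuild gene models (exon features grouped by transcript)."""
    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique",
                            disable_infer_genes=True,
                            disable_infer_transcripts=True)
    genes: dict[str, GeneModel] = {}
    tx: dict[str, dict] = {}
    for feat in db.all_features():
        gid = feat.attributes.get("gene_id", [""])[0]
        if feat.featuretype == "gene":
            genes[gid] = GeneModel(gene_id=gid, chrom=feat.seqid,
                                   strand=feat.strand, isoforms=[])
        elif feat.featuretype == "exon":
            tid = feat.attributes.get("transcript_id", [""])[0]
            rec = tx.setdefault(tid, {"gene_id": gid, "chrom": feat.seqid,
                                      "strand": feat.strand, "exons": []})
            rec["exons"].append((feat.start - 1, feat.end))
    for tid, rec in sorted(tx.items()):
        gid = rec["gene_id"]
        if gid not in genes:
            genes[gid] = GeneModel(gene_id=gid, chrom=rec["chrom"],
                                   strand=rec["strand"], isoforms=[])
        genes[gid].isoforms.append(Isoform(
            isoform_id=tid, exons=tuple(sorted(rec["exons"])),
            strand=rec["strand"]))
    return [genes[g] for g in sorted(genes)]


def write_sam(
    reads: Sequence[AlignedRead],
    chrom_sizes: Mapping[str, int],
    path: str | Path,
    umi_tag: str = "RX",
) -> Path:
    path = Path(path)
    names = sorted(chrom_sizes)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": int(chrom_sizes[n])} for n in names],
    }
    ref_id = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, r in enumerate(reads):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"read{i:08d}"
            a.reference_id = ref_id[r.chrom]
            a.reference_start = r.start
            a.cigarstring = f"{r.end - r.start}M"
            a.flag = 16 if r.strand == "-" else 0
            a.mapping_quality = 255
            a.query_sequence = "N" * (r.end - r.start)
            a.set_tag(umi_tag, r.umi)
            out.write(a)
    return path


def read_sam(path: str | Path, umi_tag: str = "RX", sample: str = "sample") -> list[AlignedRead]:
    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            reads.append(AlignedRead(
                chrom=a.reference_name,
                start=a.reference_start,
                end=a.reference_end,
                strand="-" if a.is_reverse else "+",
                umi=a.get_tag(umi_tag) if a.has_tag(umi_tag) else "",
                sample=sample,
            ))
    return reads


def write_bed(intervals: Iterable[tuple], path: str | Path) -> Path:
    """Write (chrom, start, end[, name[, score[, strand]]]) rows as BED."""
    path = Path(path)
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return path


def read_bed(path: str | Path) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    path = Path(path)
    if path.stat().st_size == 0:
        return pd.DataFrame(columns=cols[:3])
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = cols[:df.shape[1]]
    return df


def write_mask_bed(masks: MaskSet, path: str | Path) -> Path:
    rows = []
    for chrom, entries in sorted(masks.intervals.items()):
        for start, end, cls, strand in sorted(entries):
            rows.append((chrom, start, end, cls, 0, strand))
    return write_bed(rows, path)


def read_mask_bed(path: str | Path) -> MaskSet:
    masks = MaskSet()
    df = read_bed(path)
    for row in df.itertuples(index=False):
        cls = getattr(row, "name", "blacklist")
        strand = getattr(row, "strand", ".")
        masks.add(row.chrom, int(row.start), int(row.end), cls, strand)
    return masks


def write_expression_tsv(expression: Mapping[str, Mapping[str, float]],
                         path: str | Path) -> Path:
    rows = [(g, iso, tpm) for g, d in sorted(expression.items())
            for iso, tpm in sorted(d.items())]
    pd.DataFrame(rows, columns=["gene_id", "isoform_id", "tpm"]).to_csv(
        path, sep="\t", index=False)
    return Path(path)


def read_expression_tsv(path: str | Path) -> dict:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, float]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.gene_id, {})[row.isoform_id] = float(row.tpm)
    return out


def write_contacts(contacts: Sequence[Contact], path: str | Path) -> Path:
    rows = [(c.chrom1, c.start1, c.end1, c.chrom2, c.start2, c.end2,
             c.padj, c.log2fc) for c in contacts]
    pd.DataFrame(rows, columns=["chrom1", "start1", "end1", "chrom2",
                                "start2", "end2", "padj", "log2fc"]).to_csv(
        path, sep="\t", index=False)
    return Path(path)


def read_contacts(path: str | Path) -> list[Contact]:
    df = pd.read_csv(path, sep="\t")
    return [Contact(r.chrom1, int(r.start1), int(r.end1), r.chrom2,
                    int(r.start2), int(r.end2), float(r.padj),
                    float(getattr(r, "log2fc", float("nan"))))
            for r in df.itertuples(index=False)]


def write_enhancer_bed(calls: Sequence[EnhancerCall], path: str | Path) -> Path:
    rows = [
        (c.chrom, c.start, c.end,
         f"{c.enh_id}|{c.kind}|{c.directionality}", 0, ".")
        for c in sorted(calls, key=lambda c: (c.chrom, c.start))
    ]
    return write_bed(rows, path)
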