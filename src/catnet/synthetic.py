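"""Synthetic genomes, occupancy tracks, reads and perturbations with truth.

The generator emulates the inputs of a spike-in nascent-transcription
experiment on a small random genome: genes with a promoter-proximal
pausing peak (geometric decay from the TSS) over a uniform gene body,
divergent promoter antisense upstream of a configurable fraction of
TSSs, intragenic convergent-antisense (CAT) loci and extragenic
divergent loci acting as planted enhancers (with H3K27ac/H3K4me1 peaks;
decoy loci transcribe but carry neither mark), sn/snoRNA-like masked
loci, reverse-transcription mispriming and RNA-processing-intermediate
read artifacts, exogenous spike-in material on reserved ``spike_``
chromosomes at a fixed read ratio, and a global elongation-loss
perturbation that scales proximal and body signal by separate fold
changes. Every emitted read and occupancy count is attributable to
exactly one truth element or artifact class.

All randomness flows through numpy Generators seeded from
``SimConfig.seed``; element placement, counts and artifacts are drawn in
a fixed documented order, so identical configs give byte-identical
outputs. Each top-level stage uses its own fixed seed offset (genome +0,
occupancy +1, perturbation +2, reads +3, contacts +4) so stages can be
re-run independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import AlignedRead, Contact, GeneModel, Isoform, opposite
from .occupancy import MaskSet, intermediate_positions, revcomp
from .differential import Region
from .track import OccupancyTrack

__all__ = [
    "SimConfig",
    "SimAnnotation",
    "SizingError",
    "simulate_genome",
    "simulate_occupancy",
    "simulate_perturbation",
    "simulate_reads",
    "simulate_contacts",
]

# Fixed layout constants (bp). Pads keep neighbouring elements separated by
# more than the TU caller's default gap and outside each other's promoter
# and termination windows.
_TSS_PAD = 1900
_TERM_PAD = 2600
_SLOT = 1600
_START_MARGIN = 3000
_DECAY = 0.99  # geometric decay of the proximal pausing peak


class SizingError(ValueError):
    """Requested elements do not fit on the configured chromosomes."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated experiment."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 200
    n_intragenic_enh: int = 50
    n_extragenic_enh: int = 50
    n_decoy_intragenic: int = 10
    n_decoy_extragenic: int = 10
    n_ncrna: int = 8
    pausing_index: float = 4.0          # proximal / body mean density
    divergent_promoter_fraction: float = 0.7
    enh_bidirectional_fraction: float = 0.8
    multi_isoform_fraction: float = 0.2
    inactive_gene_fraction: float = 0.1
    mispriming_rate: float = 0.01
    intermediate_rate: float = 0.01
    spike_ratio: float = 0.125          # spike reads : primary reads (1:8)
    dup_factor: int = 1
    perturbation_body_fc: float = 0.3
    perturbation_proximal_fc: float = 1.3
    enhancer_coupling: float = 0.6  # extra body fold change per connected enhancer
    read_depth: int = 400_000
    read_len: int = 40
    umi_len: int = 10
    overdispersion: float = 0.0         # gamma-mixing CV^2 of element rates
    decoy_contact_fraction: float = 0.5
    contact_bin: int = 5_000
    n_spike_regions: int = 40
    spike_chrom_length: int = 250_000
    proximal_width: int = 500
    enh_proximal_halfwidth: int = 250

    def __post_init__(self):
        for name in ("divergent_promoter_fraction", "enh_bidirectional_fraction",
                     "multi_isoform_fraction", "inactive_gene_fraction",
                     "mispriming_rate", "intermediate_rate",
                     "decoy_contact_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("perturbation_body_fc", "perturbation_proximal_fc",
                     "pausing_index", "spike_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.dup_factor < 1:
            raise ValueError("dup_factor must be >= 1")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")


@dataclass
class SignalElement:
    """One transcribed locus: per-position Poisson rates on one strand."""

    element_id: str
    read_label: str   # genuine | ncRNA | spike
    species: str      # primary | spike
    chrom: str
    strand: str
    positions: np.ndarray
    rates: np.ndarray
    proximal: np.ndarray  # bool mask: perturbed by proximal_fc, else body_fc


@dataclass
class SimAnnotation:
    """Everything downstream stages need, plus the machine-readable truth."""

    config: SimConfig
    chrom_sizes: dict
    genes: list
    expression: dict
    peaks: dict
    masks: MaskSet
    elements: list
    spike_regions: list
    truth: pd.DataFrame
    enh_target: dict = field(default_factory=dict)   # enhancer id -> target gene id
    gene_enh_count: dict = field(default_factory=dict)

    def genes_by_id(self) -> dict:
        return {g.gene_id: g for g in self.genes}

    def truth_enhancers(self, marked_only: bool = True) -> pd.DataFrame:
        t = self.truth[self.truth["cls"].isin(
            ["intragenic_enhancer", "extragenic_enhancer"])]
        if marked_only:
            t = t[t["marks"]]
        return t


def _random_seq(rng: np.random.Generator, n: int) -> str:
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    return bytes(alphabet[rng.integers(0, 4, n)]).decode()


def _lognormal_weight(rng, sigma=0.3) -> float:
    return float(rng.lognormal(0.0, sigma))


def simulate_genome(config: SimConfig) -> tuple[dict, SimAnnotation]:
    """Place genes, enhancers, decoys, masks and spike regions; build rates.

    Returns ``(genome, annotation)`` where ``genome`` maps chromosome
    name to sequence. Raises :class:`SizingError` when the requested
    element counts do not fit the chromosome length.
    """
    rng = np.random.default_rng(config.seed)

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chrom_sizes = {c: config.chrom_length for c in chrom_names}

    # distribute genes and gap elements round-robin over chromosomes
    genes_per = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        genes_per[i] += 1
    gap_tags = (["extragenic_enh"] * config.n_extragenic_enh
                + ["extragenic_decoy"] * config.n_decoy_extragenic
                + ["ncrna"] * config.n_ncrna)
    rng.shuffle(gap_tags)
    tags_per: list[list[str]] = [[] for _ in range(config.n_chroms)]
    for i, tag in enumerate(gap_tags):
        tags_per[i % config.n_chroms].append(tag)

    genes: list[GeneModel] = []
    gene_meta: list[dict] = []       # layout bookkeeping per gene
    gap_sites: list[dict] = []       # placed gap elements (center, tag, chrom)
    masks = MaskSet()

    gidx = 0
    for ci, chrom in enumerate(chrom_names):
        ng = genes_per[ci]
        tags = tags_per[ci]
        if ng > 0:
            if len(tags) > ng:
                raise SizingError(
                    f"{chrom}: {len(tags)} gap elements but only {ng} slots")
            slot_idx = sorted(rng.choice(ng, size=len(tags), replace=False).tolist())
            slot_assign = dict(zip(slot_idx, tags))
        else:
            slot_assign = {}
        x = _START_MARGIN
        for gi in range(ng):
            strand = "+" if rng.random() < 0.5 else "-"
            glen = int(rng.integers(2400, 3601))
            left = _TSS_PAD if strand == "+" else _TERM_PAD
            right = _TERM_PAD if strand == "+" else _TSS_PAD
            x += left + int(rng.integers(0, 301))
            gs, ge = x, x + glen
            gene_id = f"G{gidx:04d}"
            iso_specs, iso2_share = _make_isoforms(rng, config, gene_id, gs, ge, strand)
            genes.append(GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                                   isoforms=iso_specs))
            gene_meta.append({"gene_id": gene_id, "chrom": chrom, "strand": strand,
                              "start": gs, "end": ge, "glen": glen,
                              "n_iso": len(iso_specs),
                              "iso2_share": iso2_share})
            gidx += 1
            x = ge + right + int(rng.integers(0, 301))
            if gi in slot_assign:
                gap_sites.append({"chrom": chrom, "slot_start": x,
                                  "tag": slot_assign[gi]})
                x += _SLOT + int(rng.integers(0, 201))
            if x > config.chrom_length - _START_MARGIN:
                raise SizingError(
                    f"{chrom}: layout needs {x} bp, have {config.chrom_length}")
        if ng == 0:
            for tag in tags:
                x += 3000
                gap_sites.append({"chrom": chrom, "slot_start": x, "tag": tag})
                x += _SLOT
                if x > config.chrom_length - _START_MARGIN:
                    raise SizingError(f"{chrom}: gap elements do not fit")
        # ENCODE-style blacklist stub near the chromosome start
        masks.add(chrom, 1000, 2000, "blacklist")

    # activity status: a fraction of genes is inactive, half failing the
    # TPM threshold while transcribed, half expressed but silent
    n_inactive = int(round(config.inactive_gene_fraction * config.n_genes))
    inactive_idx = set(rng.choice(config.n_genes, size=n_inactive,
                                  replace=False).tolist()) if n_inactive else set()
    low_tpm = {i for k, i in enumerate(sorted(inactive_idx)) if k % 2 == 0}

    expression: dict[str, dict[str, float]] = {}
    status: list[str] = []
    for i, gene in enumerate(genes):
        if i in low_tpm:
            total, kind = float(rng.uniform(0.1, 0.9)), "inactive_low_tpm"
        elif i in inactive_idx:
            total, kind = float(rng.uniform(1.5, 5.0)), "inactive_silent"
        else:
            total, kind = float(max(1.5, rng.lognormal(3.0, 0.8))), "active"
        status.append(kind)
        shares = [1.0]
        if len(gene.isoforms) == 2:
            s2 = gene_meta[i]["iso2_share"]
            shares = [1.0 - s2, s2]
        expression[gene.gene_id] = {
            iso.isoform_id: total * share
            for iso, share in zip(gene.isoforms, shares)
        }
        gene.isoforms = [replace(iso, tpm=total * share)
                         for iso, share in zip(gene.isoforms, shares)]

    elements: list[SignalElement] = []
    truth_rows: list[dict] = []
    peaks: dict[str, dict[str, list]] = {"H3K27ac": {}, "H3K4me1": {}}

    # gene + divergent-antisense signal (fixed order: gene index)
    for i, (gene, meta) in enumerate(zip(genes, gene_meta)):
        transcribed = status[i] != "inactive_silent"
        w = gene.tpm if status[i] == "active" else float(rng.uniform(8, 15))
        if status[i] == "inactive_silent":
            w = 0.0
        if transcribed and w > 0:
            elements.append(_gene_element(gene, meta, w, config))
            if status[i] == "active":
                ptss = gene.isoforms[0].tss  # main promoter
                peaks["H3K27ac"].setdefault(meta["chrom"], []).append(
                    (max(0, ptss - 300), ptss + 301))
                if rng.random() < config.divergent_promoter_fraction:
                    el, row = _dat_element(rng, gene, meta, w)
                    elements.append(el)
                    truth_rows.append(row)
        truth_rows.append({
            "element_id": gene.gene_id, "cls": "gene", "chrom": meta["chrom"],
            "start": meta["start"], "end": meta["end"], "strand": gene.strand,
            "origin": gene.tss, "origin2": np.nan, "host_gene": "",
            "marks": False, "active": status[i] == "active", "status": status[i],
            "expected_body_lfc": math.log2(config.perturbation_body_fc),
            "expected_proximal_lfc": math.log2(config.perturbation_proximal_fc),
        })

    # intragenic enhancers and decoy CATs on active single-isoform hosts
    host_pool = [i for i, m in enumerate(gene_meta)
                 if status[i] == "active" and m["n_iso"] == 1 and m["glen"] >= 2600]
    n_hosts = config.n_intragenic_enh + config.n_decoy_intragenic
    if len(host_pool) < n_hosts:
        raise SizingError(f"need {n_hosts} intragenic hosts, "
                          f"only {len(host_pool)} qualifying genes")
    hosts = rng.choice(host_pool, size=n_hosts, replace=False).tolist() if n_hosts else []
    for k, hi in enumerate(hosts):
        marked = k < config.n_intragenic_enh
        el, row = _cat_element(rng, genes[hi], gene_meta[hi], k, marked, config)
        elements.append(el)
        truth_rows.append(row)
        if marked:
            for mark in ("H3K27ac", "H3K4me1"):
                peaks[mark].setdefault(row["chrom"], []).append(
                    (row["start"] - 200, row["end"] + 200))

    # extragenic enhancers, decoys and ncRNA loci in gap slots
    enh_serial = decoy_serial = nc_serial = 0
    for site in gap_sites:
        if site["tag"] == "ncrna":
            el, row = _ncrna_element(rng, site, nc_serial)
            elements.append(el)
            masks.add(site["chrom"], row["start"] - 50, row["end"] + 50, "ncRNA")
            nc_serial += 1
            continue
        marked = site["tag"] == "extragenic_enh"
        serial = enh_serial if marked else decoy_serial
        els, row = _extragenic_element(rng, site, serial, marked, config)
        elements.extend(els)
        truth_rows.append(row)
        if marked:
            for mark in ("H3K27ac", "H3K4me1"):
                peaks[mark].setdefault(row["chrom"], []).append(
                    (row["start"] - 200, row["end"] + 200))
            enh_serial += 1
        else:
            decoy_serial += 1

    # spike-in chromosome with uniformly transcribed reference regions
    spike_chrom = "spike_chr1"
    chrom_sizes[spike_chrom] = config.spike_chrom_length
    spike_regions: list[Region] = []
    needed = 2000 + config.n_spike_regions * 3000
    if needed > config.spike_chrom_length:
        raise SizingError("spike chromosome too short for requested regions")
    for i in range(config.n_spike_regions):
        start = 2000 + i * 3000
        end = start + 2000
        strand = "+" if i % 2 == 0 else "-"
        dens = 0.2 * _lognormal_weight(rng, 0.4)
        positions = np.arange(start, end)
        elements.append(SignalElement(
            element_id=f"SPIKE{i:03d}", read_label="spike", species="spike",
            chrom=spike_chrom, strand=strand, positions=positions,
            rates=np.full(end - start, dens),
            proximal=np.zeros(end - start, dtype=bool)))
        spike_regions.append(Region(region_id=f"SPIKE{i:03d}", chrom=spike_chrom,
                                    start=start, end=end, strand=".",
                                    cls="spike", species="spike"))

    _normalize_rates(elements, config)

    for by_chrom in peaks.values():
        for lst in by_chrom.values():
            lst.sort()

    # enhancer -> target gene links (host gene, or nearest active gene);
    # under perturbation every connected enhancer deepens the target's body
    # loss by one coupling factor
    active_genes = [g for i, g in enumerate(genes) if status[i] == "active"]
    enh_target: dict[str, str] = {}
    for row in truth_rows:
        if (row["cls"] not in ("intragenic_enhancer", "extragenic_enhancer")
                or not row["marks"]):
            continue
        if row["host_gene"]:
            enh_target[row["element_id"]] = row["host_gene"]
        else:
            center = (row["start"] + row["end"]) // 2
            cands = [g for g in active_genes if g.chrom == row["chrom"]]
            if cands:
                enh_target[row["element_id"]] = min(
                    cands, key=lambda g: abs(g.tss - center)).gene_id
    gene_enh_count = {g.gene_id: 0 for g in genes}
    for gid in enh_target.values():
        gene_enh_count[gid] += 1
    for row in truth_rows:
        if row["cls"] == "gene":
            n = gene_enh_count[row["element_id"]]
            row["expected_body_lfc"] = math.log2(
                config.perturbation_body_fc * config.enhancer_coupling ** n)
    truth = pd.DataFrame(truth_rows)

    genome = {c: _random_seq(rng, size) for c, size in sorted(chrom_sizes.items())}
    ann = SimAnnotation(config=config, chrom_sizes=chrom_sizes, genes=genes,
                        expression=expression, peaks=peaks, masks=masks,
                        elements=elements, spike_regions=spike_regions,
                        truth=truth, enh_target=enh_target,
                        gene_enh_count=gene_enh_count)
    return genome, ann


def _make_isoforms(rng, config, gene_id, gs, ge, strand) -> list[Isoform]:
    glen = ge - gs
    spliced = rng.random() < 0.3
    if spliced:
        a = glen // 3
        exons1 = ((gs, gs + a), (gs + a + 200, ge))
    else:
        exons1 = ((gs, ge),)
    isoforms = [Isoform(isoform_id=f"{gene_id}.1", exons=exons1, strand=strand)]
    iso2_share = None
    if rng.random() < config.multi_isoform_fraction and glen >= 3000:
        # half get a downstream alternative TSS carrying an active share of
        # expression; half an upstream isoform extending the annotated span
        # 5' of the main promoter whose low share leaves it inactive, as is
        # common in reference annotations
        if rng.random() < 0.5:
            delta = int(rng.integers(600, 1201))
            exons2 = ((gs + delta, ge),) if strand == "+" else ((gs, ge - delta),)
            iso2_share = 0.15
        else:
            delta = int(rng.integers(400, 901))
            exons2 = ((gs - delta, ge),) if strand == "+" else ((gs, ge + delta),)
            iso2_share = 0.05
        isoforms.append(Isoform(isoform_id=f"{gene_id}.2", exons=exons2,
                                strand=strand))
    return isoforms, iso2_share


def _gene_element(gene, meta, w, config) -> SignalElement:
    gs, ge, strand = meta["start"], meta["end"], meta["strand"]
    d_body = w / 20.0
    pw = config.proximal_width
    offsets = np.arange(pw)
    decay = _DECAY ** offsets
    amp = config.pausing_index * d_body * pw / decay.sum()
    positions = np.arange(gs, ge)
    rates = np.full(ge - gs, d_body)
    proximal = np.zeros(ge - gs, dtype=bool)
    if strand == "+":
        rates[:pw] = amp * decay
        proximal[:pw] = True
    else:
        rates[-pw:] = (amp * decay)[::-1]
        proximal[-pw:] = True
    return SignalElement(element_id=meta["gene_id"], read_label="genuine",
                         species="primary", chrom=meta["chrom"], strand=strand,
                         positions=positions, rates=rates, proximal=proximal)


def _dat_element(rng, gene, meta, w):
    strand = opposite(gene.strand)
    d = int(rng.integers(150, 951))
    length = int(rng.integers(250, 601))
    tss = gene.isoforms[0].tss  # main promoter, not an upstream-extension TSS
    if gene.strand == "+":
        origin = tss - d
        start, end = origin - length + 1, origin + 1
    else:
        origin = tss + d
        start, end = origin, origin + length
    positions = np.arange(start, end)
    dens = 0.3 * w / 20.0
    el = SignalElement(element_id=f"DAT_{meta['gene_id']}", read_label="genuine",
                       species="primary", chrom=meta["chrom"], strand=strand,
                       positions=positions, rates=np.full(end - start, dens),
                       proximal=np.zeros(end - start, dtype=bool))
    row = {"element_id": el.element_id, "cls": "DAT", "chrom": meta["chrom"],
           "start": start, "end": end, "strand": strand, "origin": origin,
           "origin2": np.nan, "host_gene": meta["gene_id"], "marks": False,
           "active": True, "status": "",
           "expected_body_lfc": np.nan, "expected_proximal_lfc": np.nan}
    return el, row


def _cat_element(rng, host, meta, serial, marked, config):
    gs, ge, glen = meta["start"], meta["end"], meta["glen"]
    strand = opposite(host.strand)
    o = int(rng.integers(1700, glen - 99))
    length = int(rng.integers(300, 701))
    length = max(250, min(length, o - 600))
    if host.strand == "+":
        origin = gs + o
        start, end = origin - length + 1, origin + 1
    else:
        origin = ge - 1 - o
        start, end = origin, origin + length
    positions = np.arange(start, end)
    dens = 0.35 * _lognormal_weight(rng)
    eid = (f"IENH{serial:03d}" if marked else f"IDEC{serial:03d}")
    el = SignalElement(element_id=eid, read_label="genuine", species="primary",
                       chrom=meta["chrom"], strand=strand, positions=positions,
                       rates=np.full(end - start, dens),
                       proximal=np.zeros(end - start, dtype=bool))
    row = {"element_id": eid,
           "cls": "intragenic_enhancer" if marked else "CAT",
           "chrom": meta["chrom"], "start": start, "end": end, "strand": strand,
           "origin": origin, "origin2": np.nan, "host_gene": meta["gene_id"],
           "marks": marked, "active": True, "status": "",
           "expected_body_lfc": math.log2(config.perturbation_body_fc),
           "expected_proximal_lfc": math.log2(config.perturbation_proximal_fc)}
    return el, row


def _extragenic_element(rng, site, serial, marked, config):
    chrom, x0 = site["chrom"], site["slot_start"]
    center = x0 + _SLOT // 2
    bidirectional = rng.random() < config.enh_bidirectional_fraction
    els = []
    prefix = "EENH" if marked else "EDEC"
    if bidirectional:
        d = int(rng.integers(120, 431))
        o_minus = center - d // 2
        o_plus = o_minus + d
        l1 = int(rng.integers(250, 551))
        l2 = int(rng.integers(250, 551))
        for tag, strand, start, end, origin in (
            ("m", "-", o_minus - l1 + 1, o_minus + 1, o_minus),
            ("p", "+", o_plus, o_plus + l2, o_plus),
        ):
            dens = 0.35 * _lognormal_weight(rng)
            el = SignalElement(
                element_id=f"{prefix}{serial:03d}{tag}", read_label="genuine",
                species="primary", chrom=chrom, strand=strand,
                positions=np.arange(start, end),
                rates=np.full(end - start, dens),
                proximal=np.zeros(end - start, dtype=bool))
            els.append(el)
        start, end = o_minus - l1 + 1, o_plus + l2
        origin, origin2 = float(o_minus), float(o_plus)
        directionality = "bidirectional"
        strand = "."
    else:
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(300, 601))
        if strand == "+":
            start, end = center, center + length
        else:
            start, end = center - length + 1, center + 1
        dens = 0.35 * _lognormal_weight(rng)
        el = SignalElement(
            element_id=f"{prefix}{serial:03d}u", read_label="genuine",
            species="primary", chrom=chrom, strand=strand,
            positions=np.arange(start, end),
            rates=np.full(end - start, dens),
            proximal=np.zeros(end - start, dtype=bool))
        els.append(el)
        origin, origin2 = float(center), np.nan
        directionality = "unidirectional"
    row = {"element_id": f"{prefix}{serial:03d}", "cls": "extragenic_enhancer",
           "chrom": chrom, "start": start, "end": end, "strand": strand,
           "origin": origin, "origin2": origin2, "host_gene": "",
           "marks": marked, "active": True, "status": directionality,
           "expected_body_lfc": math.log2(config.perturbation_body_fc),
           "expected_proximal_lfc": math.log2(config.perturbation_proximal_fc)}
    return els, row


def _ncrna_element(rng, site, serial):
    chrom, x0 = site["chrom"], site["slot_start"]
    start = x0 + _SLOT // 2 - 100
    end = start + 200
    strand = "+" if rng.random() < 0.5 else "-"
    el = SignalElement(element_id=f"NC{serial:02d}", read_label="ncRNA",
                       species="primary", chrom=chrom, strand=strand,
                       positions=np.arange(start, end),
                       rates=np.full(end - start, 5.0),
                       proximal=np.zeros(end - start, dtype=bool))
    row = {"start": start, "end": end}
    return el, row


def _normalize_rates(elements: Sequence[SignalElement], config: SimConfig) -> None:
    primary = sum(el.rates.sum() for el in elements if el.species == "primary")
    spike = sum(el.rates.sum() for el in elements if el.species == "spike")
    f_primary = config.read_depth / primary if primary > 0 else 0.0
    f_spike = (config.spike_ratio * config.read_depth / spike) if spike > 0 else 0.0
    for el in elements:
        el.rates = el.rates * (f_primary if el.species == "primary" else f_spike)


def truth_gene_regions(ann: SimAnnotation, proximal_width: int | None = None,
                       active_only: bool = True) -> list[Region]:
    """Promoter-proximal and gene-body regions straight from the truth table."""
    pw = proximal_width or ann.config.proximal_width
    regions = []
    gene_truth = ann.truth[ann.truth["cls"] == "gene"]
    for row in gene_truth.itertuples(index=False):
        if active_only and not row.active:
            continue
        if row.strand == "+":
            prox = (row.start, row.start + pw)
            body = (row.start + pw, row.end)
        else:
            prox = (row.end - pw, row.end)
            body = (row.start, row.end - pw)
        regions.append(Region(f"{row.element_id}:proximal", row.chrom, *prox,
                              strand=row.strand, cls="promoter_proximal"))
        regions.append(Region(f"{row.element_id}:body", row.chrom, *body,
                              strand=row.strand, cls="gene_body"))
    return regions


def truth_enhancer_regions(ann: SimAnnotation) -> list[Region]:
    """Whole-span enhancer regions (both strands) from the truth table."""
    return [
        Region(f"{row.element_id}:span", row.chrom, row.start, row.end,
               strand=".", cls="enhancer")
        for row in ann.truth_enhancers(marked_only=True).itertuples(index=False)
    ]


# ----------------------------------------------------------------------
# occupancy / perturbation


def simulate_occupancy(
    ann: SimAnnotation,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
    body_fc: float = 1.0,
    proximal_fc: float = 1.0,
    gene_body_fc: Mapping[str, float] | None = None,
) -> tuple[OccupancyTrack, dict]:
    """Draw one occupancy track: independent Poisson counts per position.

    Primary-genome rates are scaled by ``proximal_fc`` inside
    promoter-proximal / enhancer-proximal windows and by ``body_fc``
    elsewhere; spike-in rates are never scaled. With
    ``config.overdispersion > 0`` every element's rates are multiplied
    by one gamma draw with mean 1 and variance ``overdispersion``,
    making region-level counts negative-binomial. Returns the merged
    track and the per-element count arrays (truth attribution).
    """
    config = config or ann.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    track = OccupancyTrack()
    element_counts: dict[str, np.ndarray] = {}
    od = config.overdispersion
    gene_body_fc = gene_body_fc or {}
    for el in ann.elements:
        rates = el.rates
        bfc = gene_body_fc.get(el.element_id, body_fc)
        if el.species == "primary" and (bfc != 1.0 or proximal_fc != 1.0):
            rates = rates * np.where(el.proximal, proximal_fc, bfc)
        if od > 0:
            rates = rates * rng.gamma(1.0 / od, od)
        counts = rng.poisson(rates)
        element_counts[el.element_id] = counts
        track.add_arrays(el.chrom, el.strand, el.positions, counts)
    return track, element_counts


def simulate_perturbation(
    ann: SimAnnotation,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[OccupancyTrack, dict, list]:
    """Treated condition plus contacts: proximal and body signal scaled
    by the configured fold changes, spike-ins untouched; contacts link
    every marked enhancer to its host/nearest gene with decoys added."""
    config = config or ann.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    gene_body_fc = {
        gid: config.perturbation_body_fc * config.enhancer_coupling ** n
        for gid, n in ann.gene_enh_count.items()
    }
    track, counts = simulate_occupancy(
        ann, config, rng,
        body_fc=config.perturbation_body_fc,
        proximal_fc=config.perturbation_proximal_fc,
        gene_body_fc=gene_body_fc)
    contacts, _pairs = simulate_contacts(ann, config, rng)
    return track, counts, contacts


def simulate_contacts(
    ann: SimAnnotation,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list, pd.DataFrame]:
    """Significant contacts linking each marked enhancer to its target gene.

    The target is the host gene (intragenic) or the active gene with the
    nearest TSS (extragenic); anchors are ``contact_bin``-sized bins.
    Decoy contacts (a ``decoy_contact_fraction`` share of the total)
    connect random bins that do not touch any transcribed non-gene
    element; half of them are significant. A few near-miss contacts pair
    enhancers with wrong genes at non-significant padj. Returns the
    contact list and the true (enhancer, gene) pair table.
    """
    config = config or ann.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 4)
    bin_ = config.contact_bin
    genes_by_id = ann.genes_by_id()
    gene_truth = ann.truth[ann.truth["cls"] == "gene"]
    active_ids = set(gene_truth.loc[gene_truth["active"], "element_id"])
    active = [g for g in ann.genes if g.gene_id in active_ids]
    truth_enh = ann.truth_enhancers(marked_only=True)
    contacts: list[Contact] = []
    pair_rows = []

    # anchors are feature-centered windows rather than grid bins, so each
    # anchor touches exactly one planted feature and the truth pairing is
    # unambiguous
    def enh_anchor(row):
        return row.chrom, int(row.start), int(row.end)

    def gene_anchor(gene):
        tss = gene.isoforms[0].tss
        return gene.chrom, tss - 500, tss + 501

    for row in truth_enh.itertuples(index=False):
        target = ann.enh_target.get(row.element_id)
        if target is None:
            continue
        gene = genes_by_id[target]
        contacts.append(Contact(*enh_anchor(row), *gene_anchor(gene),
                                padj=float(rng.uniform(1e-6, 5e-3))))
        pair_rows.append((row.element_id, gene.gene_id))

    # near-miss contacts: enhancer to a wrong gene, non-significant
    for row in truth_enh.head(5).itertuples(index=False):
        others = [g for g in active if g.chrom == row.chrom
                  and g.gene_id not in {p[1] for p in pair_rows}]
        if not others:
            continue
        g = others[int(rng.integers(len(others)))]
        contacts.append(Contact(*enh_anchor(row), *gene_anchor(g),
                                padj=float(rng.uniform(0.02, 0.5))))

    # decoy contacts between bins that do not touch any enhancer-like locus
    avoid = [
        (r.chrom, r.start - 2000, r.end + 2000)
        for r in ann.truth.itertuples(index=False)
        if r.cls in ("intragenic_enhancer", "extragenic_enhancer", "CAT", "DAT")
    ]
    f = config.decoy_contact_fraction
    n_true = len(pair_rows)
    n_decoy = int(round(n_true * f / (1 - f))) if f < 1 else 0
    primary_chroms = [c for c in ann.chrom_sizes if not c.startswith("spike_")]
    made = 0
    attempts = 0
    while made < n_decoy and attempts < 50 * max(n_decoy, 1):
        attempts += 1
        anchors = []
        for _ in range(2):
            chrom = primary_chroms[int(rng.integers(len(primary_chroms)))]
            nbins = ann.chrom_sizes[chrom] // bin_
            start = int(rng.integers(nbins)) * bin_
            anchors.append((chrom, start, start + bin_))
        if any(c == ac and s < ae and as_ < e
               for (c, s, e) in anchors for (ac, as_, ae) in avoid):
            continue
        padj = float(rng.uniform(1e-5, 5e-3)) if made % 2 == 0 \
            else float(rng.uniform(0.02, 0.9))
        contacts.append(Contact(*anchors[0], *anchors[1], padj=padj))
        made += 1

    pairs = pd.DataFrame(pair_rows, columns=["enhancer_id", "gene_id"])
    return contacts, pairs


# ----------------------------------------------------------------------
# reads


def simulate_reads(
    element_counts: Mapping[str, np.ndarray],
    genome: Mapping[str, str],
    ann: SimAnnotation,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[AlignedRead]:
    """Invert occupancy extraction: one read per occupancy count.

    Each count at (chrom, strand, pos) becomes a read whose 5'-most
    aligned base is ``pos`` and whose alignment strand is the opposite
    of the occupancy strand (the flip convention). Primary genuine reads
    are converted to artifacts in a fixed order: with probability
    ``intermediate_rate`` the read is repositioned to the 3'-most base
    of a random annotated exon/intron or polyA site; otherwise with
    probability ``mispriming_rate`` its UMI is overwritten by the
    genomic k-mer adjacent to the read 3' end (making it detectable).
    Genuine UMIs are drawn distinct per position and never equal to the
    adjacent genomic k-mer, so truth labels are exact. ``dup_factor``
    appends PCR copies of every read, labelled "duplicate".
    """
    config = config or ann.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    k = config.umi_len
    rl = config.read_len

    int_pos = intermediate_positions(ann.genes)
    int_list = [(chrom, strand, p)
                for (chrom, strand), ps in sorted(int_pos.items())
                for p in sorted(ps)]

    used_umis: dict[tuple, set] = {}
    reads: list[AlignedRead] = []

    def random_umi(key, adjacent):
        used = used_umis.setdefault(key, set())
        while True:
            umi = "".join("ACGT"[i] for i in rng.integers(0, 4, k))
            if umi != adjacent and umi not in used:
                used.add(umi)
                return umi

    def read_coords(chrom, occ_strand, pos):
        if occ_strand == "+":
            start, end, strand = pos - rl + 1, pos + 1, "-"
        else:
            start, end, strand = pos, pos + rl, "+"
        if start < 0 or end + k > len(genome[chrom]) or start - k < 0:
            raise ValueError(f"no genome margin for read at {chrom}:{pos}")
        return start, end, strand

    def adjacent_kmer(chrom, start, end, strand):
        seq = genome[chrom]
        if strand == "+":
            return seq[end:end + k]
        return revcomp(seq[start - k:start])

    for el in ann.elements:
        counts = element_counts.get(el.element_id)
        if counts is None:
            continue
        nz = np.nonzero(counts)[0]
        for idx in nz:
            pos = int(el.positions[idx])
            for _ in range(int(counts[idx])):
                label = el.read_label
                chrom, occ_strand = el.chrom, el.strand
                if el.species == "primary" and el.read_label == "genuine":
                    u = rng.random()
                    if u < config.intermediate_rate and int_list:
                        label = "intermediate"
                        chrom, occ_strand, pos2 = int_list[
                            int(rng.integers(len(int_list)))]
                        pos = pos2
                    elif u < config.intermediate_rate + config.mispriming_rate:
                        label = "mispriming"
                start, end, strand = read_coords(chrom, occ_strand, pos)
                if label == "mispriming":
                    umi = adjacent_kmer(chrom, start, end, strand)
                else:
                    adj = adjacent_kmer(chrom, start, end, strand)
                    umi = random_umi((chrom, occ_strand, pos), adj)
                reads.append(AlignedRead(
                    chrom=chrom, start=start, end=end, strand=strand, umi=umi,
                    label=label, element=el.element_id))
                pos = int(el.positions[idx])  # restore after intermediate move
    if config.dup_factor > 1:
        dupes = [replace(r, label="duplicate")
                 for r in reads for _ in range(config.dup_factor - 1)]
        reads.extend(dupes)
    return reads
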