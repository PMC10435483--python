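"""Independent brute-force implementations used as test oracles.

These deliberately re-derive every rule with naive O(n^2) all-pairs scans
and explicit per-position set arithmetic, sharing no code with the
package implementation beyond the data classes.
"""

from __future__ import annotations

import numpy as np

from catnet.model import GeneModel, Isoform, TranscriptionUnit


# ----------------------------------------------------------------------
# brute-force transcription-unit caller


def brute_force_tus(track, max_gap=250, min_count=10, min_body=150, min_cov=1):
    """Enumerate runs by scanning every position pair exhaustively."""
    units = []
    for chrom, strand in track.keys():
        counter = track.counter(chrom, strand)
        covered = sorted(p for p, n in counter.items() if n >= min_cov)
        if not covered:
            continue
        runs = [[covered[0]]]
        for pos in covered[1:]:
            if pos - runs[-1][-1] <= max_gap:
                runs[-1].append(pos)
            else:
                runs.append([pos])
        for run in runs:
            total = sum(counter[p] for p in run)
            length = run[-1] - run[0] + 1
            if length >= min_body and total >= min_count:
                units.append((chrom, strand, run[0], run[-1] + 1, total))
    return sorted(units)


# ----------------------------------------------------------------------
# brute-force antisense / enhancer classification

DAT_WINDOW = 1000
BIDIR_DIST = 500
PROM_HALF = 500
TERM_ZONE = 2000
OVL_TU = 0.50
OVL_GENE = 0.90


def _overlap(a, b, c, d):
    return max(0, min(b, d) - max(a, c))


def _positions_upstream(origin, tss, strand):
    """Signed upstream distance of origin relative to a TSS in gene orientation."""
    return tss - origin if strand == "+" else origin - tss


def brute_classify(tus, genes, peaks):
    """Classify every TU; returns {tu_id: outcome string}.

    Outcomes: "CAT:<host>", "DAT:<host>", "discarded:<reason>",
    "extragenic:bidirectional:<partner_id>", "extragenic:unidirectional",
    "extragenic:nomarks", "ineligible".
    """
    out = {}
    antisense = {}
    for tu in tus:
        host = _pick_host(tu, genes)
        if host is not None:
            antisense[tu.tu_id] = host
            out[tu.tu_id] = _classify_antisense(tu, host, genes)
    rest = [tu for tu in tus if tu.tu_id not in antisense]
    eligible = [tu for tu in rest if _is_eligible(tu, genes)]
    for tu in rest:
        if tu not in eligible:
            out[tu.tu_id] = "ineligible"
    pairs, singles = _pair(eligible)
    for a, b in pairs:
        lo, hi = min(a.start, b.start), max(a.end, b.end)
        if _marked(a.chrom, lo, hi, peaks):
            out[a.tu_id] = f"extragenic:bidirectional:{b.tu_id}"
            out[b.tu_id] = f"extragenic:bidirectional:{a.tu_id}"
        else:
            out[a.tu_id] = out[b.tu_id] = "extragenic:nomarks"
    for tu in singles:
        out[tu.tu_id] = ("extragenic:unidirectional"
                         if _marked(tu.chrom, tu.start, tu.end, peaks)
                         else "extragenic:nomarks")
    return out


def _pick_host(tu, genes):
    best, best_key = None, None
    for g in genes:
        if not g.active or g.chrom != tu.chrom:
            continue
        if (g.strand, tu.strand) not in (("+", "-"), ("-", "+")):
            continue
        ovl = _overlap(tu.start, tu.end, g.start, g.end)
        if ovl == 0:
            continue
        key = (-ovl, abs(tu.origin - g.first_active_tss), g.gene_id)
        if best is None or key < best_key:
            best, best_key = g, key
    return best


def _classify_antisense(tu, host, genes):
    # spill-over from same-strand genes
    for g in genes:
        if g.chrom != tu.chrom or g.strand != tu.strand:
            continue
        ovl = _overlap(tu.start, tu.end, g.start, g.end)
        if ovl == 0:
            continue
        if ovl / (tu.end - tu.start) >= OVL_TU or ovl / (g.end - g.start) >= OVL_GENE:
            return "discarded:overlapping_gene"
    if tu.start <= host.start and tu.end >= host.end:
        return "discarded:covers_antisense_gene"
    for tss in sorted(host.active_tss):
        up = _positions_upstream(tu.origin, tss, host.strand)
        if 0 < up < DAT_WINDOW:
            return f"DAT:{host.gene_id}"
    first = host.first_active_tss
    down = -_positions_upstream(tu.origin, first, host.strand)
    if down > 0 and host.start <= tu.origin < host.end:
        return f"CAT:{host.gene_id}"
    return "discarded:alt_promoter"


def _is_eligible(tu, genes):
    for g in genes:
        if g.chrom != tu.chrom:
            continue
        if g.active:
            es, ee = g.effective_span
            if _overlap(tu.start, tu.end, es, ee) > 0:
                return False
            for pa in sorted(g.active_polya):
                offs = (tu.origin - pa) if g.strand == "+" else (pa - tu.origin)
                if 0 <= offs <= TERM_ZONE:
                    return False
        for iso in g.isoforms:
            if abs(tu.origin - iso.tss) <= PROM_HALF:
                return False
    return True


def _pair(tus):
    cands = []
    for a in tus:
        for b in tus:
            ka = (a.chrom, a.start, a.end, a.strand)
            kb = (b.chrom, b.start, b.end, b.strand)
            if ka >= kb or a.chrom != b.chrom or a.strand == b.strand:
                continue
            d = abs(a.origin - b.origin)
            if d < BIDIR_DIST:
                cands.append((d, ka, kb, a, b))
    cands.sort(key=lambda t: t[:3])
    taken = set()
    pairs = []
    for _d, ka, kb, a, b in cands:
        if ka in taken or kb in taken:
            continue
        taken.update((ka, kb))
        pairs.append((a, b))
    singles = [t for t in tus
               if (t.chrom, t.start, t.end, t.strand) not in taken]
    return pairs, singles


def _marked(chrom, start, end, peaks):
    for mark in ("H3K27ac", "H3K4me1"):
        if not any(_overlap(start, end, s, e) > 0
                   for s, e in peaks.get(mark, {}).get(chrom, [])):
            return False
    return True


# ----------------------------------------------------------------------
# randomized toy scenarios with planted boundary cases


def _toy_gene(gene_id, chrom, strand, start, end, active=True,
              upstream_ext=0, alt_tss_offset=None):
    """Single- or two-isoform gene; the upstream extension is inactive."""
    exons1 = ((start, end),)
    isoforms = [Isoform(f"{gene_id}.1", exons1, strand, tpm=10.0)]
    if upstream_ext:
        ext = ((start - upstream_ext, end) if strand == "+"
               else (start, end + upstream_ext))
        isoforms.append(Isoform(f"{gene_id}.up", (ext,), strand, tpm=0.4))
    if alt_tss_offset is not None:
        alt = ((start + alt_tss_offset, end) if strand == "+"
               else (start, end - alt_tss_offset))
        isoforms.append(Isoform(f"{gene_id}.alt", (alt,), strand, tpm=3.0))
    g = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                  isoforms=isoforms, active=active)
    if active:
        main = isoforms[0]
        tss = {main.tss}
        polya = {main.polya}
        if alt_tss_offset is not None:
            tss.add(isoforms[-1].tss)
            polya.add(isoforms[-1].polya)
        g.active_tss = frozenset(tss)
        g.active_polya = frozenset(polya)
    return g


def _tu(tu_id, chrom, strand, start, end, count=100):
    return TranscriptionUnit(chrom=chrom, strand=strand, start=start, end=end,
                             total_count=count, tu_id=tu_id)


def random_toy_scenario(rng: np.random.Generator):
    """One random <=50 kb genome exercising every classification rule.

    Returns (tus, genes, peaks). A subset of elements sits exactly at the
    rule boundaries (999/1000 bp DAT window, 499/500 bp bidirectional
    distance, 49.9%/50% TU overlap, 90% gene coverage, termination-zone
    edge), with randomized positions and strands around them.
    """
    chrom = "toy1"
    genes, tus = [], []
    serial = 0

    def flip(s):
        return "-" if s == "+" else "+"

    def new_id():
        nonlocal serial
        serial += 1
        return f"T{serial:03d}"

    # gene A: active, upstream-extended span; plant antisense TUs at the
    # DAT boundary (999 inside, 1000 outside) and a CAT inside the body
    sa = "+" if rng.random() < 0.5 else "-"
    a0 = int(rng.integers(3000, 4000))
    alen = int(rng.integers(3000, 4000))
    if sa == "+":
        gA = _toy_gene("gA", chrom, sa, a0, a0 + alen, upstream_ext=1500)
        tssA = a0
        tus.append(_tu(new_id(), chrom, "-", tssA - 999 - 300, tssA - 999 + 1))
        tus.append(_tu(new_id(), chrom, "-", tssA - 1000 - 300, tssA - 1000 + 1))
        cat_o = tssA + int(rng.integers(1200, alen - 400))
        tus.append(_tu(new_id(), chrom, "-", cat_o - 350, cat_o + 1))
    else:
        gA = _toy_gene("gA", chrom, sa, a0, a0 + alen, upstream_ext=1500)
        tssA = a0 + alen - 1
        tus.append(_tu(new_id(), chrom, "+", tssA + 999, tssA + 999 + 301))
        tus.append(_tu(new_id(), chrom, "+", tssA + 1000, tssA + 1000 + 301))
        cat_o = tssA - int(rng.integers(1200, alen - 400))
        tus.append(_tu(new_id(), chrom, "+", cat_o, cat_o + 351))
    genes.append(gA)

    # gene B: active with a downstream alternative active TSS; antisense TU
    # just upstream of the alternative TSS must reassign to DAT
    b0 = 12_000 + int(rng.integers(0, 1000))
    blen = 3500
    sb = "+" if rng.random() < 0.5 else "-"
    if sb == "+":
        gB = _toy_gene("gB", chrom, sb, b0, b0 + blen, alt_tss_offset=1500)
        alt_tss = b0 + 1500
        o = alt_tss - int(rng.integers(200, 900))
        tus.append(_tu(new_id(), chrom, "-", o - 300, o + 1))
    else:
        gB = _toy_gene("gB", chrom, sb, b0, b0 + blen, alt_tss_offset=1500)
        alt_tss = b0 + blen - 1 - 1500
        o = alt_tss + int(rng.integers(200, 900))
        tus.append(_tu(new_id(), chrom, "+", o, o + 301))
    genes.append(gB)

    # gene C inactive: antisense TU over it is no candidate; its promoter
    # still blocks extragenic calls
    c0 = 19_000
    gC = _toy_gene("gC", chrom, "+", c0, c0 + 2000, active=False)
    genes.append(gC)
    tus.append(_tu(new_id(), chrom, "-", c0 + 600, c0 + 1000))

    # gene D short active gene fully covered by an antisense TU
    d0 = 23_000
    gD = _toy_gene("gD", chrom, "-", d0, d0 + 900)
    genes.append(gD)
    tus.append(_tu(new_id(), chrom, "+", d0 - 150, d0 + 1100))

    # gene E + same-strand neighbour gF: antisense TUs over gE whose tail
    # overlaps gF by exactly 50% of the TU (discard) or just under (keep)
    e0 = 27_000
    gE = _toy_gene("gE", chrom, "-", e0, e0 + 3500)
    genes.append(gE)
    gF = _toy_gene("gF", chrom, "+", e0 + 4000, e0 + 6000)
    genes.append(gF)
    tu_len = 2000
    start = e0 + 4000 - tu_len // 2  # second half inside gF: exactly 50%
    tus.append(_tu(new_id(), chrom, "+", start, start + tu_len))
    tus.append(_tu(new_id(), chrom, "+", start - 1, start - 1 + tu_len))
    # antisense TU covering exactly 90% (then 89.95%) of a short
    # same-strand gene gG while hosted by the antisense gene gH
    gG = _toy_gene("gG", chrom, "+", 35_000, 36_000)
    genes.append(gG)
    gH = _toy_gene("gH", chrom, "-", 34_200, 37_800)
    genes.append(gH)
    tus.append(_tu(new_id(), chrom, "+", 33_900, 35_900))
    tus.append(_tu(new_id(), chrom, "+", 33_900, 35_899))

    # extragenic cluster at 42-46 kb: divergent pairs at the 499/500
    # boundary plus a lone unit; marks over the whole window
    base = 42_000 + int(rng.integers(0, 500))
    o1 = base
    o2 = base + 499
    tus.append(_tu(new_id(), chrom, "-", o1 - 300, o1 + 1))
    tus.append(_tu(new_id(), chrom, "+", o2, o2 + 300))
    base2 = base + 1600
    tus.append(_tu(new_id(), chrom, "-", base2 - 300, base2 + 1))
    tus.append(_tu(new_id(), chrom, "+", base2 + 500, base2 + 800))
    lone = base + 3200
    tus.append(_tu(new_id(), chrom, rng.choice(["+", "-"]), lone, lone + 400))
    # a TU at the termination-zone edge of gene F (polyA + 2000)
    paF = gF.isoforms[0].polya
    tus.append(_tu(new_id(), chrom, "+", paF + 2000, paF + 2400))
    tus.append(_tu(new_id(), chrom, "+", paF + 2001, paF + 2401))

    peaks = {
        "H3K27ac": {chrom: [(a0, a0 + alen), (b0, b0 + blen),
                            (base - 600, base + 4000),
                            (paF + 1500, paF + 3000)]},
        "H3K4me1": {chrom: [(a0, a0 + alen), (b0, b0 + blen),
                            (base - 600, base + 4000),
                            (paF + 1500, paF + 3000)]},
    }
    # random extra TUs anywhere
    for _ in range(int(rng.integers(2, 6))):
        s = int(rng.integers(2000, 48_000))
        ln = int(rng.integers(160, 900))
        tus.append(_tu(new_id(), chrom, rng.choice(["+", "-"]), s, s + ln))
    return tus, genes, peaks


def package_classify(tus, genes, peaks):
    """Run the package path and map outcomes to the oracle's vocabulary."""
    from catnet.classify import (
        ClassifyParams, classify_antisense, call_extragenic_enhancers,
        extragenic_eligible, pair_bidirectional,
    )

    params = ClassifyParams()
    out = {}
    atus = classify_antisense(tus, genes, params)
    antisense_ids = set()
    for a in atus:
        antisense_ids.add(a.tu.tu_id)
        if a.cls == "discarded":
            out[a.tu.tu_id] = f"discarded:{a.discard_reason}"
        else:
            out[a.tu.tu_id] = f"{a.cls}:{a.host_gene}"
    rest = [t for t in tus if t.tu_id not in antisense_ids]
    eligible = extragenic_eligible(rest, genes, params)
    eligible_ids = {t.tu_id for t in eligible}
    for t in rest:
        if t.tu_id not in eligible_ids:
            out[t.tu_id] = "ineligible"
    calls = call_extragenic_enhancers(rest, genes, peaks, params)
    called_ids = set()
    for c in calls:
        if c.directionality == "bidirectional":
            a, b = c.member_tus
            out[a.tu_id] = f"extragenic:bidirectional:{b.tu_id}"
            out[b.tu_id] = f"extragenic:bidirectional:{a.tu_id}"
            called_ids.update((a.tu_id, b.tu_id))
        else:
            out[c.member_tus[0].tu_id] = "extragenic:unidirectional"
            called_ids.add(c.member_tus[0].tu_id)
    for t in eligible:
        if t.tu_id not in called_ids:
            out[t.tu_id] = "extragenic:nomarks"
    return out
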