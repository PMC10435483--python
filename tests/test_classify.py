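"""CAT/DAT classification and enhancer-calling rules, vs a brute-force oracle."""

import numpy as np
import pytest

from catnet.classify import (
    ClassifyParams,
    call_extragenic_enhancers,
    call_intragenic_enhancers,
    classify_antisense,
    classify_atu,
    extragenic_eligible,
    find_antisense_units,
    pair_bidirectional,
)
from catnet.model import ATUCall, GeneModel, Isoform, TranscriptionUnit

from oracles import (
    _toy_gene,
    brute_classify,
    package_classify,
    random_toy_scenario,
)


def tu(start, end, strand, tu_id="t1", chrom="chr1"):
    return TranscriptionUnit(chrom=chrom, strand=strand, start=start, end=end,
                             total_count=100, tu_id=tu_id)


def active_gene(gene_id, start, end, strand, chrom="chr1"):
    g = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                  isoforms=[Isoform(f"{gene_id}.1", ((start, end),), strand,
                                    tpm=10.0)], active=True)
    g.active_tss = frozenset({g.isoforms[0].tss})
    g.active_polya = frozenset({g.isoforms[0].polya})
    return g


# -- candidate discovery ----------------------------------------------

def test_antisense_candidate_requires_active_opposite_gene():
    host = active_gene("g1", 5000, 9000, "-")
    inside = tu(6000, 6500, "+")
    assert find_antisense_units([inside], [host])[0].host_gene == "g1"
    host_inactive = active_gene("g2", 5000, 9000, "-")
    host_inactive.active = False
    assert find_antisense_units([inside], [host_inactive]) == []
    nowhere = tu(20_000, 20_500, "+")
    assert find_antisense_units([nowhere], [host]) == []
    same_strand = tu(6000, 6500, "-")
    assert find_antisense_units([same_strand], [host]) == []


def test_host_tie_breaks_to_greater_overlap():
    g1 = active_gene("g1", 1000, 4000, "-")
    g2 = active_gene("g2", 3500, 8000, "-")
    candidate = tu(3400, 5000, "+")  # 600 bp in g1... no: 600 vs 1500
    (call,) = find_antisense_units([candidate], [g1, g2])
    assert call.host_gene == "g2"


# -- DAT/CAT assignment ------------------------------------------------

def host_with_span(start, end, strand, active_tss=None, chrom="chr1"):
    g = active_gene("h", start, end, strand, chrom)
    if active_tss is not None:
        g.active_tss = frozenset(active_tss)
    return g


@pytest.mark.parametrize("upstream,expected", [(999, "DAT"), (1000, "discarded")])
def test_dat_window_strict_boundary(upstream, expected):
    # host span extended upstream so the TU is a genuine candidate
    g = _toy_gene("h", "chr1", "+", 10_000, 14_000, upstream_ext=1500)
    origin = 10_000 - upstream
    cand = ATUCall(tu=tu(origin - 300, origin + 1, "-"), host_gene="h")
    out = classify_atu(cand, g)
    assert out.cls == expected


def test_alternative_downstream_tss_reassigns_cat_to_dat():
    g = _toy_gene("h", "chr1", "+", 10_000, 14_000, alt_tss_offset=1500)
    origin = 11_500 - 400  # 400 bp upstream of the alternative TSS, mid-gene
    cand = ATUCall(tu=tu(origin - 300, origin + 1, "-"), host_gene="h")
    assert classify_atu(cand, g).cls == "DAT"


def test_origin_downstream_of_tss_inside_span_is_cat():
    g = host_with_span(10_000, 14_000, "+")
    cand = ATUCall(tu=tu(11_500, 12_001, "-"), host_gene="h")
    out = classify_atu(cand, g)
    assert out.cls == "CAT"


def test_minus_strand_host_symmetry():
    g = host_with_span(10_000, 14_000, "-")  # TSS at 13_999
    cand = ATUCall(tu=tu(12_000, 12_400, "+"), host_gene="h")  # origin 12_000
    assert classify_atu(cand, g).cls == "CAT"


def test_host_without_active_tss_is_contract_error():
    g = host_with_span(10_000, 14_000, "+", active_tss=())
    with pytest.raises(ValueError):
        classify_atu(ATUCall(tu=tu(11_000, 11_400, "-"), host_gene="h"), g)


# -- spill-over filters ------------------------------------------------

def test_half_overlap_with_same_strand_gene_discards():
    host = active_gene("host", 27_000, 30_500, "-")
    neighb = active_gene("nb", 31_000, 33_000, "+")
    exactly_half = tu(30_000, 32_000, "+")
    out = classify_antisense([exactly_half], [host, neighb])
    assert out[0].discard_reason == "overlapping_gene"
    just_below = tu(29_999, 31_999, "+")
    out2 = classify_antisense([just_below], [host, neighb])
    assert out2[0].discard_reason != "overlapping_gene"


def test_ninety_percent_gene_coverage_discards():
    host = active_gene("host", 33_800, 37_800, "-")
    small = active_gene("small", 35_000, 36_000, "+")
    covering = tu(33_900, 35_900, "+")  # 900/1000 of `small`, 45% of itself
    out = classify_antisense([covering], [host, small])
    assert out[0].discard_reason == "overlapping_gene"
    below = tu(33_900, 35_899, "+")
    out2 = classify_antisense([below], [host, small])
    assert out2[0].cls == "CAT"


def test_tu_spanning_entire_host_discarded():
    host = active_gene("host", 23_000, 23_900, "-")
    blanket = tu(22_800, 24_000, "+")
    out = classify_antisense([blanket], [host])
    assert out[0].discard_reason == "covers_antisense_gene"


def test_every_candidate_gets_exactly_one_outcome():
    rng = np.random.default_rng(5)
    tus, genes, peaks = random_toy_scenario(rng)
    calls = classify_antisense(tus, genes)
    for c in calls:
        assert (c.cls in ("CAT", "DAT")) != (c.cls == "discarded")
        if c.cls == "discarded":
            assert c.discard_reason in ("overlapping_gene",
                                        "covers_antisense_gene", "alt_promoter")
        else:
            assert c.discard_reason == "none"


# -- intragenic enhancers ---------------------------------------------

def _peaks(chrom="chr1", intervals=((11_000, 12_500),), marks=("H3K27ac", "H3K4me1")):
    return {m: {chrom: list(intervals)} for m in marks}


def test_intragenic_requires_both_marks():
    host = host_with_span(10_000, 14_000, "+")
    cat = classify_atu(ATUCall(tu=tu(11_500, 12_001, "-"), host_gene="h"), host)
    both = call_intragenic_enhancers([cat], _peaks())
    assert len(both) == 1
    assert both[0].kind == "intragenic" and both[0].center == 12_000
    only_ac = {"H3K27ac": {"chr1": [(11_000, 12_500)]}, "H3K4me1": {"chr1": []}}
    assert call_intragenic_enhancers([cat], only_ac) == []
    with pytest.raises(ValueError):
        call_intragenic_enhancers([cat], {"H3K27ac": {"chr1": []}})


# -- extragenic enhancers ---------------------------------------------

def test_bidirectional_distance_strict_boundary():
    a = tu(9_700, 10_001, "-", "a")   # origin 10_000
    b = tu(10_499, 10_800, "+", "b")  # origin 10_499 -> distance 499
    peaks = _peaks(intervals=((9_000, 11_500),))
    calls = call_extragenic_enhancers([a, b], [], peaks)
    assert len(calls) == 1 and calls[0].directionality == "bidirectional"
    assert calls[0].center == (10_000 + 10_499) // 2
    b500 = tu(10_500, 10_800, "+", "b")
    calls2 = call_extragenic_enhancers([a, b500], [], peaks)
    assert sorted(c.directionality for c in calls2) == ["unidirectional"] * 2


def test_termination_zone_excludes_origins():
    g = active_gene("g", 5_000, 8_000, "+")  # polyA 7_999, zone to +2000
    inside = tu(7_999 + 1_999, 7_999 + 2_399, "+", "in")
    past = tu(7_999 + 2_001, 7_999 + 2_401, "+", "out")
    eligible = extragenic_eligible([inside, past], [g])
    assert [t.tu_id for t in eligible] == ["out"]


def test_promoter_window_blocks_even_inactive_genes():
    g = active_gene("g", 5_000, 8_000, "+")
    g.active = False  # fails activity, promoter still annotated
    at_promoter = tu(5_000, 5_400, "-", "p")  # origin 5_399, 399 bp from TSS
    away = tu(3_000, 3_400, "-", "q")
    eligible = extragenic_eligible([at_promoter, away], [g])
    assert [t.tu_id for t in eligible] == ["q"]


def test_greedy_pairing_is_input_order_independent():
    tus = [tu(1_000, 1_301, "-", "a"),    # origin 1_300
           tu(1_500, 1_900, "+", "b"),    # origin 1_500 (d=200 to a)
           tu(1_650, 2_000, "+", "c")]    # origin 1_650 (d=350 to a)
    for perm in ([0, 1, 2], [2, 1, 0], [1, 2, 0]):
        pairs, singles = pair_bidirectional([tus[i] for i in perm])
        assert len(pairs) == 1
        assert {p.tu_id for p in pairs[0]} == {"a", "b"}
        assert [s.tu_id for s in singles] == ["c"]


# -- oracle agreement --------------------------------------------------

@pytest.mark.parametrize("seed", range(25))
def test_agrees_with_brute_force_oracle(seed):
    """Full classification identical to an independent all-pairs
    implementation on randomized toy genomes with boundary cases."""
    rng = np.random.default_rng(seed)
    tus, genes, peaks = random_toy_scenario(rng)
    assert package_classify(tus, genes, peaks) == brute_classify(tus, genes, peaks)


def test_every_emitted_call_overlaps_both_marks(default_sim, default_tracks):
    from catnet.annotation import call_active_genes
    from catnet.tu import call_transcription_units

    cfg, genome, ann = default_sim
    control, _, _ = default_tracks
    tus = call_transcription_units(control["c0"])
    genes = call_active_genes(ann.genes, tus)
    atus = classify_antisense(tus, genes)
    cats = [a for a in atus if a.cls == "CAT"]
    intra = call_intragenic_enhancers(cats, ann.peaks)
    seen = {(a.tu.chrom, a.tu.strand, a.tu.start) for a in atus}
    rest = [t for t in tus if (t.chrom, t.strand, t.start) not in seen]
    extra = call_extragenic_enhancers(rest, genes, ann.peaks)
    for call in intra + extra:
        assert call.marks_present >= {"H3K27ac", "H3K4me1"}
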