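"""Quantification, normalization, spike-in factors and the NB Wald test."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from catnet.differential import (
    Region,
    bh_adjust,
    build_count_matrix,
    normalize,
    pausing_matrix,
    quantify_regions,
    spikein_size_factors,
    stratify_by_signal,
)
from catnet.differential import test_differential as run_diff_test
from catnet.track import OccupancyTrack


def simple_track():
    t = OccupancyTrack()
    for p in range(100, 200):
        t.add("chr1", "+", p, 2)
    for p in range(150, 250):
        t.add("chr1", "-", p, 1)
    return t


# -- quantification ----------------------------------------------------

def test_empty_track_all_zero():
    regions = [Region("r1", "chr1", 0, 100), Region("r2", "chr2", 5, 50)]
    counts = quantify_regions(OccupancyTrack(), regions)
    assert (counts == 0).all()


def test_whole_chromosome_conserves_total():
    t = simple_track()
    r = Region("all", "chr1", 0, 1000, strand=".")
    assert quantify_regions(t, [r], "both")["all"] == t.total()


@pytest.mark.parametrize("rule,expected", [
    ("sense", 200), ("antisense", 100), ("both", 300)])
def test_strand_rules(rule, expected):
    t = simple_track()
    r = Region("r", "chr1", 0, 1000, strand="+")
    assert quantify_regions(t, [r], rule)["r"] == expected


def test_region_outside_chromosome_errors():
    r = Region("r", "chr1", 0, 2000, strand="+")
    with pytest.raises(ValueError):
        quantify_regions(simple_track(), [r], chrom_sizes={"chr1": 1000})


def test_quantification_recovers_planted_signal(default_sim, default_tracks):
    """Planted gene-body counts recovered within Poisson error."""
    from catnet import synthetic as syn
    cfg, genome, ann = default_sim
    control, _, _ = default_tracks
    regions = syn.truth_gene_regions(ann)
    counts = quantify_regions(control["c0"], regions)
    rates = {el.element_id: el.rates for el in ann.elements}
    checked = 0
    for r in regions:
        gene_id = r.region_id.split(":")[0]
        if r.cls != "gene_body" or gene_id not in rates:
            continue
        el = next(e for e in ann.elements if e.element_id == gene_id)
        sel = (el.positions >= r.start) & (el.positions < r.end)
        mu = el.rates[sel].sum()
        if mu < 100:
            continue
        assert abs(counts[r.region_id] - mu) < 4 * np.sqrt(mu)
        checked += 1
    assert checked > 100


# -- normalization -----------------------------------------------------

def test_tpm_single_region_is_closure():
    counts = pd.DataFrame({"s1": [7]}, index=["r"])
    out = normalize(counts, "TPM", region_lengths=pd.Series({"r": 1500}))
    assert np.isclose(out.loc["r", "s1"], 1e6)


def test_rpm_identity_and_scale_invariance():
    counts = pd.DataFrame({"s1": [250_000, 750_000]}, index=["a", "b"])
    out = normalize(counts, "RPM")
    assert np.allclose(out["s1"], counts["s1"])  # column sums to 1e6
    doubled = normalize(counts * 2, "RPM")
    assert np.allclose(doubled, out)


def test_rle_divides_by_factors():
    counts = pd.DataFrame({"a": [10, 20], "b": [40, 80]}, index=["r1", "r2"])
    out = normalize(counts, "RLE", size_factors=pd.Series({"a": 1.0, "b": 4.0}))
    assert np.allclose(out["a"], out["b"])


def test_zero_column_sum_errors():
    with pytest.raises(ValueError):
        normalize(pd.DataFrame({"s": [0, 0]}, index=["a", "b"]), "RPM")


# -- spike-in size factors --------------------------------------------

def spike_matrix(scale_b=1.0):
    rng = np.random.default_rng(0)
    base = rng.poisson(200, 30).astype(float) + 1
    return pd.DataFrame({"a": base, "b": base * scale_b},
                        index=[f"SP{i}" for i in range(30)])


def test_identical_samples_unit_factors():
    m = spike_matrix()
    f = spikein_size_factors(m, m.index)
    assert np.allclose(f, [1.0, 1.0], atol=1e-12)


def test_doubled_sample_doubles_factor():
    m = spike_matrix(scale_b=2.0)
    f = spikein_size_factors(m, m.index)
    assert np.isclose(f["b"] / f["a"], 2.0)


def test_scale_equivariance():
    m = spike_matrix(scale_b=1.3)
    f = spikein_size_factors(m, m.index)
    m2 = m.copy()
    m2["a"] = m2["a"] * 5
    f2 = spikein_size_factors(m2, m2.index)
    assert np.isclose(f2["a"] / f["a"], 5 * f2["b"] / f["b"])


def test_zero_regions_excluded_and_all_zero_errors():
    m = spike_matrix()
    m.iloc[0, 0] = 0  # excluded from reference, still works
    spikein_size_factors(m, m.index)
    m[:] = 0
    with pytest.raises(ValueError):
        spikein_size_factors(m, m.index)


def test_spikein_recovers_global_loss(default_sim):
    """4-fold global loss: spike factors report ~-2; library size ~0."""
    from catnet import synthetic as syn
    cfg, genome, ann = default_sim
    rng = np.random.default_rng(77)
    tracks = {f"c{i}": syn.simulate_occupancy(ann, rng=rng)[0] for i in range(2)}
    tracks |= {f"t{i}": syn.simulate_occupancy(ann, rng=rng, body_fc=0.25,
                                               proximal_fc=0.25)[0]
               for i in range(2)}
    regions = syn.truth_gene_regions(ann) + ann.spike_regions
    mat = build_count_matrix(tracks, regions)
    design = {"c0": "control", "c1": "control", "t0": "treated", "t1": "treated"}
    spike_ids = [r.region_id for r in ann.spike_regions]
    body_ids = [r.region_id for r in regions if r.cls == "gene_body"]
    sf = spikein_size_factors(mat, spike_ids)
    res = run_diff_test(mat.loc[body_ids], design, size_factors=sf)
    assert -2.1 < res["log2fc"].median() < -1.9
    prim = mat.loc[[r.region_id for r in regions if r.species == "primary"]]
    lib = prim.sum(axis=0) / prim.sum(axis=0).mean()
    res2 = run_diff_test(mat.loc[body_ids], design, size_factors=lib)
    assert abs(res2["log2fc"].median()) < 0.3


# -- differential test -------------------------------------------------

def nb_counts(rng, mu, n, disp=0.05):
    r = 1 / disp
    lam = rng.gamma(r, np.asarray(mu)[:, None] / r, (len(mu), n))
    return rng.poisson(lam)


DESIGN_3V3 = {f"c{i}": "control" for i in range(3)} | \
    {f"t{i}": "treated" for i in range(3)}


def test_low_count_regions_excluded():
    counts = pd.DataFrame(
        [[1, 1, 1, 1, 1, 0], [10, 9, 11, 10, 10, 12]],
        index=["low", "ok"], columns=list(DESIGN_3V3))
    res = run_diff_test(counts, DESIGN_3V3)
    assert "low" not in res.index and "ok" in res.index


def test_identical_conditions_zero_lfc():
    counts = pd.DataFrame({s: [100, 40] for s in DESIGN_3V3},
                          index=["a", "b"])
    res = run_diff_test(counts, DESIGN_3V3)
    assert (res["log2fc"] == 0).all()
    assert (res["pvalue"] == 1.0).all()


def test_null_type_one_error_calibrated():
    rng = np.random.default_rng(42)
    mu = rng.lognormal(np.log(100), 1.0, 1000)
    counts = pd.DataFrame(
        np.hstack([nb_counts(rng, mu, 3), nb_counts(rng, mu, 3)]),
        columns=list(DESIGN_3V3), index=[f"r{i}" for i in range(1000)])
    res = run_diff_test(counts, DESIGN_3V3)
    rate = (res["pvalue"] < 0.05).mean()
    assert 0.03 <= rate <= 0.08


def test_power_for_fourfold_change():
    rng = np.random.default_rng(43)
    mu = rng.lognormal(np.log(300), 0.3, 200)
    counts = pd.DataFrame(
        np.hstack([nb_counts(rng, mu, 3), nb_counts(rng, mu * 0.25, 3)]),
        columns=list(DESIGN_3V3), index=[f"r{i}" for i in range(200)])
    res = run_diff_test(counts, DESIGN_3V3)
    assert res["significant"].mean() >= 0.9
    assert (res["log2fc"] - (-2)).abs().median() < 0.3


def test_single_replicate_falls_back_to_poisson():
    counts = pd.DataFrame({"c": [100], "t": [400]}, index=["r"])
    res = run_diff_test(counts, {"c": "control", "t": "treated"})
    assert res.loc["r", "pvalue"] < 0.01


def test_degenerate_design_errors():
    counts = pd.DataFrame({"a": [5]}, index=["r"])
    with pytest.raises(ValueError):
        run_diff_test(counts, {"a": "control"})


def test_bh_matches_statsmodels():
    rng = np.random.default_rng(1)
    p = rng.uniform(size=200)
    ours = bh_adjust(p)
    ref = multipletests(p, method="fdr_bh")[1]
    assert np.allclose(ours, ref)


# -- pausing matrix ----------------------------------------------------

def df(lfcs):
    return pd.DataFrame({"log2fc": lfcs},
                        index=[f"g{i}" for i in range(len(lfcs))])


def test_quadrants_by_sign():
    pm = pausing_matrix(df([0.5, -1.0, 0.0]), df([-1.2, 2.0, 0.3]))
    assert list(pm["quadrant"]) == ["up/down", "down/up", "unchanged"]


def test_id_mismatch_errors():
    with pytest.raises(ValueError):
        pausing_matrix(df([1.0]), df([1.0, 2.0]))


def test_perturbation_lands_in_pausing_quadrant(default_sim, default_tracks):
    """Pause-release defect: proximal up, body down for nearly all genes."""
    from catnet import synthetic as syn
    cfg, genome, ann = default_sim
    control, treated, _ = default_tracks
    regions = syn.truth_gene_regions(ann) + ann.spike_regions
    mat = build_count_matrix(control | treated, regions)
    sf = spikein_size_factors(mat, [r.region_id for r in ann.spike_regions])
    design = {s: ("control" if s.startswith("c") else "treated")
              for s in control | treated}
    prox = run_diff_test(
        mat.loc[[r.region_id for r in regions if r.cls == "promoter_proximal"]],
        design, size_factors=sf)
    body = run_diff_test(
        mat.loc[[r.region_id for r in regions if r.cls == "gene_body"]],
        design, size_factors=sf)
    prox.index = [i.split(":")[0] for i in prox.index]
    body.index = [i.split(":")[0] for i in body.index]
    common = prox.index.intersection(body.index)
    pm = pausing_matrix(prox.loc[common], body.loc[common])
    assert (pm["quadrant"] == "up/down").mean() >= 0.9


@pytest.mark.parametrize("proximal_width", [300, 500, 800])
def test_pausing_conclusion_robust_to_region_geometry(default_sim,
                                                      default_tracks,
                                                      proximal_width):
    """The pause-release signature survives varying the proximal window."""
    from catnet import synthetic as syn
    cfg, genome, ann = default_sim
    control, treated, _ = default_tracks
    regions = (syn.truth_gene_regions(ann, proximal_width=proximal_width)
               + ann.spike_regions)
    mat = build_count_matrix(control | treated, regions)
    sf = spikein_size_factors(mat, [r.region_id for r in ann.spike_regions])
    design = {s: ("control" if s.startswith("c") else "treated")
              for s in control | treated}
    prox = run_diff_test(
        mat.loc[[r.region_id for r in regions if r.cls == "promoter_proximal"]],
        design, size_factors=sf)
    body = run_diff_test(
        mat.loc[[r.region_id for r in regions if r.cls == "gene_body"]],
        design, size_factors=sf)
    prox.index = [i.split(":")[0] for i in prox.index]
    body.index = [i.split(":")[0] for i in body.index]
    common = prox.index.intersection(body.index)
    pm = pausing_matrix(prox.loc[common], body.loc[common])
    assert (pm["quadrant"] == "up/down").mean() >= 0.85


def test_region_builders_from_models(default_sim, default_tracks):
    from catnet.annotation import call_active_genes
    from catnet.classify import ClassifyParams
    from catnet.differential import regions_from_enhancers, regions_from_genes
    from catnet.model import EnhancerCall
    from catnet.tu import call_transcription_units

    cfg, genome, ann = default_sim
    control, _, _ = default_tracks
    genes = call_active_genes(ann.genes, call_transcription_units(control["c0"]))
    regions = regions_from_genes(genes, proximal_width=500)
    active = [g for g in genes if g.active]
    assert len(regions) == 2 * len(active)
    by_gene = {}
    for r in regions:
        by_gene.setdefault(r.region_id.split(":")[0], []).append(r)
    for g in active:
        prox, body = sorted(by_gene[g.gene_id], key=lambda r: r.cls != "promoter_proximal")
        assert prox.end - prox.start == 500
        es, ee = g.effective_span
        assert (prox.end - prox.start) + (body.end - body.start) == ee - es
    call = EnhancerCall(enh_id="e", kind="extragenic",
                        directionality="bidirectional", chrom="chr1",
                        start=1000, end=2200, center=1300, member_tus=())
    rs = {r.cls: r for r in regions_from_enhancers([call])}
    assert rs["enhancer_proximal"].start == 1050
    assert rs["enhancer_proximal"].end == 1551
    assert rs["enhancer_distal"] .start == 1551 and rs["enhancer_distal"].end == 2200


# -- stratification ----------------------------------------------------

def test_equal_group_sizes():
    values = pd.Series(range(8), index=[f"r{i}" for i in range(8)])
    labels = stratify_by_signal(values, k=4)
    assert labels.value_counts().to_dict() == {f"Q{i}": 2 for i in range(1, 5)}


def test_ties_break_by_id_order():
    values = pd.Series([5.0] * 4, index=["d", "c", "b", "a"])
    labels = stratify_by_signal(values, k=2)
    assert labels["a"] == "Q1" and labels["b"] == "Q1"
    assert labels["c"] == "Q2" and labels["d"] == "Q2"


def test_rank_arithmetic_top_quartile():
    values = pd.Series(range(1, 101), index=[f"r{i:03d}" for i in range(100)])
    labels = stratify_by_signal(values, k=4)
    q4 = values[labels == "Q4"]
    assert sorted(q4) == list(range(76, 101))


def test_k_larger_than_n_errors():
    with pytest.raises(ValueError):
        stratify_by_signal(pd.Series([1.0, 2.0], index=["a", "b"]), k=3)
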