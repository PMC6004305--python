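"""Landscape summaries: fractions, histograms, composition, metagene profiles."""

import math

import numpy as np
import pandas as pd
import pytest

from bsmeth import landscape, simulate
from bsmeth.landscape import MetageneConfig

from conftest import make_counts


def _sites_at(positions, chrom="c", context="CG", strand="+"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=np.int64),
            "strand": strand,
            "context": context,
            "neighborhood": "N" * 9,
        }
    )


# ---------------------------------------------------------------------------
# global fractions


def test_global_fractions_by_hand():
    sites = _sites_at([10, 20, 30, 40])
    counts = make_counts(sites, [5, 7, 9, 0], [5, 3, 1, 10], conversion_failure_rate=0.0)
    gf = landscape.global_fractions(counts)
    cg = gf[gf["context"] == "CG"].iloc[0]
    assert cg["n_covered"] == 4 and cg["n_methylated"] == 3
    assert cg["fraction_covered"] == 0.75


def test_global_fractions_all_unmethylated():
    sites = _sites_at([10, 20])
    counts = make_counts(sites, [0, 0], [9, 9])
    gf = landscape.global_fractions(counts)
    assert (gf.loc[gf["n_covered"] > 0, "fraction_covered"] == 0).all()


def test_global_fractions_undefined_without_coverage():
    sites = _sites_at([10])
    counts = make_counts(sites, [0], [0])
    gf = landscape.global_fractions(counts)
    assert np.isnan(gf.loc[gf["context"] == "CG", "fraction_covered"]).all()


def test_configured_fractions_recovered(default_bundle):
    """Realised per-context methylated fractions sit within 3 binomial SE
    of the configured regime (0.81 CG / 0.64 CHG / 0.05 CHH)."""
    cfg = default_bundle["config"]
    counts = default_bundle["counts"]["sample_a"]
    gf = landscape.global_fractions(counts).set_index("context")
    for ctx, p in cfg.p_methylated.items():
        row = gf.loc[ctx]
        se = math.sqrt(p * (1 - p) / row["n_covered"])
        # the conversion-failure floor biases the call rate upward a little;
        # allow it on top of sampling error
        bias = 0.01
        assert abs(row["fraction_covered"] - p) < 3 * se + bias, ctx


# ---------------------------------------------------------------------------
# level histogram


def test_histogram_single_top_bin():
    sites = _sites_at([10, 20, 30])
    counts = make_counts(sites, [19, 23, 20], [1, 2, 1])
    h = landscape.level_histogram(counts, "CG")
    assert h.loc[9, "proportion"] == 1.0


def test_histogram_spread_and_right_closure():
    sites = _sites_at([10, 20, 30])
    counts = make_counts(sites, [3, 7, 19], [17, 13, 1])  # 0.15, 0.35, 0.95
    h = landscape.level_histogram(counts, "CG")
    assert h.loc[1, "proportion"] == pytest.approx(1 / 3)
    assert h.loc[3, "proportion"] == pytest.approx(1 / 3)
    assert h.loc[9, "proportion"] == pytest.approx(1 / 3)
    # a level exactly on an edge belongs to the lower (right-closed) bin
    counts2 = make_counts(_sites_at([5]), [2], [8])  # 0.2
    h2 = landscape.level_histogram(counts2, "CG")
    assert h2.loc[1, "n"] == 1


def test_histogram_proportions_sum_to_one(small_bundle):
    counts = small_bundle["counts"]["sample_a"]
    for ctx in ("CG", "CHG", "CHH"):
        h = landscape.level_histogram(counts, ctx)
        assert h["proportion"].sum() == pytest.approx(1.0, abs=1e-9)


def test_chh_histogram_shape_matches_beta_truth(default_bundle):
    """CHH site levels drawn from a low broad distribution put more mass in
    (0.1, 0.4] than above 0.9; CG does the opposite."""
    counts = default_bundle["counts"]["sample_a"]
    chh = landscape.level_histogram(counts, "CHH")
    mass_low = chh.loc[1:3, "proportion"].sum()
    assert mass_low > chh.loc[9, "proportion"]
    cg = landscape.level_histogram(counts, "CG")
    assert cg.loc[9, "proportion"] == cg["proportion"].max()


# ---------------------------------------------------------------------------
# neighbourhood composition


def test_composition_single_site():
    sites = _sites_at([10])
    sites["neighborhood"] = ["AAAACGAAA"]
    counts = make_counts(sites, [5], [0])
    comp = landscape.neighborhood_composition(sites, counts)
    g = comp[(comp["offset"] == 1) & (comp["base"] == "G") & (comp["status"] == "mC")]
    assert g["frequency"].iloc[0] == 1.0


def test_composition_columns_sum_to_one(small_bundle):
    comp = landscape.neighborhood_composition(
        small_bundle["sites"], small_bundle["counts"]["sample_a"]
    )
    sums = comp.groupby(["context", "status", "offset"])["frequency"].sum()
    assert np.allclose(sums, 1.0)


def test_composition_enrichment_is_visible():
    """mCHH sites built around CAT trinucleotides show elevated A at +1."""
    rng = np.random.default_rng(0)
    n = 400
    neigh_mc = ["".join(rng.choice(list("ACGT"), 3)) + "NCAT" + "AA" for _ in range(n)]
    neigh_c = ["".join(rng.choice(list("ACGT"), 3)) + "NCTT" + "AA" for _ in range(n)]
    sites = _sites_at(np.arange(2 * n) * 10, context="CHH")
    sites["neighborhood"] = [s.replace("N", "A") for s in neigh_mc + neigh_c]
    counts = make_counts(sites, [9] * n + [0] * n, [1] * n + [9] * n,
                         conversion_failure_rate=0.0)
    comp = landscape.neighborhood_composition(sites, counts)
    sel = (comp["context"] == "CHH") & (comp["offset"] == 1) & (comp["base"] == "A")
    a_mc = comp[sel & (comp["status"] == "mC")]["frequency"].iloc[0]
    a_c = comp[sel & (comp["status"] == "C")]["frequency"].iloc[0]
    assert a_mc > a_c


# ---------------------------------------------------------------------------
# metagene profiles


def _one_gene(start, end, strand, chrom="c"):
    return pd.DataFrame(
        [{"chrom": chrom, "start": start, "end": end, "name": "g0",
          "strand": strand, "label": "gene"}]
    )


def test_metagene_single_upstream_site():
    """A site 50 bp before the TSS of a + gene lands in the last upstream bin."""
    sites = _sites_at([1950])
    counts = make_counts(sites, [6], [4])
    prof = landscape.metagene_profile(counts, _one_gene(2000, 3000, "+"), contexts=("CG",))
    up = prof[(prof["zone"] == "upstream")].set_index("bin")
    assert up.loc[19, "mean_level"] == pytest.approx(0.6)
    assert up.loc[19, "n_sites"] == pytest.approx(1.0)
    others = prof[~((prof["zone"] == "upstream") & (prof["bin"] == 19))]
    assert others["n_sites"].sum() == 0
    assert others["mean_level"].isna().all()


def test_metagene_minus_strand_flips_zone():
    """The same site is downstream bin 0 when the gene is on the - strand."""
    sites = _sites_at([1950])
    counts = make_counts(sites, [6], [4])
    prof = landscape.metagene_profile(counts, _one_gene(2000, 3000, "-"), contexts=("CG",))
    down = prof[prof["zone"] == "downstream"].set_index("bin")
    assert down.loc[0, "mean_level"] == pytest.approx(0.6)


def test_metagene_constant_level_preserved(small_bundle):
    sites = small_bundle["sites"]
    counts = make_counts(sites, np.full(len(sites), 5), np.full(len(sites), 5))
    prof = landscape.metagene_profile(counts, small_bundle["genes"])
    filled = prof[prof["n_sites"] > 0]
    assert np.allclose(filled["mean_level"], 0.5)


def test_metagene_strand_flip_symmetry(small_bundle):
    """Flipping every feature's strand reverses the 60-bin profile exactly."""
    counts = small_bundle["counts"]["sample_a"]
    genes = small_bundle["genes"]
    flipped = genes.copy()
    flipped["strand"] = np.where(genes["strand"] == "+", "-", "+")
    a = landscape.metagene_profile(counts, genes)
    b = landscape.metagene_profile(counts, flipped)
    for ctx in ("CG", "CHG", "CHH"):
        pa = a[a["context"] == ctx].reset_index(drop=True)
        pb = b[b["context"] == ctx].reset_index(drop=True)
        va = pa["mean_level"].to_numpy()
        vb = pb["mean_level"].to_numpy()[::-1]
        assert np.array_equal(va, vb, equal_nan=True)
        assert np.array_equal(pa["n_sites"].to_numpy(), pb["n_sites"].to_numpy()[::-1])


def test_metagene_pooled_mean_identity(small_bundle):
    """Weighted mean of body-bin means equals the direct body-site mean."""
    counts = small_bundle["counts"]["sample_a"]
    genes = small_bundle["genes"]
    prof = landscape.metagene_profile(counts, genes, contexts=("CG",))
    body = prof[(prof["zone"] == "body") & (prof["n_sites"] > 0)]
    pooled = (body["mean_level"] * body["n_sites"]).sum() / body["n_sites"].sum()
    covered = counts[(counts["context"] == "CG") & (counts["n_meth"] + counts["n_unmeth"] > 0)]
    direct_terms = []
    for g in genes.itertuples():
        sel = (covered["chrom"] == g.chrom) & (covered["pos"] >= g.start) & (covered["pos"] < g.end)
        direct_terms.append(covered.loc[sel, "level"])
    direct = pd.concat(direct_terms)
    assert pooled == pytest.approx(direct.mean(), abs=1e-9)


def test_metagene_short_feature_flags_empty_bins():
    sites = _sites_at([105])
    counts = make_counts(sites, [5], [5])
    prof = landscape.metagene_profile(
        counts, _one_gene(100, 110, "+"), contexts=("CG",)
    )
    body = prof[prof["zone"] == "body"]
    # a 10-bp body cannot fill 20 bins; empties are NaN, the site's two bins share it
    assert body["mean_level"].isna().sum() == 18
    assert body["n_sites"].sum() == pytest.approx(1.0)


def test_metagene_rejects_bad_binning():
    with pytest.raises(ValueError):
        MetageneConfig(flank=2000, bin_size=130)


# ---------------------------------------------------------------------------
# expression stratification


def test_expression_classes_partition():
    assert landscape.expression_class(0.0) == "none"
    assert landscape.expression_class(1.0) == "none"
    assert landscape.expression_class(1.01) == "low"
    assert landscape.expression_class(10.0) == "low"
    assert landscape.expression_class(99.9) == "medium"
    assert landscape.expression_class(100.0) == "high"


def test_stratified_single_class_equals_unstratified(small_bundle):
    counts = small_bundle["counts"]["sample_a"]
    genes = small_bundle["genes"]
    expr = pd.DataFrame({"gene_id": genes["name"], "rpkm": 0.0})
    strat = landscape.expression_stratified_profiles(counts, genes, expr, contexts=("CG",))
    assert set(strat["expression_class"]) == {"none"}
    plain = landscape.metagene_profile(counts, genes, contexts=("CG",))
    merged = strat.drop(columns=["expression_class", "n_genes"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(merged, plain)


def test_stratified_requires_matches(small_bundle):
    counts = small_bundle["counts"]["sample_a"]
    genes = small_bundle["genes"]
    expr = pd.DataFrame({"gene_id": ["nope"], "rpkm": [5.0]})
    with pytest.raises(ValueError):
        landscape.expression_stratified_profiles(counts, genes, expr)


def test_chg_elevation_in_unexpressed_bodies():
    """With the CHG body contrast on (0.3 unexpressed vs 0.05 expressed),
    the 'none' class exceeds the 'high' class in every body bin."""
    cfg = simulate.SimConfig(
        chrom_lengths={"c": 60_000}, n_genes=10, n_tes=0,
        spikes=simulate.SpikeConfig(n_per_context={}),
        chg_body_levels=(0.3, 0.05),
        expression_class_mix={"none": 0.5, "high": 0.5, "low": 0.0, "medium": 0.0},
        seed=21,
    )
    b = simulate.simulate_bundle(cfg)
    strat = landscape.expression_stratified_profiles(
        b["counts"]["sample_a"], b["genes"], b["expression"], contexts=("CHG",)
    )
    body = strat[strat["zone"] == "body"]
    none_ = body[body["expression_class"] == "none"].set_index("bin")["mean_level"]
    high = body[body["expression_class"] == "high"].set_index("bin")["mean_level"]
    assert (none_ > high).all()
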