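"""DMR calling: chi-square, chains, five criteria, association, audit."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bsmeth import dmr as dmr_mod
from bsmeth.dmr import (
    DmrThresholds,
    associate_dmrs,
    audit_dmrs,
    build_candidate_regions,
    call_dmrs,
    classify_hyper_hypo,
    fold_change,
    pearson_chi2,
    region_counts,
    zone_count_table,
)

from conftest import make_counts
import oracles


# ---------------------------------------------------------------------------
# Pearson chi-square


def test_chi2_diagonal_table_is_twenty():
    stat, p = pearson_chi2([[10, 0], [0, 10]])
    assert stat == 20.0
    assert p == pytest.approx(stats.chi2.sf(20.0, 1))


def test_chi2_independence_gives_zero():
    stat, p = pearson_chi2([[5, 5], [5, 5]])
    assert stat == 0.0 and p == 1.0


def test_chi2_zero_margin_degenerate():
    stat, p = pearson_chi2([[0, 0], [5, 5]])
    assert stat == 0.0 and p == 1.0


def test_chi2_rejects_negative_cells():
    with pytest.raises(ValueError):
        pearson_chi2([[-1, 2], [3, 4]])


def test_chi2_matches_expected_count_formula():
    """Closed form equals the textbook expected-count sum on random tables."""
    rng = np.random.default_rng(42)
    for _ in range(2000):
        a, b, c, d = rng.integers(1, 200, size=4)
        stat, _ = pearson_chi2([[a, b], [c, d]])
        assert stat == pytest.approx(oracles.chi2_expected_counts(a, b, c, d), abs=1e-9)


# ---------------------------------------------------------------------------
# candidate chains


def _th(**kw):
    return DmrThresholds(**kw)


def test_chain_by_hand_five_sites():
    """Sites at 100..700 with gaps < 200 form one kept candidate of span 601."""
    pos = np.array([100, 250, 400, 560, 700])
    out = build_candidate_regions(pos, pos, np.array([]), _th())
    assert out == [(100, 700)]
    assert out[0][1] - out[0][0] + 1 == 601


def test_chain_gap_rule_singletons_dropped():
    pos = np.array([100, 350])  # gap 250 splits; each singleton span 1 < 40
    out = build_candidate_regions(pos, pos, pos, _th())
    assert out == []


def test_chain_span_floor():
    pos = np.array([100, 105, 110, 115, 120])  # 5 sites in 21 bp
    out = build_candidate_regions(pos, pos, pos, _th())
    assert out == []


def test_chain_needs_five_methylated_in_one_sample():
    pos = np.array([100, 150, 200, 250, 300])
    # only 4 methylated sites in each sample inside the span
    out = build_candidate_regions(pos, pos[:4], pos[:4], _th())
    assert out == []
    out = build_candidate_regions(pos, pos, pos[:1], _th())
    assert out == [(100, 300)]


def test_chain_sign_flip_breaks():
    pos = np.array([100, 150, 200, 250, 300, 350])
    signs = np.array([1, 1, 1, -1, -1, -1], dtype=np.int8)
    out = build_candidate_regions(pos, pos, pos, _th(min_sites=3), seed_sign=signs)
    assert out == [(100, 200), (250, 350)]


def test_chains_match_brute_force_enumeration():
    """Chain construction equals an exhaustive enumerator on random inputs."""
    rng = np.random.default_rng(7)
    th = _th(min_sites=2)
    for _ in range(300):
        n = int(rng.integers(0, 25))
        pos = np.unique(rng.integers(0, 3000, size=n))
        signs = rng.choice([-1, 1], size=pos.size).astype(np.int8)
        mc_a = pos[rng.random(pos.size) < 0.7]
        mc_b = pos[rng.random(pos.size) < 0.7]
        got = build_candidate_regions(pos, mc_a, mc_b, th, seed_sign=signs)
        expected = oracles.brute_force_candidates(
            pos.tolist(), signs.tolist(), mc_a.tolist(), mc_b.tolist(),
            th.max_gap, th.min_length, th.max_length, th.min_sites,
        )
        assert got == expected


# ---------------------------------------------------------------------------
# region counts, fold change, direction


def _two_sample_counts(positions, meth_a, unmeth_a, meth_b, unmeth_b, context="CG"):
    sites = pd.DataFrame(
        {
            "chrom": "c",
            "pos": np.asarray(positions, dtype=np.int64),
            "strand": "+",
            "context": context,
            "neighborhood": "N" * 9,
        }
    )
    ca = make_counts(sites, meth_a, unmeth_a, conversion_failure_rate=0.0)
    cb = make_counts(sites, meth_b, unmeth_b, conversion_failure_rate=0.0)
    return ca, cb


def test_region_counts_pooled_levels():
    ca, cb = _two_sample_counts(
        [100, 250, 400, 560, 700],
        [10, 10, 10, 10, 10], [10, 10, 10, 10, 10],
        [2, 2, 2, 2, 2], [18, 18, 18, 18, 18],
    )
    data = dmr_mod._align_context(ca, cb, "CG", "c")
    rc = region_counts(data, 100, 700)
    assert rc["level_a"] == 0.5 and rc["level_b"] == 0.1
    assert rc["depth_a"] == 20.0 and rc["depth_b"] == 20.0


def test_mean_depth_exactly_ten_fails_strict_rule():
    """'more than ten reads' is strict: mean depth 10.0 is rejected."""
    ca, cb = _two_sample_counts(
        [100, 160, 220, 280, 340],
        [9, 9, 9, 9, 9], [1, 1, 1, 1, 1],   # depth 10.0 in A
        [1, 1, 1, 1, 1], [19, 19, 19, 19, 19],  # depth 20 in B
    )
    out = call_dmrs(ca, cb, "CG")
    assert len(out) == 0
    ca2, cb2 = _two_sample_counts(
        [100, 160, 220, 280, 340],
        [24, 24, 24, 24, 24], [3, 3, 3, 3, 3],
        [3, 3, 3, 3, 3], [24, 24, 24, 24, 24],
    )
    assert len(call_dmrs(ca2, cb2, "CG")) == 1  # depth 27 passes


def test_fold_change_pseudofloor():
    # zero level in B floored at 1/(reads+1)
    fc = fold_change(0.5, 100, 0.0, 99)
    assert fc == pytest.approx(0.5 / (1 / 100))
    assert fold_change(0.4, 50, 0.2, 50) == pytest.approx(2.0)


def test_direction_labels():
    assert classify_hyper_hypo(0.1, 0.5) == "hyper"
    assert classify_hyper_hypo(0.5, 0.1) == "hypo"


# ---------------------------------------------------------------------------
# call_dmrs composition


def test_call_dmrs_composed_example():
    """Levels 0.5 vs 0.1 over five dense sites at depth 20: one hypo DMR."""
    ca, cb = _two_sample_counts(
        [100, 250, 400, 560, 700],
        [10, 10, 10, 10, 10], [10, 10, 10, 10, 10],
        [2, 2, 2, 2, 2], [18, 18, 18, 18, 18],
    )
    out = call_dmrs(ca, cb, "CG")
    assert len(out) == 1
    d = out.iloc[0]
    assert d["start"] == 100 and d["end"] == 701
    assert d["direction"] == "hypo"
    assert d["fold_change"] == pytest.approx(5.0)
    assert d["p"] < 0.05


def test_identical_samples_no_dmrs():
    ca, cb = _two_sample_counts(
        [100, 250, 400, 560, 700],
        [10] * 5, [10] * 5, [10] * 5, [10] * 5,
    )
    assert len(call_dmrs(ca, ca.copy(), "CG")) == 0


def test_call_dmrs_direction_antisymmetric():
    ca, cb = _two_sample_counts(
        [100, 250, 400, 560, 700],
        [18, 18, 18, 18, 18], [2, 2, 2, 2, 2],
        [4, 4, 4, 4, 4], [16, 16, 16, 16, 16],
    )
    fwd = call_dmrs(ca, cb, "CG")
    rev = call_dmrs(cb, ca, "CG")
    assert list(fwd["direction"]) == ["hypo"]
    assert list(rev["direction"]) == ["hyper"]


def test_call_dmrs_context_mismatch():
    ca, cb = _two_sample_counts([100], [1], [1], [1], [1])
    with pytest.raises(ValueError):
        call_dmrs(ca, cb, "bogus")


def test_monotonicity_in_thresholds(small_bundle):
    """Raising min_fold or lowering alpha never yields more DMRs."""
    ca = small_bundle["counts"]["sample_a"]
    cb = small_bundle["counts"]["sample_b"]
    base = len(call_dmrs(ca, cb, "CG", _th()))
    stricter_fold = len(call_dmrs(ca, cb, "CG", _th(min_fold=3.0)))
    stricter_alpha = len(call_dmrs(ca, cb, "CG", _th(alpha=0.001)))
    assert stricter_fold <= base
    assert stricter_alpha <= base


def test_spike_recovery_small(small_bundle):
    """Spiked CG regions are found; calls cluster on spikes."""
    ca = small_bundle["counts"]["sample_a"]
    cb = small_bundle["counts"]["sample_b"]
    spikes = small_bundle["truth"].spikes
    cg_spikes = spikes[spikes["context"] == "CG"]
    out = call_dmrs(ca, cb, "CG")
    recovered = sum(
        ((out["chrom"] == s.chrom) & (out["start"] < s.end) & (out["end"] > s.start)).any()
        for s in cg_spikes.itertuples()
    )
    assert recovered >= len(cg_spikes) - 1


def test_audit_passes_on_emitted_dmrs(small_bundle):
    ca = small_bundle["counts"]["sample_a"]
    cb = small_bundle["counts"]["sample_b"]
    out = dmr_mod.concat_dmrs([call_dmrs(ca, cb, c) for c in ("CG", "CHG", "CHH")])
    failures = audit_dmrs(out, ca, cb)
    assert len(failures) == 0


def test_deterministic_output(small_bundle):
    ca = small_bundle["counts"]["sample_a"]
    cb = small_bundle["counts"]["sample_b"]
    d1 = call_dmrs(ca, cb, "CG")
    d2 = call_dmrs(ca.copy(), cb.copy(), "CG")
    pd.testing.assert_frame_equal(d1, d2)


# ---------------------------------------------------------------------------
# association


def _dmr_row(chrom, start, end, context="CG", direction="hyper"):
    return {
        "chrom": chrom, "start": start, "end": end, "context": context,
        "n_sites_a": 5, "n_sites_b": 5, "meth_a": 50, "unmeth_a": 50,
        "meth_b": 90, "unmeth_b": 10, "level_a": 0.5, "level_b": 0.9,
        "fold_change": 2.0, "chi2": 30.0, "p": 1e-8, "direction": direction,
    }


def _gene(chrom, start, end, strand, name="g0"):
    return pd.DataFrame(
        [{"chrom": chrom, "start": start, "end": end, "name": name,
          "strand": strand, "label": "gene"}]
    )


def test_associate_body():
    dmrs = pd.DataFrame([_dmr_row("c", 2500, 2600)])
    overlaps, ann = associate_dmrs(dmrs, _gene("c", 2000, 3000, "+"))
    assert list(overlaps["zone"]) == ["body"]
    assert ann["assoc_zone"].iloc[0] == "body"


def test_associate_up2k_respects_strand():
    dmrs = pd.DataFrame([_dmr_row("c", 100, 200)])
    _, ann_plus = associate_dmrs(dmrs, _gene("c", 2000, 3000, "+"))
    assert ann_plus["assoc_zone"].iloc[0] == "up2k"
    _, ann_minus = associate_dmrs(dmrs, _gene("c", 2000, 3000, "-"))
    assert ann_minus["assoc_zone"].iloc[0] == "down2k"


def test_associate_none():
    dmrs = pd.DataFrame([_dmr_row("c", 50_000, 50_100)])
    overlaps, ann = associate_dmrs(dmrs, _gene("c", 2000, 3000, "+"))
    assert len(overlaps) == 0
    assert ann["assoc_zone"].iloc[0] == "none"


def test_associate_priority_body_over_flank():
    """A DMR straddling the TSS is summarised as body, not up2k."""
    dmrs = pd.DataFrame([_dmr_row("c", 1950, 2050)])
    overlaps, ann = associate_dmrs(dmrs, _gene("c", 2000, 3000, "+"))
    assert set(overlaps["zone"]) == {"up2k", "body"}
    assert ann["assoc_zone"].iloc[0] == "body"


def test_zone_count_table_shape():
    dmrs = pd.DataFrame(
        [
            _dmr_row("c", 2500, 2600, "CG"),
            _dmr_row("c", 100, 200, "CHG"),
            _dmr_row("c", 9000, 9100, "CHH"),
        ]
    )
    _, ann = associate_dmrs(dmrs, _gene("c", 2000, 3000, "+"))
    tab = zone_count_table(ann)
    assert list(tab.columns) == ["context", "up2k", "body", "down2k"]
    assert tab.set_index("context").loc["CG", "body"] == 1
    assert tab.set_index("context").loc["CHG", "up2k"] == 1
    assert tab.set_index("context").loc["CHH"].sum() == 0  # outside all zones
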