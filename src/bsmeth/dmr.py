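"""Differentially methylated region (DMR) detection between two samples.

A DMR is a cluster of cytosines of one context whose pooled methylation
differs between two samples.  Every emitted region satisfies five
criteria:

(a) at least five methylated cytosine sites in at least one sample;
(b) coverage by more than ten reads (mean per-site depth, both samples);
(c) adjacent methylated sites inside the region < 200 bp apart;
(d) region length between 40 bp and 10,000 bp (first to last site,
    inclusive);
(e) a methylation-level difference of at least two-fold with a Pearson
    chi-square test p <= 0.05 on the pooled 2x2 read-count table.

Candidate search
----------------
Candidates are maximal chains of seed cytosines in which every adjacent
gap is under the 200-bp limit.  Two seeding policies are provided.  The
default, ``differential``, seeds chains with cytosines that are methylated
in at least one sample *and* individually show a significant read-count
difference (per-site chi-square), with chains additionally split where the
direction of the per-site difference flips; in a densely methylated
context such as
plant CG (~80% of sites methylated) this is what localises regional
differences, because chains of all methylated sites would merge into
chromosome-scale runs that no length ceiling can represent.  The
literal ``all_methylated`` policy (chains of every
methylated-in-either-sample site) is available for sparse methylomes.
Either way the five criteria above are enforced on the emitted regions,
with methylated-site counts and gaps measured on the full methylated-site
sets, not just on seeds.

The two-fold "difference in methylation levels" is a ratio of pooled
region levels; zero levels are floored at 1/(pooled reads + 1) so that a
sample with no methylated reads can still be called against, without
manufacturing infinite folds.  An absolute-difference mode is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

DMR_COLUMNS = [
    "chrom", "start", "end", "context",
    "n_sites_a", "n_sites_b",
    "meth_a", "unmeth_a", "meth_b", "unmeth_b",
    "level_a", "level_b", "fold_change", "chi2", "p", "direction",
]


@dataclass
class DmrThresholds:
    min_sites: int = 5          # criterion (a)
    min_depth: float = 10.0     # criterion (b), strict: mean depth must exceed it
    max_gap: int = 200          # criterion (c), strict: gaps must be below it
    min_length: int = 40        # criterion (d)
    max_length: int = 10_000
    min_fold: float = 2.0       # criterion (e)
    alpha: float = 0.05
    seed_mode: str = "differential"   # or "all_methylated"
    seed_alpha: float = 0.01          # per-site chi-square cut for differential seeds
    effect_mode: str = "fold"         # or "absolute"
    min_abs_diff: float = 0.2
    fdr: bool = False                 # Benjamini-Hochberg across candidates


def pearson_chi2(table) -> tuple[float, float]:
    """Pearson chi-square statistic and p (df=1) for a 2x2 count table.

    Uses the closed form N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) without
    continuity correction.  A zero margin makes the test degenerate:
    statistic 0, p 1.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell in contingency table")
    margins = ((a + b), (c + d), (a + c), (b + d))
    if 0 in margins:
        return 0.0, 1.0
    n = a + b + c + d
    stat = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return float(stat), float(stats.chi2.sf(stat, df=1))


def _chi2_vec(a, b, c, d):
    """Vectorised closed-form Pearson chi-square over parallel cell arrays."""
    a, b, c, d = (x.astype(np.float64) for x in (a, b, c, d))
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, n * (a * d - b * c) ** 2 / np.where(denom > 0, denom, 1), 0.0)
    p = np.where(denom > 0, stats.chi2.sf(stat, df=1), 1.0)
    return stat, p


@dataclass
class _ContextData:
    """Aligned per-chromosome arrays for one context across two samples."""

    pos: np.ndarray
    meth_a: np.ndarray
    unmeth_a: np.ndarray
    meth_b: np.ndarray
    unmeth_b: np.ndarray
    called_a: np.ndarray
    called_b: np.ndarray


def _align_context(counts_a, counts_b, context, chrom) -> _ContextData:
    sel_a = (counts_a["chrom"] == chrom) & (counts_a["context"] == context)
    sel_b = (counts_b["chrom"] == chrom) & (counts_b["context"] == context)
    sub_a = counts_a[sel_a]
    sub_b = counts_b[sel_b]
    pa = sub_a["pos"].to_numpy()
    pb = sub_b["pos"].to_numpy()
    if pa.shape != pb.shape or not np.array_equal(np.sort(pa), np.sort(pb)):
        raise ValueError(
            f"count tables disagree on {context} sites of {chrom}; "
            "both samples must derive from the same cytosine report"
        )
    oa = np.argsort(pa, kind="stable")
    ob = np.argsort(pb, kind="stable")
    return _ContextData(
        pos=pa[oa],
        meth_a=sub_a["n_meth"].to_numpy()[oa],
        unmeth_a=sub_a["n_unmeth"].to_numpy()[oa],
        meth_b=sub_b["n_meth"].to_numpy()[ob],
        unmeth_b=sub_b["n_unmeth"].to_numpy()[ob],
        called_a=sub_a["is_methylated"].to_numpy()[oa],
        called_b=sub_b["is_methylated"].to_numpy()[ob],
    )


def seed_mask(data: _ContextData, thresholds: DmrThresholds) -> np.ndarray:
    """Which sites may seed a candidate chain."""
    union_mc = data.called_a | data.called_b
    if thresholds.seed_mode == "all_methylated":
        return union_mc
    if thresholds.seed_mode != "differential":
        raise ValueError(f"unknown seed_mode {thresholds.seed_mode!r}")
    covered = ((data.meth_a + data.unmeth_a) > 0) & ((data.meth_b + data.unmeth_b) > 0)
    _, p = _chi2_vec(data.meth_a, data.unmeth_a, data.meth_b, data.unmeth_b)
    return union_mc & covered & (p <= thresholds.seed_alpha)


def seed_signs(data: _ContextData) -> np.ndarray:
    """Sign of the per-site level difference (B minus A): +1, -1 or 0."""
    with np.errstate(invalid="ignore", divide="ignore"):
        la = data.meth_a / np.maximum(data.meth_a + data.unmeth_a, 1)
        lb = data.meth_b / np.maximum(data.meth_b + data.unmeth_b, 1)
    return np.sign(lb - la).astype(np.int8)


def build_candidate_regions(
    seed_pos: np.ndarray,
    mc_pos_a: np.ndarray,
    mc_pos_b: np.ndarray,
    thresholds: DmrThresholds,
    seed_sign: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Maximal chains of seed sites -> candidate intervals [first, last] (bp).

    Chains break wherever the gap between adjacent seeds reaches the 200-bp
    limit or (when `seed_sign` is given) the direction of the per-site
    difference flips; chains whose first-to-last span (inclusive) falls
    outside [40, 10000] bp are discarded, as are chains holding fewer than
    five methylated sites in both samples (methylated sites counted on the
    full per-sample sets within the span).
    """
    if seed_pos.size == 0:
        return []
    gaps = np.diff(seed_pos)
    break_mask = gaps >= thresholds.max_gap
    if seed_sign is not None and seed_sign.size:
        break_mask |= seed_sign[1:] != seed_sign[:-1]
    breaks = np.flatnonzero(break_mask)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [seed_pos.size - 1]])
    out = []
    for s, e in zip(starts, ends):
        first, last = int(seed_pos[s]), int(seed_pos[e])
        span = last - first + 1
        if not (thresholds.min_length <= span <= thresholds.max_length):
            continue
        na = int(np.searchsorted(mc_pos_a, last, "right") - np.searchsorted(mc_pos_a, first))
        nb = int(np.searchsorted(mc_pos_b, last, "right") - np.searchsorted(mc_pos_b, first))
        if max(na, nb) < thresholds.min_sites:
            continue
        out.append((first, last))
    return out


def region_counts(data: _ContextData, first: int, last: int) -> dict:
    """Pooled 2x2 table, levels and mean depths over [first, last] sites."""
    lo = np.searchsorted(data.pos, first)
    hi = np.searchsorted(data.pos, last, "right")
    ma = int(data.meth_a[lo:hi].sum())
    ua = int(data.unmeth_a[lo:hi].sum())
    mb = int(data.meth_b[lo:hi].sum())
    ub = int(data.unmeth_b[lo:hi].sum())
    cov_a = int(((data.meth_a[lo:hi] + data.unmeth_a[lo:hi]) > 0).sum())
    cov_b = int(((data.meth_b[lo:hi] + data.unmeth_b[lo:hi]) > 0).sum())
    return {
        "meth_a": ma, "unmeth_a": ua, "meth_b": mb, "unmeth_b": ub,
        "covered_sites_a": cov_a, "covered_sites_b": cov_b,
        "level_a": ma / (ma + ua) if (ma + ua) else np.nan,
        "level_b": mb / (mb + ub) if (mb + ub) else np.nan,
        "depth_a": (ma + ua) / cov_a if cov_a else 0.0,
        "depth_b": (mb + ub) / cov_b if cov_b else 0.0,
        "n_sites_a": int(data.called_a[lo:hi].sum()),
        "n_sites_b": int(data.called_b[lo:hi].sum()),
    }


def fold_change(level_a: float, reads_a: int, level_b: float, reads_b: int) -> float:
    """Ratio of pooled levels with a pseudo-floor on zero levels."""
    fa = max(level_a, 1.0 / (reads_a + 1))
    fb = max(level_b, 1.0 / (reads_b + 1))
    return max(fa, fb) / min(fa, fb)


def classify_hyper_hypo(level_a: float, level_b: float) -> str:
    """Direction of the second-listed sample relative to the first."""
    return "hyper" if level_b > level_a else "hypo"


def call_dmrs(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    context: str,
    thresholds: DmrThresholds | None = None,
) -> pd.DataFrame:
    """Call DMRs of one context between two samples (comparison "B:A").

    Both count tables must derive from the same cytosine report.  Returns
    a frame sorted by coordinate; `direction` is hyper when sample B's
    pooled level exceeds sample A's.
    """
    th = thresholds or DmrThresholds()
    if context not in set(counts_a["context"]).union(counts_b["context"]):
        raise ValueError(f"context {context!r} absent from count tables")
    chroms = list(dict.fromkeys(counts_a["chrom"]))
    rows = []
    for chrom in chroms:
        data = _align_context(counts_a, counts_b, context, chrom)
        if data.pos.size == 0:
            continue
        smask = seed_mask(data, th)
        seeds = data.pos[smask]
        signs = seed_signs(data)[smask] if th.seed_mode == "differential" else None
        mc_a = data.pos[data.called_a]
        mc_b = data.pos[data.called_b]
        for first, last in build_candidate_regions(seeds, mc_a, mc_b, th, signs):
            rc = region_counts(data, first, last)
            if rc["covered_sites_a"] == 0 or rc["covered_sites_b"] == 0:
                log.debug("dropped %s:%d-%d: a sample has no covered sites", chrom, first, last)
                continue
            if not (rc["depth_a"] > th.min_depth and rc["depth_b"] > th.min_depth):
                continue
            reads_a = rc["meth_a"] + rc["unmeth_a"]
            reads_b = rc["meth_b"] + rc["unmeth_b"]
            if th.effect_mode == "fold":
                fc = fold_change(rc["level_a"], reads_a, rc["level_b"], reads_b)
                if fc < th.min_fold:
                    continue
            else:
                fc = fold_change(rc["level_a"], reads_a, rc["level_b"], reads_b)
                if abs(rc["level_a"] - rc["level_b"]) < th.min_abs_diff:
                    continue
            chi2, p = pearson_chi2(
                [[rc["meth_a"], rc["unmeth_a"]], [rc["meth_b"], rc["unmeth_b"]]]
            )
            if p > th.alpha:
                continue
            rows.append(
                {
                    "chrom": chrom,
                    "start": first,
                    "end": last + 1,  # half-open
                    "context": context,
                    "n_sites_a": rc["n_sites_a"],
                    "n_sites_b": rc["n_sites_b"],
                    "meth_a": rc["meth_a"],
                    "unmeth_a": rc["unmeth_a"],
                    "meth_b": rc["meth_b"],
                    "unmeth_b": rc["unmeth_b"],
                    "level_a": rc["level_a"],
                    "level_b": rc["level_b"],
                    "fold_change": fc,
                    "chi2": chi2,
                    "p": p,
                    "direction": classify_hyper_hypo(rc["level_a"], rc["level_b"]),
                }
            )
    dmrs = pd.DataFrame(rows, columns=DMR_COLUMNS)
    if th.fdr and len(dmrs):
        dmrs = dmrs[_bh_reject(dmrs["p"].to_numpy(), th.alpha)].reset_index(drop=True)
    return dmrs


def _bh_reject(p: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg rejection mask."""
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = alpha * (np.arange(1, m + 1) / m)
    passed = np.flatnonzero(p[order] <= thresh)
    keep = np.zeros(m, dtype=bool)
    if passed.size:
        keep[order[: passed[-1] + 1]] = True
    return keep


def concat_dmrs(frames) -> pd.DataFrame:
    """Concatenate per-context DMR frames, tolerating empty ones."""
    nonempty = [f for f in frames if len(f)]
    if not nonempty:
        return pd.DataFrame(columns=DMR_COLUMNS)
    return pd.concat(nonempty, ignore_index=True)


def audit_dmrs(
    dmrs: pd.DataFrame,
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    thresholds: DmrThresholds | None = None,
) -> pd.DataFrame:
    """Re-verify the five criteria on every emitted DMR from raw counts.

    Returns one row per (DMR, criterion) that fails; empty means all pass.
    Checks are computed directly from the count tables, independent of the
    caller's internal state.
    """
    th = thresholds or DmrThresholds()
    failures = []
    for i, d in dmrs.iterrows():
        data = _align_context(counts_a, counts_b, d["context"], d["chrom"])
        first, last = int(d["start"]), int(d["end"]) - 1
        rc = region_counts(data, first, last)

        if max(rc["n_sites_a"], rc["n_sites_b"]) < th.min_sites:
            failures.append((i, "a", "fewer than five methylated sites in both samples"))
        if not (rc["depth_a"] > th.min_depth and rc["depth_b"] > th.min_depth):
            failures.append((i, "b", "mean per-site depth not above ten reads"))
        lo = np.searchsorted(data.pos, first)
        hi = np.searchsorted(data.pos, last, "right")
        union = data.pos[lo:hi][(data.called_a | data.called_b)[lo:hi]]
        if union.size and np.any(np.diff(union) >= th.max_gap):
            failures.append((i, "c", "adjacent methylated sites >= 200 bp apart"))
        span = last - first + 1
        if not (th.min_length <= span <= th.max_length):
            failures.append((i, "d", f"span {span} outside [40, 10000]"))
        fc = fold_change(
            rc["level_a"], rc["meth_a"] + rc["unmeth_a"],
            rc["level_b"], rc["meth_b"] + rc["unmeth_b"],
        )
        _, p = pearson_chi2([[rc["meth_a"], rc["unmeth_a"]], [rc["meth_b"], rc["unmeth_b"]]])
        if th.effect_mode == "fold" and fc < th.min_fold:
            failures.append((i, "e", "pooled fold change below two"))
        if p > th.alpha:
            failures.append((i, "e", "chi-square p above 0.05"))
    return pd.DataFrame(failures, columns=["dmr", "criterion", "reason"])


# ---------------------------------------------------------------------------
# Feature association

ZONE_PRIORITY = {"body": 0, "up2k": 1, "down2k": 2}


def _feature_zones(feature, flank: int):
    s, e, strand = feature.start, feature.end, feature.strand
    if strand == "+":
        return {
            "up2k": (max(0, s - flank), s),
            "body": (s, e),
            "down2k": (e, e + flank),
        }
    return {
        "up2k": (e, e + flank),
        "body": (s, e),
        "down2k": (max(0, s - flank), s),
    }


def associate_dmrs(
    dmrs: pd.DataFrame,
    features: pd.DataFrame,
    flank: int = 2000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign DMRs to the up2k / body / down2k zones of stranded features.

    Returns (overlaps, dmrs_annotated): `overlaps` has one row per
    (dmr, feature, zone) sharing at least 1 bp; `dmrs_annotated` adds the
    single highest-priority association (body > up2k > down2k; ties broken
    by feature order) plus 'none' for DMRs overlapping nothing.
    """
    overlap_rows = []
    for feature in features.itertuples():
        zones = _feature_zones(feature, flank)
        sel = dmrs["chrom"] == feature.chrom
        for zone, (zs, ze) in zones.items():
            if ze <= zs:
                continue
            hit = sel & (dmrs["start"] < ze) & (dmrs["end"] > zs)
            for i in dmrs.index[hit]:
                overlap_rows.append((i, feature.name, zone))
    overlaps = pd.DataFrame(overlap_rows, columns=["dmr", "feature_id", "zone"])

    annotated = dmrs.copy()
    annotated["assoc_zone"] = "none"
    annotated["assoc_feature"] = ""
    if len(overlaps):
        best = (
            overlaps.assign(prio=overlaps["zone"].map(ZONE_PRIORITY))
            .sort_values(["dmr", "prio"], kind="stable")
            .groupby("dmr", sort=False)
            .first()
        )
        annotated.loc[best.index, "assoc_zone"] = best["zone"]
        annotated.loc[best.index, "assoc_feature"] = best["feature_id"]
    return overlaps, annotated


def zone_count_table(annotated: pd.DataFrame) -> pd.DataFrame:
    """Context x zone DMR counts (each DMR once, in its best zone)."""
    sub = annotated[annotated["assoc_zone"] != "none"]
    tab = (
        sub.groupby(["context", "assoc_zone"]).size().unstack(fill_value=0)
        .reindex(index=["CG", "CHG", "CHH"], columns=["up2k", "body", "down2k"], fill_value=0)
    )
    tab.index.name = "context"
    return tab.reset_index()
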