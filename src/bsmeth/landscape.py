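"""Genome-scale methylome summaries.

Covers the descriptive layer of a WGBS study: per-context methylated-site
fractions, site-level histograms of methylated cytosines, base composition
of the 9-bp neighbourhood of methylated vs unmethylated cytosines, and
metagene profiles (2-kb flanks in fixed 100-bp bins, gene/TE body rescaled
to a fixed number of proportional bins), optionally stratified by gene
expression class.

Metagene geometry notes
-----------------------
Flank bins are exact 100-bp windows oriented 5'->3' relative to the
feature, so flipping a feature's strand maps upstream bin b to downstream
bin (n-1-b) exactly.  Body bins distribute each 1-bp site across the
proportional bins it overlaps using integer overlap weights (site interval
scaled by the bin count), which makes the strand-flip symmetry exact in
integer arithmetic rather than approximate at bin-edge ties; per-bin sums
use exactly-rounded summation so mirrored profiles are bit-identical.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ZONES = ("upstream", "body", "downstream")

# RPKM class partition of [0, inf): none <= 1 < low <= 10 < medium < 100 <= high.
EXPRESSION_CLASSES = {
    "none": (0.0, 1.0),
    "low": (1.0, 10.0),
    "medium": (10.0, 100.0),
    "high": (100.0, math.inf),
}


def expression_class(rpkm: float) -> str:
    if rpkm <= 1:
        return "none"
    if rpkm <= 10:
        return "low"
    if rpkm < 100:
        return "medium"
    return "high"


def global_fractions(counts: pd.DataFrame) -> pd.DataFrame:
    """Methylated-site fractions per context and overall.

    The primary fraction uses covered sites of the context as denominator
    (the "mC among covered C" convention); the all-sites denominator is
    reported alongside.  NA-context sites are excluded throughout.
    """
    rows = []
    informative = counts[counts["context"] != "NA"]
    for ctx in ("CG", "CHG", "CHH", "all"):
        sub = informative if ctx == "all" else informative[informative["context"] == ctx]
        n_sites = len(sub)
        cov = (sub["n_meth"] + sub["n_unmeth"]) > 0
        n_cov = int(cov.sum())
        n_mc = int(sub["is_methylated"].sum())
        rows.append(
            {
                "context": ctx,
                "n_sites": n_sites,
                "n_covered": n_cov,
                "n_methylated": n_mc,
                "fraction_covered": n_mc / n_cov if n_cov else np.nan,
                "fraction_all": n_mc / n_sites if n_sites else np.nan,
            }
        )
    return pd.DataFrame(rows)


def level_histogram(counts: pd.DataFrame, context: str, n_bins: int = 10) -> pd.DataFrame:
    """Histogram of site methylation levels over methylated sites only.

    Bins are right-closed over (0, 1]; a called site always has level > 0.
    Proportions sum to 1 whenever any methylated site exists.
    """
    sub = counts[(counts["context"] == context) & counts["is_methylated"]]
    levels = sub["level"].to_numpy()
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.digitize(levels, edges, right=True) - 1
    idx = np.clip(idx, 0, n_bins - 1)
    hist = np.bincount(idx, minlength=n_bins)
    total = hist.sum()
    return pd.DataFrame(
        {
            "context": context,
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "n": hist,
            "proportion": hist / total if total else np.nan,
        }
    )


def neighborhood_composition(
    sites: pd.DataFrame, counts: pd.DataFrame, window: int = 9
) -> pd.DataFrame:
    """Per-position base frequencies around methylated vs unmethylated Cs.

    For each context, covered sites are split by methylation call and the
    ACGT frequency at each of the `window` neighbourhood offsets is
    tabulated (N bases are dropped from the denominator).  Offsets run
    -(window//2) .. +(window//2) with the cytosine at 0.
    """
    half = window // 2
    merged = counts.copy()
    merged["neighborhood"] = sites["neighborhood"].to_numpy()
    covered = merged[(merged["n_meth"] + merged["n_unmeth"]) > 0]
    rows = []
    for ctx in ("CG", "CHG", "CHH"):
        for status, flag in (("mC", True), ("C", False)):
            sub = covered[(covered["context"] == ctx) & (covered["is_methylated"] == flag)]
            if not len(sub):
                continue
            mat = np.frombuffer(
                "".join(sub["neighborhood"]).encode("ascii"), dtype=np.uint8
            ).reshape(-1, window)
            for off in range(window):
                col = mat[:, off]
                denom = 0
                freqs = {}
                for base, code in (("A", 65), ("C", 67), ("G", 71), ("T", 84)):
                    c = int((col == code).sum())
                    freqs[base] = c
                    denom += c
                for base in "ACGT":
                    rows.append(
                        {
                            "context": ctx,
                            "status": status,
                            "offset": off - half,
                            "base": base,
                            "frequency": freqs[base] / denom if denom else np.nan,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Metagene machinery


@dataclass
class MetageneConfig:
    flank: int = 2000
    bin_size: int = 100
    body_bins: int = 20

    def __post_init__(self):
        if self.flank % self.bin_size:
            raise ValueError("flank must be divisible by bin_size")

    @property
    def flank_bins(self) -> int:
        return self.flank // self.bin_size


def _body_bin_weights(offset: int, length: int, n_bins: int):
    """Integer overlap of site interval [offset, offset+1) with each body bin.

    Scaled by n_bins so everything stays integral: the site covers
    [offset*n_bins, offset*n_bins + n_bins), bin k covers
    [k*length, (k+1)*length).  Yields (bin, weight) with weights summing to
    n_bins.
    """
    a = offset * n_bins
    b = a + n_bins
    k0 = a // length
    k1 = (b - 1) // length
    for k in range(k0, min(k1, n_bins - 1) + 1):
        lo = max(a, k * length)
        hi = min(b, (k + 1) * length)
        if hi > lo:
            yield k, hi - lo


def _collect_feature_terms(feature, pos, level, cfg: MetageneConfig, terms):
    """Append (weight, level) observations of one feature into `terms`.

    terms is a dict keyed by (zone, bin) holding [weights list, w*level list].
    pos/level are the covered-site arrays of the feature's chromosome,
    sorted by position.
    """
    start, end, strand = feature.start, feature.end, feature.strand
    length = end - start
    fb = cfg.flank_bins

    def add(zone, b, w, lv):
        key = (zone, b)
        if key not in terms:
            terms[key] = ([], [])
        terms[key][0].append(w)
        terms[key][1].append(w * lv)

    # Flanks: fixed windows, bin index oriented 5'->3'.
    lo = np.searchsorted(pos, start - cfg.flank)
    hi = np.searchsorted(pos, start)
    for p, lv in zip(pos[lo:hi], level[lo:hi]):
        d = int(p) - (start - cfg.flank)
        b = d // cfg.bin_size
        if strand == "+":
            add("upstream", b, cfg.body_bins, lv)
        else:
            add("downstream", fb - 1 - b, cfg.body_bins, lv)

    lo = np.searchsorted(pos, end)
    hi = np.searchsorted(pos, end + cfg.flank)
    for p, lv in zip(pos[lo:hi], level[lo:hi]):
        d = int(p) - end
        b = d // cfg.bin_size
        if strand == "+":
            add("downstream", b, cfg.body_bins, lv)
        else:
            add("upstream", fb - 1 - b, cfg.body_bins, lv)

    lo = np.searchsorted(pos, start)
    hi = np.searchsorted(pos, end)
    for p, lv in zip(pos[lo:hi], level[lo:hi]):
        o = int(p) - start
        if strand == "-":
            o = length - 1 - o
        for k, w in _body_bin_weights(o, length, cfg.body_bins):
            add("body", k, w, lv)


def metagene_profile(
    counts: pd.DataFrame,
    features: pd.DataFrame,
    config: MetageneConfig | None = None,
    contexts=("CG", "CHG", "CHH"),
) -> pd.DataFrame:
    """Average methylation level in positional bins across aligned features.

    Sites are pooled across features (site-weighted averaging); per-bin
    site weights are reported so zone means can be reconstituted exactly.
    Empty bins carry NaN means and zero weight rather than zeroes.
    """
    cfg = config or MetageneConfig()
    covered = counts[(counts["n_meth"] + counts["n_unmeth"]) > 0]
    out_frames = []
    for ctx in contexts:
        sub = covered[covered["context"] == ctx]
        by_chrom = {}
        for chrom, csub in sub.groupby("chrom", sort=False):
            p = csub["pos"].to_numpy()
            order = np.argsort(p)
            by_chrom[chrom] = (p[order], csub["level"].to_numpy()[order])
        terms: dict = {}
        for feature in features.itertuples():
            if feature.chrom not in by_chrom:
                continue
            pos, level = by_chrom[feature.chrom]
            _collect_feature_terms(feature, pos, level, cfg, terms)
        rows = []
        nb = {"upstream": cfg.flank_bins, "body": cfg.body_bins, "downstream": cfg.flank_bins}
        for zone in ZONES:
            for b in range(nb[zone]):
                ws, wls = terms.get((zone, b), ([], []))
                wsum = math.fsum(ws)
                rows.append(
                    {
                        "context": ctx,
                        "zone": zone,
                        "bin": b,
                        "mean_level": (math.fsum(wls) / wsum) if ws else np.nan,
                        "n_sites": wsum / cfg.body_bins,
                    }
                )
        out_frames.append(pd.DataFrame(rows))
    return pd.concat(out_frames, ignore_index=True)


def expression_stratified_profiles(
    counts: pd.DataFrame,
    features: pd.DataFrame,
    expression: pd.DataFrame,
    config: MetageneConfig | None = None,
    contexts=("CG", "CHG", "CHH"),
) -> pd.DataFrame:
    """Metagene profiles per expression class (none/low/medium/high RPKM).

    Genes absent from the expression table are dropped (count logged);
    raises if nothing matches.
    """
    expr = expression.set_index("gene_id")["rpkm"]
    matched = features[features["name"].isin(expr.index)]
    n_drop = len(features) - len(matched)
    if not len(matched):
        raise ValueError("no gene ids shared between features and expression table")
    if n_drop:
        log.info("expression stratification: dropped %d unmatched genes", n_drop)
    classes = matched["name"].map(lambda g: expression_class(float(expr[g])))
    frames = []
    for label in EXPRESSION_CLASSES:
        feats = matched[classes == label]
        if not len(feats):
            continue
        prof = metagene_profile(counts, feats, config, contexts)
        prof.insert(0, "expression_class", label)
        prof["n_genes"] = len(feats)
        frames.append(prof)
    return pd.concat(frames, ignore_index=True)
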