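"""Cross-referencing DMRs with differential expression and 24-nt siRNA loci.

CHH methylation is laid down by the RNA-directed DNA methylation pathway,
guided by 24-nt siRNAs, so a methylome study routinely asks (i) which
DMR-associated genes are differentially expressed, and (ii) how 24-nt
siRNA loci distribute over gene/TE bodies and flanks and over hyper- vs
hypomethylated regions.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .landscape import MetageneConfig

DEG_LOG2FC = 1.0
DEG_FDR = 0.05


def deg_status(log2fc, fdr, log2fc_cut: float = DEG_LOG2FC, fdr_cut: float = DEG_FDR):
    """'up' / 'down' / 'ns' from log2 fold change and FDR thresholds."""
    log2fc = np.asarray(log2fc, dtype=float)
    fdr = np.asarray(fdr, dtype=float)
    out = np.full(log2fc.shape, "ns", dtype=object)
    out[(log2fc > log2fc_cut) & (fdr < fdr_cut)] = "up"
    out[(log2fc < -log2fc_cut) & (fdr < fdr_cut)] = "down"
    return out


def load_deg_table(expression: pd.DataFrame) -> pd.DataFrame:
    """Attach DEG status to an expression table (gene_id, log2fc, fdr)."""
    out = expression.copy()
    out["gene_id"] = out["gene_id"].astype(str).str.strip()
    out["status"] = deg_status(out["log2fc"], out["fdr"])
    return out


def dmr_deg_intersection(
    overlaps: pd.DataFrame,
    dmrs: pd.DataFrame,
    deg: pd.DataFrame,
    contexts=("CG", "CHG", "CHH"),
) -> tuple[pd.DataFrame, dict]:
    """DMR-related genes intersected with DEGs, per context.

    overlaps: (dmr, feature_id, zone) rows from `associate_dmrs`;
    deg: table with gene_id and status.  Gene ids match as exact strings
    after whitespace normalisation.  Returns a per-context summary frame
    and a dict of cross-context overlap (Venn-style) counts of DMR-related
    DEGs.

    Raises when the id universes are disjoint.
    """
    deg = deg.copy()
    deg["gene_id"] = deg["gene_id"].astype(str).str.strip()
    deg_ids = set(deg["gene_id"])
    dmr_genes_all = set(overlaps["feature_id"].astype(str).str.strip())
    if dmr_genes_all and deg_ids.isdisjoint(dmr_genes_all):
        raise ValueError("no gene ids shared between DMR associations and DEG table")
    status = deg.set_index("gene_id")["status"]

    per_ctx_deg_genes = {}
    rows = []
    ctx_of = dmrs["context"]
    for ctx in contexts:
        dmr_ids = dmrs.index[ctx_of == ctx]
        genes = set(
            overlaps.loc[overlaps["dmr"].isin(dmr_ids), "feature_id"].astype(str).str.strip()
        )
        known = {g for g in genes if g in status.index}
        up = {g for g in known if status[g] == "up"}
        down = {g for g in known if status[g] == "down"}
        per_ctx_deg_genes[ctx] = up | down
        rows.append(
            {
                "context": ctx,
                "n_dmr_genes": len(genes),
                "n_deg": len(up) + len(down),
                "n_up": len(up),
                "n_down": len(down),
            }
        )
    venn = {}
    for r in range(1, len(contexts) + 1):
        for combo in itertools.combinations(contexts, r):
            inter = set.intersection(*(per_ctx_deg_genes[c] for c in combo))
            outside = set.union(
                set(), *(per_ctx_deg_genes[c] for c in contexts if c not in combo)
            )
            venn["&".join(combo)] = len(inter - outside)
    return pd.DataFrame(rows), venn


def sirna_positional_abundance(
    sirna: pd.DataFrame,
    features: pd.DataFrame,
    config: MetageneConfig | None = None,
    length: int | None = 24,
) -> pd.DataFrame:
    """Binned 24-nt siRNA locus counts over up2k / body / down2k zones.

    Loci are first filtered to the requested length class (None disables),
    then assigned by midpoint to the metagene bin geometry.  A locus is
    counted once per feature zone its midpoint falls in.
    """
    cfg = config or MetageneConfig()
    loci = sirna
    if length is not None:
        loci = sirna[(sirna["end"] - sirna["start"]) == length]
    mid = ((loci["start"] + loci["end"]) // 2).to_numpy()
    chroms = loci["chrom"].to_numpy()

    fb, bb = cfg.flank_bins, cfg.body_bins
    counts = {("upstream", b): 0 for b in range(fb)}
    counts.update({("body", b): 0 for b in range(bb)})
    counts.update({("downstream", b): 0 for b in range(fb)})

    for feature in features.itertuples():
        on = chroms == feature.chrom
        m = mid[on]
        s, e, strand = feature.start, feature.end, feature.strand
        length_f = e - s
        for p in m:
            p = int(p)
            if s - cfg.flank <= p < s:
                b = (p - (s - cfg.flank)) // cfg.bin_size
                zone = ("upstream", b) if strand == "+" else ("downstream", fb - 1 - b)
            elif e <= p < e + cfg.flank:
                b = (p - e) // cfg.bin_size
                zone = ("downstream", b) if strand == "+" else ("upstream", fb - 1 - b)
            elif s <= p < e:
                o = p - s if strand == "+" else e - 1 - p
                zone = ("body", min(bb - 1, bb * o // length_f))
            else:
                continue
            counts[zone] += 1
    rows = [
        {"zone": z, "bin": b, "n_loci": n}
        for (z, b), n in counts.items()
    ]
    return pd.DataFrame(rows)


def sirna_dmr_overlap(
    sirna: pd.DataFrame,
    dmrs: pd.DataFrame,
    length: int | None = 24,
) -> pd.DataFrame:
    """Count (locus, DMR) overlap pairs per direction x context.

    A locus counts once per DMR it overlaps (>= 1 bp), so the cell total
    equals the number of overlapping pairs.
    """
    loci = sirna
    if length is not None:
        loci = sirna[(sirna["end"] - sirna["start"]) == length]
    cells = {
        (d, c): 0 for d in ("hyper", "hypo") for c in ("CG", "CHG", "CHH")
    }
    for d in dmrs.itertuples():
        hit = (
            (loci["chrom"] == d.chrom)
            & (loci["start"] < d.end)
            & (loci["end"] > d.start)
        )
        key = (d.direction, d.context)
        if key in cells:
            cells[key] += int(hit.sum())
    rows = [
        {"direction": k[0], "context": k[1], "n_loci": v} for k, v in cells.items()
    ]
    return pd.DataFrame(rows)
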