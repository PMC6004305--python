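"""Synthetic bisulfite-sequencing data with known ground truth.

The generator emulates the statistical structure of a plant WGBS study of
an allotetraploid crop genome: per-context methylated-site fractions near
the genome-wide values observed in cotton shoot apices (mCG/CG ~ 0.81,
mCHG/CHG ~ 0.64, mCHH/CHH ~ 0.05), site-level distributions that are
bimodal-high for CG/CHG (most methylated sites above 90%) and broad-low
for CHH (mostly 10-40%), ~27x sequencing depth, bisulfite
conversion-failure noise, and stage-specific spiked DMRs with known
coordinates and fold effects.  It emits a toy genome with gene/TE
annotations, per-stage true methylomes, count tables, optionally
pre-aligned 125-bp paired-end reads (SAM), an expression table with DEG
flags, 24-nt siRNA loci, and a machine-readable truth set for recovery
testing.

What it does NOT emulate: mappability gaps, M-bias along reads, PCR
duplicates, base-quality-dependent errors, or biological replication —
the study design it mirrors had none.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import genome_context, io as bio
from .meth_extract import ExtractionConfig, attach_calls

READ_LEN = 125

TE_CLASSES = ("LTR", "LINE", "SINE", "simple")


@dataclass
class SpikeConfig:
    """Stage-specific regional effects of known fold, per context."""

    n_per_context: dict = field(
        default_factory=lambda: {"CG": 20, "CHG": 15, "CHH": 10}
    )
    fold: float = 2.5
    span_range: tuple = (200, 2000)
    min_sites: int = 5  # a spike must contain this many context cytosines


@dataclass
class SimConfig:
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 120_000, "chr2": 80_000}
    )
    gc_fraction: float = 0.34
    n_genes: int = 20
    gene_length_range: tuple = (800, 3000)
    n_exons_range: tuple = (1, 4)
    gene_clearance: int = 2000
    n_tes: int = 20
    te_class_mix: dict = field(
        default_factory=lambda: {"LTR": 0.4, "LINE": 0.25, "SINE": 0.2, "simple": 0.15}
    )
    te_length_range: tuple = (200, 2500)
    samples: tuple = ("sample_a", "sample_b")
    # Genome-wide probability that a site of each context is methylated.
    p_methylated: dict = field(
        default_factory=lambda: {"CG": 0.81, "CHG": 0.64, "CHH": 0.05}
    )
    # Mixture weight of the high (>0.9) site-level component for CG/CHG.
    high_weight: dict = field(default_factory=lambda: {"CG": 0.8, "CHG": 0.7})
    depth_mean: float = 27.48
    conversion_failure_rate: float = 0.005
    sequencing_error_rate: float = 0.0
    spikes: SpikeConfig = field(default_factory=SpikeConfig)
    # Optional expression coupling: CHG body methylation of unexpressed vs
    # expressed genes (None disables).
    chg_body_levels: tuple | None = None  # e.g. (0.3, 0.05)
    expression_class_mix: dict = field(
        default_factory=lambda: {"none": 0.3, "low": 0.3, "medium": 0.25, "high": 0.15}
    )
    n_deg_up: int = 8
    n_deg_down: int = 6
    n_sirna_loci: int = 300
    sirna_24nt_fraction: float = 0.85
    seed: int = 0


@dataclass
class TruthSet:
    """Ground truth of one simulated study."""

    levels: pd.DataFrame          # sites + one true-level column per sample
    spikes: pd.DataFrame          # chrom,start,end,context,fold,direction,sample
    gene_classes: pd.DataFrame    # gene_id, expression_class, rpkm
    te_classes: pd.DataFrame      # te_id, te_class

    def to_files(self, outdir: Path, prefix: str = "truth") -> None:
        outdir = Path(outdir)
        lv = self.levels.copy()
        lv["pos"] = lv["pos"] + 1
        bio.write_tsv(lv, outdir / f"{prefix}_levels.tsv")
        meta = {
            "spikes": self.spikes.to_dict(orient="records"),
            "gene_classes": self.gene_classes.to_dict(orient="records"),
            "te_classes": self.te_classes.to_dict(orient="records"),
        }
        (outdir / f"{prefix}.json").write_text(json.dumps(meta, indent=1))


# ---------------------------------------------------------------------------
# Genome and annotation


def simulate_genome(config: SimConfig, rng: np.random.Generator):
    """Random genome plus non-overlapping stranded genes and TEs.

    Returns (seqs, genes, gene_parts, tes): genes carry >= `gene_clearance`
    bp spacing where the packing allows; TEs fill intergenic space.  Raises
    when the requested features cannot be packed.
    """
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seqs = {}
    for chrom, length in config.chrom_lengths.items():
        seqs[chrom] = "".join(
            np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)]
        )

    chroms = list(config.chrom_lengths)
    weights = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()

    occupied = {c: [] for c in chroms}

    def place(length, clearance, max_tries=500):
        for _ in range(max_tries):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            limit = config.chrom_lengths[chrom] - length
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            lo, hi = start - clearance, start + length + clearance
            if all(e <= lo or s >= hi for s, e in occupied[chrom]):
                occupied[chrom].append((start, start + length))
                return chrom, start
        return None

    genes, parts = [], []
    for i in range(config.n_genes):
        length = int(rng.integers(*config.gene_length_range))
        spot = place(length, config.gene_clearance)
        if spot is None:
            raise ValueError(
                f"could not pack gene {i}: reduce n_genes/n_tes or enlarge the genome"
            )
        chrom, start = spot
        strand = "+" if rng.random() < 0.5 else "-"
        name = f"gene{i:03d}"
        genes.append((chrom, start, start + length, name, strand, "gene"))
        n_exons = int(rng.integers(config.n_exons_range[0], config.n_exons_range[1] + 1))
        cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_exons - 2, replace=False)) \
            if n_exons > 1 else np.array([], dtype=int)
        bounds = np.concatenate([[0], cuts, [length]])
        for j in range(len(bounds) - 1):
            label = "CDS" if j % 2 == 0 else "intron"
            parts.append(
                (chrom, start + int(bounds[j]), start + int(bounds[j + 1]),
                 f"{name}_{label}{j}", strand, label)
            )

    te_labels = list(config.te_class_mix)
    te_probs = np.array([config.te_class_mix[k] for k in te_labels], dtype=float)
    te_probs /= te_probs.sum()
    tes = []
    for i in range(config.n_tes):
        length = int(rng.integers(*config.te_length_range))
        spot = place(length, 0)
        if spot is None:
            raise ValueError(f"could not pack TE {i}: reduce n_tes or enlarge the genome")
        chrom, start = spot
        strand = "+" if rng.random() < 0.5 else "-"
        klass = te_labels[rng.choice(len(te_labels), p=te_probs)]
        tes.append((chrom, start, start + length, f"te{i:03d}", strand, klass))

    cols = ["chrom", "start", "end", "name", "strand", "label"]
    genes = pd.DataFrame(genes, columns=cols).sort_values(["chrom", "start"], ignore_index=True)
    parts = pd.DataFrame(parts, columns=cols).sort_values(["chrom", "start"], ignore_index=True)
    tes = pd.DataFrame(tes, columns=cols).sort_values(["chrom", "start"], ignore_index=True)
    return seqs, genes, parts, tes


# ---------------------------------------------------------------------------
# Methylome truth


def _draw_levels(context: str, size: int, config: SimConfig, rng) -> np.ndarray:
    """Site-level distribution of methylated sites for one context."""
    if context in ("CG", "CHG"):
        w = config.high_weight[context]
        hi = rng.beta(45, 2, size=size)      # mass concentrated above 0.9
        lo = rng.beta(2, 2, size=size)       # broad minor component
        return np.where(rng.random(size) < w, hi, lo)
    # CHH: broad low levels, mostly 0.1-0.4.
    out = rng.beta(2, 6, size=size)
    redraw = out < 0.05
    while redraw.any():
        out[redraw] = rng.beta(2, 6, size=int(redraw.sum()))
        redraw = out < 0.05
    return out


def simulate_expression(genes: pd.DataFrame, config: SimConfig, rng) -> pd.DataFrame:
    """Expression table: gene_id, rpkm, log2fc, fdr (DEG flags by construction)."""
    labels = list(config.expression_class_mix)
    probs = np.array([config.expression_class_mix[k] for k in labels], dtype=float)
    probs /= probs.sum()
    klass = np.array(labels)[rng.choice(len(labels), size=len(genes), p=probs)]
    rpkm = np.empty(len(genes))
    rpkm[klass == "none"] = rng.uniform(0, 1, size=int((klass == "none").sum()))
    rpkm[klass == "low"] = rng.uniform(1.001, 10, size=int((klass == "low").sum()))
    rpkm[klass == "medium"] = rng.uniform(10.001, 99.9, size=int((klass == "medium").sum()))
    rpkm[klass == "high"] = rng.uniform(100, 1000, size=int((klass == "high").sum()))

    log2fc = rng.normal(0, 0.3, size=len(genes)).clip(-0.9, 0.9)
    fdr = rng.uniform(0.1, 1.0, size=len(genes))
    expressed = np.flatnonzero(klass != "none")
    n_deg = min(config.n_deg_up + config.n_deg_down, expressed.size)
    deg_idx = rng.choice(expressed, size=n_deg, replace=False)
    up = deg_idx[: config.n_deg_up]
    down = deg_idx[config.n_deg_up:]
    log2fc[up] = rng.uniform(1.2, 5.0, size=up.size)
    log2fc[down] = -rng.uniform(1.2, 5.0, size=down.size)
    fdr[deg_idx] = rng.uniform(1e-6, 0.01, size=deg_idx.size)
    return pd.DataFrame(
        {
            "gene_id": genes["name"],
            "expression_class": klass,
            "rpkm": rpkm,
            "log2fc": log2fc,
            "fdr": fdr,
        }
    )


def _place_spikes(sites, config: SimConfig, rng) -> pd.DataFrame:
    """Disjoint spike intervals per context, each holding enough sites."""
    chroms = list(config.chrom_lengths)
    rows = []
    pos_by = {
        (c, ctx): np.sort(
            sites.loc[(sites["chrom"] == c) & (sites["context"] == ctx), "pos"].to_numpy()
        )
        for c in chroms
        for ctx in ("CG", "CHG", "CHH")
    }
    taken = {c: [] for c in chroms}
    for ctx, n in config.spikes.n_per_context.items():
        placed = 0
        tries = 0
        while placed < n and tries < 5000:
            tries += 1
            chrom = chroms[int(rng.integers(len(chroms)))]
            span = int(rng.integers(*config.spikes.span_range))
            limit = config.chrom_lengths[chrom] - span
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            end = start + span
            if any(s < end and e > start for s, e in taken[chrom]):
                continue
            pos = pos_by[(chrom, ctx)]
            n_sites = np.searchsorted(pos, end) - np.searchsorted(pos, start)
            if n_sites < config.spikes.min_sites:
                continue
            taken[chrom].append((start, end))
            direction = "hypo" if rng.random() < 0.5 else "hyper"
            rows.append((chrom, start, end, ctx, config.spikes.fold, direction))
            placed += 1
        if placed < n:
            raise ValueError(f"could not place {n} {ctx} spikes; genome too small")
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "context", "fold", "direction"]
    )


def simulate_methylome(
    sites: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    genes: pd.DataFrame | None = None,
    expression: pd.DataFrame | None = None,
) -> TruthSet:
    """Per-sample true methylation level for every cytosine site.

    A shared base methylome is drawn (methylation status per context
    probability, then a site level from the context's distribution), so
    the two stages differ only through the spiked regions — and, when
    `chg_body_levels` is set, through the optional CHG gene-body contrast
    between unexpressed and expressed genes applied to both stages alike.

    Spikes act on the second sample ("hyper": sample A's levels divided by
    the fold so B is relatively higher; "hypo": sample B's divided), which
    realises the configured fold exactly without clipping at 1.
    """
    n = len(sites)
    ctx = sites["context"].to_numpy()
    base = np.zeros(n)
    for c, p in config.p_methylated.items():
        mask = ctx == c
        k = int(mask.sum())
        meth = rng.random(k) < p
        lv = np.zeros(k)
        lv[meth] = _draw_levels(c, int(meth.sum()), config, rng)
        base[mask] = lv

    if config.chg_body_levels is not None:
        if genes is None or expression is None:
            raise ValueError("chg_body_levels requires genes and expression")
        lv_none, lv_expr = config.chg_body_levels
        rpkm = expression.set_index("gene_id")["rpkm"]
        chrom_arr = sites["chrom"].to_numpy()
        pos_arr = sites["pos"].to_numpy()
        for g in genes.itertuples():
            target = lv_none if float(rpkm.get(g.name, 0.0)) <= 1 else lv_expr
            mask = (
                (chrom_arr == g.chrom)
                & (pos_arr >= g.start)
                & (pos_arr < g.end)
                & (ctx == "CHG")
            )
            k = int(mask.sum())
            # jitter around the target mean, clipped into (0, 1)
            base[mask] = np.clip(rng.normal(target, 0.03, size=k), 0.01, 0.99)

    levels = {s: base.copy() for s in config.samples}
    spikes = _place_spikes(sites, config, rng)
    sample_a, sample_b = config.samples[0], config.samples[1]
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    spikes["sample"] = np.where(spikes["direction"] == "hyper", sample_a, sample_b)
    for sp in spikes.itertuples():
        mask = (
            (chrom_arr == sp.chrom)
            & (pos_arr >= sp.start)
            & (pos_arr < sp.end)
            & (ctx == sp.context)
        )
        levels[sp.sample][mask] = levels[sp.sample][mask] / sp.fold

    out = sites[["chrom", "pos", "strand", "context"]].copy()
    for s in config.samples:
        out[f"level_{s}"] = levels[s]
    gene_classes = (
        expression[["gene_id", "expression_class", "rpkm"]]
        if expression is not None
        else pd.DataFrame(columns=["gene_id", "expression_class", "rpkm"])
    )
    return TruthSet(levels=out, spikes=spikes, gene_classes=gene_classes,
                    te_classes=pd.DataFrame(columns=["te_id", "te_class"]))


# ---------------------------------------------------------------------------
# Counts and reads


def simulate_counts(
    sites: pd.DataFrame,
    true_levels: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    extraction: ExtractionConfig | None = None,
) -> pd.DataFrame:
    """Direct count-table sampling: depth ~ Poisson, methylated reads ~ Binomial.

    A read reports C when the cytosine escaped conversion (methylated, or
    conversion failure) and was not mis-sequenced; a flat substitution
    error feeds the n_other channel.
    """
    n = len(sites)
    depth = rng.poisson(config.depth_mean, size=n)
    conv = config.conversion_failure_rate
    err = config.sequencing_error_rate
    q = true_levels + (1 - true_levels) * conv  # P(read base is unconverted C)
    p_c = q * (1 - err) + (1 - q) * (err / 3)
    p_other = 2 * err / 3
    n_meth = rng.binomial(depth, p_c)
    rest = depth - n_meth
    n_other = rng.binomial(rest, np.divide(
        p_other, 1 - p_c, out=np.zeros_like(p_c), where=p_c < 1)) if err > 0 else np.zeros(n, dtype=np.int64)
    counts = sites[["chrom", "pos", "strand", "context"]].copy()
    counts["n_meth"] = n_meth
    counts["n_unmeth"] = rest - n_other
    counts["n_other"] = n_other
    cfg = extraction or ExtractionConfig(conversion_failure_rate=conv)
    return attach_calls(counts, cfg)


def _sam_header(config: SimConfig) -> str:
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for chrom, length in config.chrom_lengths.items():
        lines.append(f"@SQ\tSN:{chrom}\tLN:{length}")
    lines.append("@PG\tID:bsmeth-sim\tPN:bsmeth-sim")
    return "\n".join(lines) + "\n"


def simulate_reads(
    seqs: dict[str, str],
    sites: pd.DataFrame,
    true_levels: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    sam_path,
    fastq_prefix=None,
) -> pd.DataFrame:
    """Pre-aligned directional bisulfite paired reads plus their count table.

    Fragments are dropped uniformly over each sequence at the configured
    depth; each fragment converts one genome strand (Watson or Crick with
    equal probability), drawing per-site methylation states Bernoulli(true
    level).  Mates are emitted with correct coordinates, 125M CIGARs and an
    XG strand tag, so the extractor can be exercised without an aligner.
    Insert sizes (250-400 bp) keep mates non-overlapping.

    Returns the count table implied by the same per-site draws, against
    which `extract_counts` on the emitted SAM must agree exactly when the
    sequencing error rate is zero.
    """
    comp = str.maketrans("ACGTN", "TGCAN")
    conv = config.conversion_failure_rate
    err = config.sequencing_error_rate
    bases = np.array(list("ACGT"))

    n_meth = np.zeros(len(sites), dtype=np.int64)
    n_unmeth = np.zeros(len(sites), dtype=np.int64)

    idx_by = {}
    for (chrom, strand), sub in sites.groupby(["chrom", "strand"], sort=False):
        pos = sub["pos"].to_numpy()
        order = np.argsort(pos)
        idx_by[(chrom, strand)] = (pos[order], sub.index.to_numpy()[order])

    records = []
    frag_id = 0
    for chrom, seq in seqs.items():
        length = len(seq)
        arr = np.frombuffer(seq.encode(), dtype="S1")
        n_frags = int(round(config.depth_mean * length / (2 * READ_LEN)))
        for _ in range(n_frags):
            insert = int(rng.integers(250, 401))
            if length <= insert:
                continue
            fstart = int(rng.integers(0, length - insert))
            watson = rng.random() < 0.5
            key = (chrom, "+") if watson else (chrom, "-")
            pos_arr, idx_arr = idx_by[key]
            windows = ((fstart, fstart + READ_LEN), (fstart + insert - READ_LEN, fstart + insert))
            mate_seqs = []
            for ws, we in windows:
                tmpl = arr[ws:we].astype("U1")
                lo = np.searchsorted(pos_arr, ws)
                hi = np.searchsorted(pos_arr, we)
                covered = pos_arr[lo:hi]
                cidx = idx_arr[lo:hi]
                lv = true_levels[cidx]
                unconverted = rng.random(covered.size) < (lv + (1 - lv) * conv)
                # tally against truth counts (methylation state, not conversion)
                meth_state = unconverted  # a read shows C iff unconverted
                n_meth[cidx[meth_state]] += 1
                n_unmeth[cidx[~meth_state]] += 1
                off = covered - ws
                if watson:
                    tmpl[off] = np.where(meth_state, "C", "T")
                else:
                    tmpl[off] = np.where(meth_state, "G", "A")
                # remaining cytosines on the template strand are converted too
                # (all cytosines are sites, so `covered` already handles them)
                if err > 0:
                    flip = rng.random(tmpl.size) < err
                    tmpl[flip] = bases[rng.integers(0, 4, size=int(flip.sum()))]
                mate_seqs.append("".join(tmpl))
            qname = f"frag{frag_id:08d}"
            frag_id += 1
            xg = "CT" if watson else "GA"
            qual = "I" * READ_LEN
            r1s, r2s = windows[0][0], windows[1][0]
            if watson:
                flags = (99, 147)  # read1 forward, read2 reverse
            else:
                flags = (83, 163)  # read1 reverse, read2 forward
            tlen = insert
            records.append(
                (chrom, r1s, f"{qname}\t{flags[0]}\t{chrom}\t{r1s + 1}\t42\t{READ_LEN}M\t=\t"
                 f"{r2s + 1}\t{tlen}\t{mate_seqs[0]}\t{qual}\tXG:Z:{xg}")
            )
            records.append(
                (chrom, r2s, f"{qname}\t{flags[1]}\t{chrom}\t{r2s + 1}\t42\t{READ_LEN}M\t=\t"
                 f"{r1s + 1}\t{-tlen}\t{mate_seqs[1]}\t{qual}\tXG:Z:{xg}")
            )

    order = {c: i for i, c in enumerate(config.chrom_lengths)}
    records.sort(key=lambda r: (order[r[0]], r[1]))
    with open(sam_path, "w") as fh:
        fh.write(_sam_header(config))
        for _, _, line in records:
            fh.write(line + "\n")

    if fastq_prefix is not None:
        _write_fastq(records, fastq_prefix, comp)

    counts = sites[["chrom", "pos", "strand", "context"]].copy()
    counts["n_meth"] = n_meth
    counts["n_unmeth"] = n_unmeth
    counts["n_other"] = 0
    return attach_calls(counts, ExtractionConfig(conversion_failure_rate=conv))


def _write_fastq(records, prefix, comp):
    qual = "I" * READ_LEN
    with open(f"{prefix}_1.fastq", "w") as f1, open(f"{prefix}_2.fastq", "w") as f2:
        for _, _, line in records:
            f = line.split("\t")
            qname, flag, seq = f[0], int(f[1]), f[9]
            if flag & 16:  # stored reference-forward; restore read orientation
                seq = seq.translate(comp)[::-1]
            out = f1 if flag & 64 else f2
            out.write(f"@{qname}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# siRNA loci


def simulate_sirna(
    config: SimConfig,
    rng: np.random.Generator,
    genes: pd.DataFrame,
    spikes: pd.DataFrame | None = None,
    mode: str = "random",
) -> pd.DataFrame:
    """24-nt (and minor other-length) siRNA loci.

    mode 'random': uniform over the genome.  mode 'dmr_enriched': half the
    24-nt loci land inside spiked regions, emulating RdDM attraction to
    differentially methylated sequence.
    """
    chroms = list(config.chrom_lengths)
    weights = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    rows = []
    n24 = int(round(config.n_sirna_loci * config.sirna_24nt_fraction))
    for i in range(config.n_sirna_loci):
        length = 24 if i < n24 else int(rng.choice([21, 22]))
        if (
            mode == "dmr_enriched"
            and spikes is not None
            and len(spikes)
            and length == 24
            and rng.random() < 0.5
        ):
            sp = spikes.iloc[int(rng.integers(len(spikes)))]
            limit = max(sp.start + 1, sp.end - length)
            start = int(rng.integers(sp.start, limit))
            chrom = sp.chrom
        else:
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            start = int(rng.integers(0, config.chrom_lengths[chrom] - length))
        rows.append((chrom, start, start + length, f"sirna{i:04d}", int(rng.integers(1, 50)), "+"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"]) \
        .sort_values(["chrom", "start"], ignore_index=True)


# ---------------------------------------------------------------------------
# Bundle


def simulate_bundle(
    config: SimConfig,
    outdir=None,
    with_reads: bool = False,
    extraction: ExtractionConfig | None = None,
):
    """Run the full generator; optionally write every emission to `outdir`.

    Returns a dict with seqs, sites, genes, gene_parts, tes, expression,
    truth (TruthSet), counts (per sample), sirna, and (with_reads) the SAM
    path plus the read-backed count table for the first sample.
    """
    rng = np.random.default_rng(config.seed)
    seqs, genes, parts, tes = simulate_genome(config, rng)
    sites = genome_context.enumerate_cytosines(seqs)
    expression = simulate_expression(genes, config, rng)
    truth = simulate_methylome(sites, config, rng, genes=genes, expression=expression)
    truth.te_classes = tes[["name", "label"]].rename(
        columns={"name": "te_id", "label": "te_class"}
    )
    counts = {
        s: simulate_counts(
            sites, truth.levels[f"level_{s}"].to_numpy(), config, rng, extraction
        )
        for s in config.samples
    }
    sirna = simulate_sirna(config, rng, genes, truth.spikes, mode="dmr_enriched")
    bundle = {
        "config": config,
        "seqs": seqs,
        "sites": sites,
        "genes": genes,
        "gene_parts": parts,
        "tes": tes,
        "expression": expression,
        "truth": truth,
        "counts": counts,
        "sirna": sirna,
    }
    if with_reads:
        sam_path = (Path(outdir) if outdir else Path(".")) / "reads.sam"
        first = config.samples[0]
        read_counts = simulate_reads(
            seqs, sites, truth.levels[f"level_{first}"].to_numpy(), config, rng, sam_path
        )
        bundle["sam_path"] = sam_path
        bundle["read_counts"] = read_counts

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        bio.write_fasta(seqs, outdir / "genome.fa")
        bio.write_bed(genes, outdir / "genes.bed", extra_cols=["label"])
        bio.write_bed(parts, outdir / "gene_parts.bed", extra_cols=["label"])
        bio.write_bed(tes, outdir / "tes.bed", extra_cols=["label"])
        bio.write_bed(sirna, outdir / "sirna.bed")
        bio.write_cytosine_report(sites, outdir / "cytosines.tsv")
        bio.write_tsv(expression, outdir / "expression.tsv")
        for s, df in counts.items():
            bio.write_count_table(df, outdir / f"counts_{s}.tsv")
        truth.to_files(outdir)
        (outdir / "sim_config.json").write_text(
            json.dumps(asdict(config), indent=1, default=str)
        )
    return bundle
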