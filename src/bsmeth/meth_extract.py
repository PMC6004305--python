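"""Per-cytosine methylation counts from bisulfite alignments.

Bisulfite conversion turns unmethylated C into T, so at a reference
cytosine the informative reads are those sequenced from the same bisulfite
strand: reads from the Watson-converted strand report forward-strand sites
(C = methylated, T = converted), reads from the Crick-converted strand
report reverse-strand sites as G/A in reference orientation.  The
bisulfite strand is taken from the XG tag (``CT``/``GA``, as written by
common bisulfite aligners and by the simulator) and inferred from the FLAG
orientation of a directional library when the tag is absent.

The per-site methylation level is the fraction of informative reads
retaining C, and a site is called methylated either permissively (any
methylated read) or with a one-sided binomial test against the bisulfite
conversion-failure rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class ExtractionConfig:
    min_mapq: int = 10
    skip_duplicates: bool = True
    conversion_failure_rate: float = 0.005
    alpha: float = 0.05
    call_mode: str = "binomial"  # or "any"


def site_level(n_meth: int, n_unmeth: int) -> float:
    """Methylation level = methylated / (methylated + converted) reads."""
    n = n_meth + n_unmeth
    if n == 0:
        raise ValueError("site_level undefined for an uncovered site")
    return n_meth / n


def call_methylated(
    n_meth,
    n_unmeth,
    conversion_failure_rate: float = 0.005,
    alpha: float = 0.05,
    mode: str = "binomial",
):
    """Binary methylation call(s); vectorised over array inputs.

    mode 'any': methylated iff at least one unconverted read.
    mode 'binomial': upper-tail binomial P(X >= n_meth | n, failure rate)
    <= alpha, which discounts apparent methylation explicable by
    incomplete bisulfite conversion.
    """
    if not (0 <= conversion_failure_rate < 1):
        raise ValueError("conversion_failure_rate must be in [0, 1)")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    n_meth = np.asarray(n_meth)
    n_unmeth = np.asarray(n_unmeth)
    n = n_meth + n_unmeth
    if mode == "any":
        out = n_meth >= 1
    elif mode == "binomial":
        with np.errstate(invalid="ignore"):
            tail = stats.binom.sf(n_meth - 1, n, conversion_failure_rate)
        out = (n_meth >= 1) & (tail <= alpha)
    else:
        raise ValueError(f"unknown call mode {mode!r}")
    return bool(out) if out.ndim == 0 else out


def attach_calls(counts: pd.DataFrame, config: ExtractionConfig | None = None) -> pd.DataFrame:
    """Fill level/is_methylated columns from raw counts."""
    config = config or ExtractionConfig()
    n = counts["n_meth"].to_numpy() + counts["n_unmeth"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(n > 0, counts["n_meth"].to_numpy() / np.maximum(n, 1), np.nan)
    counts = counts.copy()
    counts["level"] = level
    called = np.zeros(len(counts), dtype=bool)
    cov = n > 0
    called[cov] = call_methylated(
        counts.loc[cov, "n_meth"].to_numpy(),
        counts.loc[cov, "n_unmeth"].to_numpy(),
        config.conversion_failure_rate,
        config.alpha,
        config.call_mode,
    )
    counts["is_methylated"] = called
    return counts


def _bisulfite_strand(aln: pysam.AlignedSegment) -> str:
    """'CT' (Watson-converted) or 'GA' (Crick-converted) for one read."""
    if aln.has_tag("XG"):
        tag = aln.get_tag("XG")
        if tag in ("CT", "GA"):
            return tag
        raise ValueError(f"unrecognised XG tag {tag!r} on read {aln.query_name}")
    # Directional library: read1 keeps the template strand, read2 is its
    # complement.  A forward read1 / reverse read2 comes from Watson.
    if aln.is_paired and aln.is_read2:
        return "GA" if not aln.is_reverse else "CT"
    return "GA" if aln.is_reverse else "CT"


def _read_site_observations(aln, pos_arr, seq, quals):
    """(site positions, bases, quals) of `pos_arr` sites covered by this read."""
    start, end = aln.reference_start, aln.reference_end
    lo = np.searchsorted(pos_arr, start)
    hi = np.searchsorted(pos_arr, end)
    if lo == hi:
        return pos_arr[lo:hi], [], []
    covered = pos_arr[lo:hi]
    if aln.cigartuples is not None and len(aln.cigartuples) == 1 and aln.cigartuples[0][0] == 0:
        offsets = covered - start
        return covered, [seq[o] for o in offsets], [quals[o] for o in offsets]
    ref2q = {r: q for q, r in aln.get_aligned_pairs(matches_only=True)}
    keep, bases, qs = [], [], []
    for p in covered:
        q = ref2q.get(p)
        if q is not None:
            keep.append(p)
            bases.append(seq[q])
            qs.append(quals[q])
    return np.asarray(keep, dtype=pos_arr.dtype), bases, qs


def extract_counts(
    alignments,
    sites: pd.DataFrame,
    config: ExtractionConfig | None = None,
) -> pd.DataFrame:
    """Tally methylated/converted read bases at every cytosine site.

    Parameters
    ----------
    alignments:
        Path to a coordinate-sorted SAM/BAM whose reference names match the
        cytosine report.
    sites:
        Cytosine report frame from :func:`enumerate_cytosines`.

    Returns the count-table frame (one row per site, in site order) with
    n_meth / n_unmeth / n_other, level and the binary call.

    Overlapping mates of a proper pair are reconciled so each fragment
    contributes one observation per site; the mate with the higher base
    quality at the site wins.
    """
    config = config or ExtractionConfig()

    by_key: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for (chrom, strand), sub in sites.groupby(["chrom", "strand"], sort=False):
        pos = sub["pos"].to_numpy()
        order = np.argsort(pos)
        by_key[(chrom, strand)] = (pos[order], sub.index.to_numpy()[order])

    n_meth = np.zeros(len(sites), dtype=np.int64)
    n_unmeth = np.zeros(len(sites), dtype=np.int64)
    n_other = np.zeros(len(sites), dtype=np.int64)

    meth_base = {"CT": "C", "GA": "G"}
    unmeth_base = {"CT": "T", "GA": "A"}
    site_strand = {"CT": "+", "GA": "-"}

    def tally(chrom, bs, obs):
        key = (chrom, site_strand[bs])
        if key not in by_key:
            return
        pos_arr, idx_arr = by_key[key]
        for p, (base, _q) in obs.items():
            i = idx_arr[np.searchsorted(pos_arr, p)]
            if base == meth_base[bs]:
                n_meth[i] += 1
            elif base == unmeth_base[bs]:
                n_unmeth[i] += 1
            else:
                n_other[i] += 1

    known_chroms = set(sites["chrom"].unique())
    pending: dict[str, tuple[str, str, dict]] = {}
    last = (-1, -1)

    with pysam.AlignmentFile(str(alignments), check_sq=False) as bam:
        unmatched = [r for r in bam.references if r not in known_chroms]
        if unmatched:
            raise ValueError(
                "alignment reference names absent from cytosine report: "
                + ", ".join(unmatched)
            )
        for aln in bam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if (aln.reference_id, aln.reference_start) < last:
                raise ValueError("alignments are not coordinate-sorted")
            last = (aln.reference_id, aln.reference_start)
            if aln.mapping_quality < config.min_mapq:
                continue
            if config.skip_duplicates and aln.is_duplicate:
                continue
            chrom = aln.reference_name
            bs = _bisulfite_strand(aln)
            key = (chrom, site_strand[bs])
            if key not in by_key:
                continue
            pos_arr, _ = by_key[key]
            seq = aln.query_sequence
            quals = aln.query_qualities or [0] * len(seq)
            covered, bases, qs = _read_site_observations(aln, pos_arr, seq, quals)
            obs = {int(p): (b, q) for p, b, q in zip(covered, bases, qs)}

            if aln.query_name in pending:
                p_chrom, p_bs, p_obs = pending.pop(aln.query_name)
                if p_chrom == chrom and p_bs == bs:
                    for p, (b, q) in obs.items():
                        if p not in p_obs or q > p_obs[p][1]:
                            p_obs[p] = (b, q)
                    tally(chrom, bs, p_obs)
                    continue
                tally(p_chrom, p_bs, p_obs)

            overlap_expected = (
                aln.is_proper_pair
                and aln.next_reference_id == aln.reference_id
                and aln.reference_start <= aln.next_reference_start < (aln.reference_end or 0)
            )
            if overlap_expected:
                pending[aln.query_name] = (chrom, bs, obs)
            else:
                tally(chrom, bs, obs)
        for p_chrom, p_bs, p_obs in pending.values():
            tally(p_chrom, p_bs, p_obs)

    counts = sites[["chrom", "pos", "strand", "context"]].copy()
    counts["n_meth"] = n_meth
    counts["n_unmeth"] = n_unmeth
    counts["n_other"] = n_other
    return attach_calls(counts, config)


def coverage_summary(
    counts: pd.DataFrame,
    features: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Coverage rates and mean levels per chromosome / feature class / context.

    The methylated-site fraction is reported against both plausible
    denominators — covered sites and all sites — because summary
    percentages of the "mC / covered C" kind are ambiguous between the two.

    features, when given, is the internal feature frame with a `label`
    column carrying gene parts (CDS/intron) or TE classes.
    """
    rows = []

    def summarise(scope, name, sub):
        for ctx in ("CG", "CHG", "CHH", "all"):
            s = sub if ctx == "all" else sub[sub["context"] == ctx]
            s = s[s["context"] != "NA"]
            n_sites = len(s)
            cov = s["n_meth"] + s["n_unmeth"] > 0
            n_cov = int(cov.sum())
            n_mc = int(s["is_methylated"].sum())
            rows.append(
                {
                    "scope": scope,
                    "name": name,
                    "context": ctx,
                    "n_sites": n_sites,
                    "n_covered": n_cov,
                    "coverage_rate": n_cov / n_sites if n_sites else np.nan,
                    "mean_level": s.loc[cov, "level"].mean() if n_cov else np.nan,
                    "mc_fraction_covered": n_mc / n_cov if n_cov else np.nan,
                    "mc_fraction_all": n_mc / n_sites if n_sites else np.nan,
                }
            )

    summarise("genome", "genome", counts)
    for chrom, sub in counts.groupby("chrom", sort=False):
        summarise("chromosome", chrom, sub)

    if features is not None and len(features):
        for label, feats in features.groupby("label", sort=False):
            if not label:
                continue
            mask = np.zeros(len(counts), dtype=bool)
            for chrom, fsub in feats.groupby("chrom", sort=False):
                cmask = counts["chrom"].to_numpy() == chrom
                pos = counts["pos"].to_numpy()
                starts = fsub["start"].to_numpy()
                ends = fsub["end"].to_numpy()
                inside = np.zeros(len(counts), dtype=bool)
                for s, e in zip(starts, ends):
                    inside |= (pos >= s) & (pos < e)
                mask |= cmask & inside
            summarise("feature_class", label, counts[mask])
    return pd.DataFrame(rows)
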