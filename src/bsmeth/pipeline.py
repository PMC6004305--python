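"""Pipeline orchestration: configuration, validation, staged execution.

The pipeline runs the stages in dependency order — cytosine-context
enumeration, count extraction (or direct count-table input), landscape
summaries, DMR calling per comparison and context, and DMR/DEG/siRNA
integration — and records a machine-readable manifest (config hash, row
counts per output) so a run can be audited and reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dmr as dmr_mod
from . import genome_context, integrate, landscape, meth_extract, simulate
from . import io as bio

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run configuration; round-trips losslessly through YAML."""

    outdir: str = "bsmeth_out"
    seed: int = 0
    samples: list = field(default_factory=lambda: ["sample_a", "sample_b"])
    comparisons: list = field(default_factory=lambda: ["sample_b:sample_a"])
    contexts: list = field(default_factory=lambda: ["CG", "CHG", "CHH"])
    # input paths; when `simulate` is true the bundle is generated instead
    genome: str | None = None
    counts: dict = field(default_factory=dict)      # sample -> count table TSV
    alignments: dict = field(default_factory=dict)  # sample -> SAM/BAM
    genes: str | None = None
    tes: str | None = None
    expression: str | None = None
    sirna: str | None = None
    simulate: bool = True
    sim: dict = field(default_factory=dict)         # SimConfig overrides
    dmr: dict = field(default_factory=dict)         # DmrThresholds overrides
    extraction: dict = field(default_factory=dict)  # ExtractionConfig overrides
    flank: int = 2000
    bin_size: int = 100
    body_bins: int = 20

    def __post_init__(self):
        for comp in self.comparisons:
            a, b = _parse_comparison(comp)
            for s in (a, b):
                if s not in self.samples:
                    raise ValueError(f"comparison {comp!r} references undeclared sample {s!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    def sim_config(self) -> simulate.SimConfig:
        overrides = dict(self.sim)
        if "spikes" in overrides:
            overrides["spikes"] = simulate.SpikeConfig(**overrides["spikes"])
        cfg = simulate.SimConfig(seed=self.seed, samples=tuple(self.samples), **overrides)
        return cfg

    def dmr_thresholds(self) -> dmr_mod.DmrThresholds:
        return dmr_mod.DmrThresholds(**self.dmr)

    def extraction_config(self) -> meth_extract.ExtractionConfig:
        return meth_extract.ExtractionConfig(**self.extraction)

    def metagene_config(self) -> landscape.MetageneConfig:
        return landscape.MetageneConfig(
            flank=self.flank, bin_size=self.bin_size, body_bins=self.body_bins
        )


def _parse_comparison(comp: str) -> tuple[str, str]:
    """'B:A' lists the *second* sample first, mirroring 'stage2:stage1'
    comparison naming: hyper/hypo describe B relative to A."""
    b, a = comp.split(":")
    return a.strip(), b.strip()


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Collect every validation failure (missing files, schema, coordinates)."""
    failures = []
    if config.simulate:
        return failures

    def need(path, what):
        if path is None:
            failures.append(f"{what}: no path configured")
            return None
        if not Path(path).exists():
            failures.append(f"{what}: {path} does not exist")
            return None
        return path

    genome_path = need(config.genome, "genome FASTA")
    seqs = None
    if genome_path:
        try:
            seqs = bio.read_fasta(genome_path)
        except ValueError as exc:
            failures.append(str(exc))
    for sample in config.samples:
        if sample not in config.counts and sample not in config.alignments:
            failures.append(f"sample {sample}: neither counts nor alignments configured")
    for sample, path in config.counts.items():
        if not Path(path).exists():
            failures.append(f"counts[{sample}]: {path} does not exist")
            continue
        try:
            df = bio.read_count_table(path)
        except ValueError as exc:
            failures.append(str(exc))
            continue
        if seqs:
            for chrom, sub in df.groupby("chrom"):
                if chrom not in seqs:
                    failures.append(f"counts[{sample}]: chrom {chrom} absent from genome")
                elif sub["pos"].max() >= len(seqs[chrom]):
                    failures.append(f"counts[{sample}]: position beyond end of {chrom}")
    for what, path in (("genes", config.genes), ("tes", config.tes), ("sirna", config.sirna)):
        if path is None:
            continue
        if not Path(path).exists():
            failures.append(f"{what}: {path} does not exist")
            continue
        try:
            feats = bio.read_features(path)
        except ValueError as exc:
            failures.append(str(exc))
            continue
        if seqs:
            for i, row in feats.iterrows():
                if row["chrom"] not in seqs:
                    failures.append(f"{what}:{path} line {i + 1}: unknown chrom {row['chrom']}")
                elif row["end"] > len(seqs[row["chrom"]]):
                    failures.append(f"{what}:{path} line {i + 1}: interval beyond chromosome end")
    if config.expression and not Path(config.expression).exists():
        failures.append(f"expression: {config.expression} does not exist")
    return failures


def _row_count(path: Path) -> int:
    with open(path) as fh:
        return sum(1 for _ in fh)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "validate"
    try:
        failures = validate_inputs(config)
        if failures:
            raise ValueError("input validation failed:\n" + "\n".join(failures))

        if config.simulate:
            stage = "simulate"
            bundle = simulate.simulate_bundle(
                config.sim_config(), outdir=outdir,
                extraction=config.extraction_config(),
            )
            sites = bundle["sites"]
            counts = bundle["counts"]
            genes = bundle["genes"]
            parts = bundle["gene_parts"]
            tes = bundle["tes"]
            expression = bundle["expression"]
            sirna = bundle["sirna"]
        else:
            stage = "genome_context"
            seqs = bio.read_fasta(config.genome)
            sites = genome_context.enumerate_cytosines(seqs)
            bio.write_cytosine_report(sites, outdir / "cytosines.tsv")
            stage = "extract"
            counts = {}
            for sample in config.samples:
                if sample in config.counts:
                    counts[sample] = bio.read_count_table(config.counts[sample])
                else:
                    counts[sample] = meth_extract.extract_counts(
                        config.alignments[sample], sites, config.extraction_config()
                    )
                    bio.write_count_table(counts[sample], outdir / f"counts_{sample}.tsv")
            genes = bio.read_features(config.genes) if config.genes else None
            parts = None
            tes = bio.read_features(config.tes) if config.tes else None
            expression = bio.read_tsv(config.expression) if config.expression else None
            sirna = bio.read_features(config.sirna) if config.sirna else None
            if sirna is not None:
                sirna = sirna.rename(columns={"label": "score"})

        stage = "landscape"
        mcfg = config.metagene_config()
        for sample in config.samples:
            bio.write_tsv(
                landscape.global_fractions(counts[sample]),
                outdir / f"global_fractions_{sample}.tsv",
            )
            hists = pd.concat(
                [landscape.level_histogram(counts[sample], c) for c in config.contexts],
                ignore_index=True,
            )
            bio.write_tsv(hists, outdir / f"level_histogram_{sample}.tsv")
            feats = pd.concat([f for f in (parts, tes) if f is not None], ignore_index=True) \
                if (parts is not None or tes is not None) else None
            bio.write_tsv(
                meth_extract.coverage_summary(counts[sample], feats),
                outdir / f"coverage_summary_{sample}.tsv",
            )
            if genes is not None and len(genes):
                bio.write_tsv(
                    landscape.metagene_profile(counts[sample], genes, mcfg),
                    outdir / f"metagene_genes_{sample}.tsv",
                )
            if tes is not None and len(tes):
                bio.write_tsv(
                    landscape.metagene_profile(counts[sample], tes, mcfg),
                    outdir / f"metagene_tes_{sample}.tsv",
                )
            if genes is not None and expression is not None:
                bio.write_tsv(
                    landscape.expression_stratified_profiles(
                        counts[sample], genes, expression, mcfg
                    ),
                    outdir / f"metagene_expression_{sample}.tsv",
                )

        stage = "dmr"
        th = config.dmr_thresholds()
        all_features = pd.concat(
            [f for f in (genes, tes) if f is not None], ignore_index=True
        ) if (genes is not None or tes is not None) else None
        dmr_results = {}
        for comp in config.comparisons:
            a, b = _parse_comparison(comp)
            tag = comp.replace(":", "_vs_")
            frames = []
            for ctx in config.contexts:
                frames.append(dmr_mod.call_dmrs(counts[a], counts[b], ctx, th))
            dmrs = dmr_mod.concat_dmrs(frames)
            if all_features is not None and len(dmrs):
                overlaps, dmrs = dmr_mod.associate_dmrs(dmrs, all_features, config.flank)
                bio.write_tsv(dmr_mod.zone_count_table(dmrs), outdir / f"dmr_zones_{tag}.tsv")
            else:
                overlaps = pd.DataFrame(columns=["dmr", "feature_id", "zone"])
            out = dmrs.copy()
            bio.write_tsv(out, outdir / f"dmrs_{tag}.tsv")
            dmr_results[comp] = (dmrs, overlaps)

        stage = "integrate"
        for comp, (dmrs, overlaps) in dmr_results.items():
            tag = comp.replace(":", "_vs_")
            if expression is not None and len(overlaps):
                deg = integrate.load_deg_table(expression)
                summary, venn = integrate.dmr_deg_intersection(overlaps, dmrs, deg)
                bio.write_tsv(summary, outdir / f"dmr_deg_{tag}.tsv")
                (outdir / f"dmr_deg_venn_{tag}.json").write_text(
                    json.dumps(venn, indent=1, sort_keys=True)
                )
            if sirna is not None and len(dmrs):
                bio.write_tsv(
                    integrate.sirna_dmr_overlap(sirna, dmrs),
                    outdir / f"sirna_dmr_{tag}.tsv",
                )
        if sirna is not None and genes is not None:
            bio.write_tsv(
                integrate.sirna_positional_abundance(sirna, genes, mcfg),
                outdir / "sirna_genes.tsv",
            )
            if tes is not None:
                bio.write_tsv(
                    integrate.sirna_positional_abundance(sirna, tes, mcfg),
                    outdir / "sirna_tes.tsv",
                )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    stage = "manifest"
    cfg_dict = dataclasses.asdict(config)
    outputs = sorted(
        p.name for p in outdir.iterdir()
        if p.suffix in {".tsv", ".bed", ".fa", ".json", ".sam"} and p.name != "manifest.json"
    )
    manifest = {
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": config.seed,
        "outputs": {name: _row_count(outdir / name) for name in outputs},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    config.to_yaml(outdir / "config_used.yaml")
    return manifest
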