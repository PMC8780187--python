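"""End-to-end pipeline: simulate -> qc -> quant -> annotate -> diff (site,
gene, promoter) [-> enrich], with fixed output names and a run manifest.

All randomness flows from one global seed; each stage receives a derived
sub-seed ``(seed * 1_000_003 + stage_index) % 2**31`` so stages are
individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate as ann
from . import diffmeth as dm
from . import enrich as en
from . import io as mio
from . import readqc as qc
from . import sitequant as sq
from . import synthio
from .digestion import LibrarySpec, enumerate_recognition_sites, simulate_library
from .model import ValidationError

__version__ = "0.1.0"

#: fixed analysis output contract (simulation fixtures and manifest extra)
OUTPUT_FILES = [
    "qc_stats.tsv",
    "mapping_stats.tsv",
    "site_counts.tsv",
    "site_rpm.tsv",
    "context_summary.tsv",
    "sample_correlation.tsv",
    "feature_distribution.tsv",
    "window_profile.tsv",
    "metaprofile.tsv",
    "sites.bed",
    "diff_site.tsv",
    "diff_gene.tsv",
    "diff_promoter.tsv",
    "diff_summary.json",
]


def stage_seed(seed: int, stage: int) -> int:
    return (seed * 1_000_003 + stage) % (2**31)


@dataclass
class SampleSpec:
    sample_id: str
    condition: str
    scale: float = 1.0


@dataclass
class PipelineConfig:
    outdir: str = "methylrad_run"
    seed: int = 0
    genome: synthio.SyntheticGenomeSpec = field(default_factory=synthio.SyntheticGenomeSpec)
    n_genes: int = 120
    methylome: synthio.MethylomeSpec = field(default_factory=synthio.MethylomeSpec)
    samples: list[SampleSpec] = field(
        default_factory=lambda: [
            SampleSpec("EG1", "EG", 1.0),
            SampleSpec("EG2", "EG", 1.15),
            SampleSpec("CK1", "CK", 0.95),
            SampleSpec("CK2", "CK", 1.25),
        ]
    )
    error_rate: float = 0.0
    adapter: str = ""
    qc: qc.QCParams = field(default_factory=qc.QCParams)
    min_depth: int = 5
    max_mismatch: int = 1
    window: int = 10_000
    step: int = 5_000
    flank: int = 2000
    body_bins: int = 100
    flank_bins: int = 101
    diff: dm.DiffOptions = field(default_factory=dm.DiffOptions)
    terms_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValidationError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if dataclasses.is_dataclass(current) and isinstance(value, dict):
                setattr(cfg, key, dataclasses.replace(current, **value))
            elif key == "samples":
                setattr(cfg, key, [SampleSpec(**s) for s in value])
            else:
                setattr(cfg, key, value)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunResult:
    config: PipelineConfig
    genome: object
    annotation: object
    sites: list
    methylome: object
    truth: dict[str, dict]  # sample -> read id -> locus
    qc_stats: dict
    matrix: sq.SiteCountMatrix          # merged + reliability-filtered
    matrix_unfiltered: sq.SiteCountMatrix
    rpm: pd.DataFrame
    mapping_stats: dict
    diff_tables: dict[str, pd.DataFrame]
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_sites_tsv(matrix: sq.SiteCountMatrix, path: Path) -> None:
    df = matrix.table.reset_index()
    df["position"] = df["position"] + 1  # 1-based external coordinates
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> RunResult:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    # ---- simulate -------------------------------------------------------
    gspec = dataclasses.replace(config.genome, seed=stage_seed(seed, 1))
    genome = synthio.generate_genome(gspec)
    annotation = synthio.generate_gene_models(
        genome, config.n_genes, seed=stage_seed(seed, 2), flank=config.flank
    )
    sites = enumerate_recognition_sites(genome)
    mspec = dataclasses.replace(config.methylome, seed=stage_seed(seed, 3))
    methylome = synthio.generate_methylome(sites, mspec)
    mio.write_fasta(genome, out / "genome.fasta")
    mio.write_gff3(annotation, out / "annotation.gff3")
    mio.write_methylome_tsv(methylome, out / "methylome.tsv")

    raw: dict[str, list] = {}
    truth: dict[str, dict] = {}
    for i, s in enumerate(config.samples):
        spec = LibrarySpec(
            sample_id=s.sample_id,
            condition=s.condition,
            scale=s.scale,
            error_rate=config.error_rate,
            adapter=config.adapter,
            seed=stage_seed(seed, 10 + i),
        )
        rs = simulate_library(genome, sites, methylome, spec, dispersion=mspec.dispersion)
        raw[s.sample_id] = rs.reads
        truth[s.sample_id] = rs.truth
        mio.write_fastq(rs.reads, out / f"{s.sample_id}.fastq")

    # ---- qc -------------------------------------------------------------
    params = dataclasses.replace(config.qc, adapter=config.adapter, seed=stage_seed(seed, 20))
    clean, qstats = qc.run_qc(raw, params)
    qc.stats_table(qstats).to_csv(out / "qc_stats.tsv", sep="\t", index=False)
    for name, reads in clean.items():
        mio.write_fastq(reads, out / f"{name}.clean.fastq")

    # ---- quant ----------------------------------------------------------
    index = sq.build_site_index(sites, genome)
    matrix_raw, mstats = sq.map_tags(clean, index, max_mismatch=config.max_mismatch)
    sq.mapping_stats_table(mstats).to_csv(out / "mapping_stats.tsv", sep="\t", index=False)
    merged = sq.merge_duplicate_sites(matrix_raw)
    reliable = sq.filter_reliable_sites(merged, min_depth=config.min_depth)
    _write_sites_tsv(reliable, out / "site_counts.tsv")
    rpm = sq.rpm_normalize(reliable)
    rpm_out = rpm.reset_index()
    rpm_out["position"] = rpm_out["position"] + 1
    rpm_out.to_csv(out / "site_rpm.tsv", sep="\t", index=False)
    totals = {
        "CG": sum(1 for l in sites if l.context == "CG"),
        "CWG": sum(1 for l in sites if l.context == "CWG"),
    }
    sq.context_summary(reliable, totals).to_csv(out / "context_summary.tsv", sep="\t", index=False)
    sq.sample_correlation(rpm).to_csv(out / "sample_correlation.tsv", sep="\t")
    mio.write_bed(
        [(scaf, pos, strand) for scaf, pos, strand in reliable.table.index],
        out / "sites.bed",
    )

    # ---- annotate -------------------------------------------------------
    ann.feature_distribution(reliable, annotation).to_csv(
        out / "feature_distribution.tsv", sep="\t", index=False
    )
    ann.sliding_window_profile(
        reliable, sites, genome, window=config.window, step=config.step
    ).to_csv(out / "window_profile.tsv", sep="\t", index=False)
    profiles = ann.metaprofile(
        rpm, annotation, flank=config.flank,
        body_bins=config.body_bins, flank_bins=config.flank_bins,
    )
    ann.metaprofile_table(profiles).to_csv(out / "metaprofile.tsv", sep="\t", index=False)

    # ---- diff -----------------------------------------------------------
    design = dm.GroupDesign({s.sample_id: s.condition for s in config.samples})
    diff_tables: dict[str, pd.DataFrame] = {}
    summary: dict[str, dict] = {}
    site_diff = dm.call_differential(reliable, design, config.diff)
    diff_tables["site"] = site_diff
    summary["site"] = dm.diff_summary(site_diff)
    for context in ("CG", "CWG"):
        summary[f"site_{context}"] = dm.diff_summary(site_diff[site_diff["context"] == context])
    site_out = site_diff.reset_index()
    site_out["position"] = site_out["position"] + 1
    site_out.to_csv(out / "diff_site.tsv", sep="\t", index=False)

    for level, regions in (
        ("gene", dm.RegionSet.gene_bodies(annotation)),
        ("promoter", dm.RegionSet.promoters(annotation)),
    ):
        agg, n_empty = dm.aggregate_regions(reliable, regions)
        if len(agg.table) >= 2:
            table = dm.call_differential(agg, design, config.diff)
        else:
            table = pd.DataFrame()
        diff_tables[level] = table
        summary[level] = dm.diff_summary(table) if len(table) else {
            "n_tested": 0, "n_up": 0, "n_down": 0, "n_hyper": 0, "n_hypo": 0,
        }
        summary[level]["n_zero_site_regions"] = n_empty
        table.to_csv(out / f"diff_{level}.tsv", sep="\t")

    with open(out / "diff_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    # ---- enrich (optional) ---------------------------------------------
    if config.terms_path:
        terms = en.TermMap.from_tsv(config.terms_path)
        assoc = dm.associate_dms_to_genes(
            site_diff[site_diff["direction"] != "ns"], annotation
        )
        gene_diff = diff_tables["gene"]
        background = set(gene_diff.index.astype(str)) if len(gene_diff) else set()
        for cls_name in ("hypo", "hyper"):
            linked = set(
                assoc.loc[assoc["class"].eq(cls_name) & assoc["gene_id"].notna(), "gene_id"]
            ) & background
            table = (
                en.enrich(linked, background, terms)
                if linked
                else pd.DataFrame()
            )
            table.to_csv(out / f"enrichment_{cls_name}.tsv", sep="\t", index=False)

    # ---- manifest -------------------------------------------------------
    cfg_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    manifest = {
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "records": {
            "raw_reads": {k: len(v) for k, v in raw.items()},
            "clean_reads": {k: len(v) for k, v in clean.items()},
            "sites_enumerated": len(sites),
            "sites_reliable": int(len(reliable.table)),
        },
        "outputs": {},
    }
    for name in OUTPUT_FILES:
        path = out / name
        if path.exists():
            manifest["outputs"][name] = _sha256(path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return RunResult(
        config=config,
        genome=genome,
        annotation=annotation,
        sites=sites,
        methylome=methylome,
        truth=truth,
        qc_stats=qstats,
        matrix=reliable,
        matrix_unfiltered=merged,
        rpm=rpm,
        mapping_stats=mstats,
        diff_tables=diff_tables,
        manifest=manifest,
    )
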