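"""End-to-end orchestration from one YAML config, with a run manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, colonyquant, enrichment, metabolomics, rnaseq, synthdata
from .synthdata import (
    PlantedDE,
    PlantedFeature,
    PlantedTruth,
    SyntheticDesign,
    sample_label,
)


@dataclass
class RunConfig:
    """Validated parameters for a full pipeline run."""

    outdir: Path
    seed: int = 0
    strains: list[str] = field(default_factory=lambda: ["A", "C"])
    days: list[int] = field(default_factory=lambda: [2, 4])
    replicates: int = 3
    # rnaseq
    genome_len: int = 15_000
    n_genes: int = 10
    shared_fraction: float = 0.0
    depth: float = 120.0
    read_len: int = 80
    k: int = 21
    rrna_fraction: float = 0.05
    de_mode: str = "wald"
    # metabolomics
    n_features: int = 60
    drift_slope: float = 0.2
    missing_rate: float = 0.05
    alpha: float = 0.05
    lfc_min: float = 1.5
    glog_lambda: float | str = "auto"
    # colonies
    plate_mm: float = 90.0
    # enrichment
    min_size: int = 10
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "rnaseq", "metabolomics",
                                 "colonies", "enrich", "report"]
    )

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        if not 0 <= self.shared_fraction < 1:
            raise ValueError("shared_fraction must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if len(self.strains) < 2:
            raise ValueError("need >= 2 strains")
        unknown = set(self.stages) - {"simulate", "rnaseq", "metabolomics",
                                      "colonies", "enrich", "report"}
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw["outdir"] = Path(raw.get("outdir", "coculture_run"))
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class Manifest:
    def __init__(self, config: RunConfig):
        self.entries: dict[str, dict] = {}
        self.config = config
        self.log: list[str] = []

    def add(self, stage: str, path: Path) -> None:
        self.entries[str(path)] = {"stage": stage, "sha256": _sha256(path)}

    def write(self, path: Path) -> None:
        payload = {
            "version": __version__,
            "seed": self.config.seed,
            "parameters": {
                k: str(v) if isinstance(v, Path) else v
                for k, v in vars(self.config).items()
            },
            "outputs": self.entries,
            "log": self.log,
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def _default_truth(cfg: RunConfig) -> PlantedTruth:
    x, y = cfg.strains[0], cfg.strains[1]
    truth = PlantedTruth()
    truth.de_genes[f"{x}_g0000"] = PlantedDE(
        strain=x, partner=y, days=(min(cfg.days), max(cfg.days)), log2fc=2.0
    )
    truth.producer_features["F0000"] = PlantedFeature(
        producer=x, partner=y, log2fc=3.0, diffusible=False
    )
    truth.producer_features["F0001"] = PlantedFeature(
        producer=y, partner=None, log2fc=4.0, diffusible=True
    )
    return truth


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; return manifest dict."""
    config.validate()
    cfg = config
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(cfg)
    design = SyntheticDesign(
        strains=cfg.strains, days=cfg.days, replicates=cfg.replicates, seed=cfg.seed
    )
    truth = _default_truth(cfg)
    x, y = cfg.strains[0], cfg.strains[1]

    state: dict = {}
    for stage in ["simulate", "rnaseq", "metabolomics", "colonies", "enrich", "report"]:
        if stage not in cfg.stages:
            continue
        try:
            _STAGES[stage](cfg, design, truth, out, manifest, state, x, y)
            manifest.log.append(f"{stage}: ok")
        except Exception as e:
            manifest.log.append(f"{stage}: FAILED ({e})")
            manifest.write(out / "manifest.json")
            raise RuntimeError(f"stage {stage!r} failed: {e}") from e
    manifest.write(out / "manifest.json")
    manifest.add("manifest", out / "manifest.json")
    return {"outputs": manifest.entries, "log": manifest.log}


def _stage_simulate(cfg, design, truth, out, manifest, state, x, y):
    d = out / "inputs"
    d.mkdir(exist_ok=True)
    genomes = synthdata.gen_genomes(
        design, genome_len=cfg.genome_len, n_genes=cfg.n_genes,
        shared_fraction=cfg.shared_fraction,
    )
    genomes.write_fasta(d / "genomes.fasta", d / "rrna.fasta")
    genomes.annotation.to_csv(d / "annotation.tsv", sep="\t", index=False)
    manifest.add("simulate", d / "genomes.fasta")
    manifest.add("simulate", d / "annotation.tsv")

    rep = 1
    day = cfg.days[0]
    samples = [
        sample_label(f, p, day, rep)
        for (f, p) in [(x, y), (x, x), (y, x), (y, y)]
    ]
    libs = synthdata.gen_reads(
        genomes, truth, samples, depth=cfg.depth, read_len=cfg.read_len,
        rrna_fraction=cfg.rrna_fraction, seed=cfg.seed,
    )
    for name, reads in libs.items():
        p = d / f"{name}.fastq"
        synthdata.write_fastq(reads, p)
        manifest.add("simulate", p)

    table = synthdata.gen_peaktable(
        design, truth, n_features=cfg.n_features, drift_slope=cfg.drift_slope,
        missing_rate=cfg.missing_rate, seed=cfg.seed,
    )
    table.to_tsv(d / "peaks.tsv", d / "peak_samples.tsv")
    manifest.add("simulate", d / "peaks.tsv")
    manifest.add("simulate", d / "peak_samples.tsv")

    img, disks, _ = synthdata.gen_plate_image(
        colonies=[(230, 300, 50, 160), (370, 300, 35, 160)], seed=cfg.seed
    )
    from PIL import Image

    Image.fromarray(img).save(d / "plate_0.png")
    manifest.add("simulate", d / "plate_0.png")
    truth.colony_truth["plate_0"] = disks
    truth.to_json(d / "truth.json")
    manifest.add("simulate", d / "truth.json")

    gene2ko, ko2path = synthdata.gen_annotation(
        n_genes=cfg.n_genes * len(cfg.strains),
        n_pathways=max(1, cfg.n_genes * len(cfg.strains) // max(cfg.min_size, 1)),
        genes_per_pathway=cfg.min_size,
        seed=cfg.seed,
        gene_ids=list(genomes.annotation["gene_id"]),
    )
    gene2ko.to_csv(d / "gene2ko.tsv", sep="\t", index=False)
    ko2path.to_csv(d / "ko2path.tsv", sep="\t", index=False)
    manifest.add("simulate", d / "gene2ko.tsv")
    manifest.add("simulate", d / "ko2path.tsv")

    state.update(genomes=genomes, libs=libs, table=table, samples=samples,
                 gene2ko=gene2ko, ko2path=ko2path)


def _stage_rnaseq(cfg, design, truth, out, manifest, state, x, y):
    d = out / "rnaseq"
    d.mkdir(exist_ok=True)
    genomes = state["genomes"]
    index = rnaseq.build_index(genomes, k=cfg.k)
    # replicate libraries for the DE contrast X-Y vs X-X
    day = cfg.days[0]
    de_samples = [
        sample_label(f, p, day, r)
        for (f, p) in [(x, y), (x, x)]
        for r in range(1, cfg.replicates + 1)
    ]
    libs = synthdata.gen_reads(
        genomes, truth, de_samples, depth=cfg.depth, read_len=cfg.read_len,
        rrna_fraction=cfg.rrna_fraction, seed=cfg.seed,
    )
    las = {s: rnaseq.assign_library(r, index, library=s) for s, r in libs.items()}
    counts = rnaseq.count_genes(las, index.annotation)
    counts.to_csv(d / "raw_counts.tsv", sep="\t")
    manifest.add("rnaseq", d / "raw_counts.tsv")

    gene_counts = counts.drop(index=rnaseq.INTERGENIC)
    focal_counts = gene_counts.loc[
        index.annotation.loc[index.annotation["strain"] == x, "gene_id"]
    ]
    sf = rnaseq.size_factors(focal_counts.loc[(focal_counts != 0).any(axis=1)])
    norm = rnaseq.normalized_counts(
        focal_counts.loc[(focal_counts != 0).any(axis=1)], sf
    )
    norm.to_csv(d / "normalized_counts.tsv", sep="\t")
    manifest.add("rnaseq", d / "normalized_counts.tsv")

    tpm_tab = rnaseq.tpm(gene_counts, index.gene_lengths())
    tpm_tab.to_csv(d / "tpm.tsv", sep="\t")
    manifest.add("rnaseq", d / "tpm.tsv")

    meta = pd.DataFrame(
        {"group": [c.split("_")[0] for c in focal_counts.columns]},
        index=focal_counts.columns,
    )
    de = rnaseq.differential_expression(
        focal_counts, meta, mode="wald", levels=(f"{x}-{x}", f"{x}-{y}")
    )
    de.to_csv(d / "de.tsv", sep="\t")
    manifest.add("rnaseq", d / "de.tsv")

    summary = {
        lib: {
            "total": la.total_reads, "rrna": la.rrna,
            "per_strain": la.per_strain, "ambiguous": la.ambiguous,
            "unmapped": la.unmapped,
        }
        for lib, la in las.items()
    }
    (d / "assignment_summary.json").write_text(json.dumps(summary, indent=1))
    manifest.add("rnaseq", d / "assignment_summary.json")
    state.update(de=de, index=index)


def _stage_metabolomics(cfg, design, truth, out, manifest, state, x, y):
    d = out / "metabolomics"
    d.mkdir(exist_ok=True)
    table = state["table"]
    norm, glog_t = metabolomics.run_preprocessing(table, lam=cfg.glog_lambda)
    res = metabolomics.attribute_producers(
        glog_t, norm, x, y, alpha=cfg.alpha, lfc_min=cfg.lfc_min
    )
    res.stats.to_csv(d / f"attribution_{x}-{y}.tsv", sep="\t", index=False)
    manifest.add("metabolomics", d / f"attribution_{x}-{y}.tsv")
    sel = {
        "focal": x, "partner": y, "alpha": cfg.alpha, "lfc_min": cfg.lfc_min,
        "selected": res.selected_features,
    }
    (d / "selection.json").write_text(json.dumps(sel, indent=1))
    manifest.add("metabolomics", d / "selection.json")
    state.update(norm=norm, glog=glog_t, attribution=res)


def _stage_colonies(cfg, design, truth, out, manifest, state, x, y):
    d = out / "colonies"
    d.mkdir(exist_ok=True)
    from PIL import Image

    rows = []
    for img_path in sorted((out / "inputs").glob("plate_*.png")):
        img = np.asarray(Image.open(img_path))
        diameter_px = colonyquant.estimate_plate_diameter_px(img)
        c = colonyquant.px_to_mm_factor(diameter_px, cfg.plate_mm)
        for i, ct in enumerate(colonyquant.segment_colonies(img)):
            rows.append(
                {
                    "image_id": img_path.stem, "contour_id": i,
                    "area_px": ct.area_px,
                    "area_mm2": colonyquant.area_mm2(ct.area_px, c),
                }
            )
    tab = pd.DataFrame(rows)
    tab.to_csv(d / "colony_areas.tsv", sep="\t", index=False)
    manifest.add("colonies", d / "colony_areas.tsv")
    state.update(colony_areas=tab)


def _stage_enrich(cfg, design, truth, out, manifest, state, x, y):
    d = out / "enrichment"
    d.mkdir(exist_ok=True)
    de = state["de"]
    for direction in ("up", "down"):
        q = enrichment.de_to_query(de, direction=direction)
        res = enrichment.hypergeom_enrich(
            q, state["gene2ko"], state["ko2path"], min_size=cfg.min_size
        )
        res.table.to_csv(d / f"enrichment_{direction}.tsv", sep="\t", index=False)
        manifest.add("enrich", d / f"enrichment_{direction}.tsv")


def _stage_report(cfg, design, truth, out, manifest, state, x, y):
    d = out / "report"
    d.mkdir(exist_ok=True)
    de = state["de"]
    volcano = de.assign(significant=rnaseq.volcano_flags(de))
    volcano.to_csv(d / "volcano.tsv", sep="\t")
    manifest.add("report", d / "volcano.tsv")

    glog_t = state["glog"]
    res = state["attribution"]
    samp = glog_t.sample_meta.index[glog_t.sample_meta["role"] == "sample"]
    feats = res.selected_features or list(glog_t.features[:5])
    Z, _flags = metabolomics.row_zscore(glog_t.intensities.loc[feats, list(samp)])
    Z.to_csv(d / "heatmap_rows.tsv", sep="\t")
    manifest.add("report", d / "heatmap_rows.tsv")

    if "colony_areas" in state and len(state["colony_areas"]):
        state["colony_areas"].to_csv(d / "boxplot_data.tsv", sep="\t", index=False)
        manifest.add("report", d / "boxplot_data.tsv")

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ok = volcano.dropna(subset=["pvalue"])
    ax.scatter(ok["log2FoldChange"], -np.log10(ok["pvalue"]),
               c=np.where(ok["significant"], "crimson", "grey"), s=12)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    fig.savefig(d / "volcano.png", dpi=120, bbox_inches="tight")
    plt.close(fig)
    manifest.add("report", d / "volcano.png")

    fig, ax = plt.subplots(figsize=(5, 3))
    ax.imshow(Z.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-2, vmax=2)
    ax.set_yticks(range(len(Z.index)), Z.index, fontsize=6)
    ax.set_xticks([])
    fig.savefig(d / "heatmap.png", dpi=120, bbox_inches="tight")
    plt.close(fig)
    manifest.add("report", d / "heatmap.png")


_STAGES = {
    "simulate": _stage_simulate,
    "rnaseq": _stage_rnaseq,
    "metabolomics": _stage_metabolomics,
    "colonies": _stage_colonies,
    "enrich": _stage_enrich,
    "report": _stage_report,
}
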