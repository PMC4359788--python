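"""End-to-end orchestration: simulate -> profile -> classify -> SNP filters
and spectrum -> phylogeny -> chromosome signature -> GO enrichment.

A single TOML config drives every stage; all thresholds default to the
published procedure (0.25x/0.90 and 0.75x/0.40 SNP filters, 5 bp proximity,
1.3/2.7 class boundaries, the >0.95 CNV rule, 100 bootstraps, Fisher
p < 0.01), so a bare config reproduces it.  Every stage records its inputs,
outputs, seed and runtime in a manifest with SHA-256 checksums, making
reruns verifiable: the same seed yields byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import depth_profiling, go_enrichment, ploidy, snp_filters, synthetic_data
from .cnv_phylogeny import bootstrap_consensus
from .io_formats import write_gene_table, write_go_table, write_matrix, write_newick, write_variants
from .ploidy import ClassificationThresholds
from .snp_filters import SnpFilterConfig, substitution_spectrum
from .synthetic_data import SimulationConfig

log = logging.getLogger(__name__)

DEMO_SAMPLES = ("C_griseus", "CHO-K1_ATCC", "CHO_DXB11", "F435")


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    n_bootstrap: int = 100
    samples: tuple[str, ...] = DEMO_SAMPLES
    reference_sample: str = "C_griseus"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: ClassificationThresholds = field(default_factory=ClassificationThresholds)
    snp_filter: SnpFilterConfig = field(default_factory=SnpFilterConfig)
    go_p_cutoff: float = 0.01
    input_files: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as handle:
            raw = tomllib.load(handle)
        pipeline = raw.get("pipeline", {})
        seed = pipeline.get("seed", 0)
        sim_kwargs = dict(raw.get("simulation", {}))
        sim_kwargs.setdefault("seed", seed)
        return cls(
            out_dir=Path(pipeline.get("out_dir", "chocnv_out")),
            seed=seed,
            n_bootstrap=pipeline.get("n_bootstrap", 100),
            samples=tuple(pipeline.get("samples", DEMO_SAMPLES)),
            reference_sample=pipeline.get("reference_sample", "C_griseus"),
            simulation=SimulationConfig(**sim_kwargs),
            thresholds=ClassificationThresholds(**raw.get("thresholds", {})),
            snp_filter=SnpFilterConfig(**raw.get("snp_filter", {})),
            go_p_cutoff=pipeline.get("go_p_cutoff", 0.01),
            input_files=dict(raw.get("inputs", {})),
        )

    def validate(self) -> None:
        if self.reference_sample not in self.samples:
            raise ValueError(f"reference sample {self.reference_sample!r} not in samples")
        for name, path in self.input_files.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"input {name!r}: no such file {path}")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path, seed: int) -> None:
        self.out_dir = out_dir
        self.seed = seed
        self.stages: list[dict[str, Any]] = []

    def record(self, stage: str, started: float, outputs: list[Path]) -> None:
        self.stages.append(
            {
                "stage": stage,
                "seed": self.seed,
                "runtime_s": round(time.monotonic() - started, 3),
                "outputs": {
                    str(p.relative_to(self.out_dir)): _sha256(p) for p in outputs
                },
            }
        )

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        with open(path, "w") as handle:
            json.dump({"seed": self.seed, "stages": self.stages}, handle, indent=1)
        return path


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run all stages in dependency order; returns the manifest dict.

    Any stage failure aborts with the stage name attached to the exception.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, config.seed)
    state: dict[str, Any] = {}

    stages = [
        ("simulate", _stage_simulate),
        ("profile", _stage_profile),
        ("classify", _stage_classify),
        ("snp", _stage_snp),
        ("phylo", _stage_phylo),
        ("signature", _stage_signature),
        ("go_enrich", _stage_go),
    ]
    for name, stage in stages:
        started = time.monotonic()
        try:
            outputs = stage(config, out, state)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest.record(name, started, outputs)
        log.info("stage %s done (%.1fs)", name, time.monotonic() - started)
    manifest.write()
    return {"seed": config.seed, "stages": manifest.stages}


def _stage_simulate(config: PipelineConfig, out: Path, state: dict) -> list[Path]:
    sim = config.simulation
    annotation = synthetic_data.generate_annotation(sim)
    cn_maps = synthetic_data.preset_cn_maps(sim, config.samples)
    go_table = synthetic_data.generate_go_table(annotation, sim)
    state.update(annotation=annotation, cn_maps=cn_maps, go_table=go_table)

    genes_path = out / "genes.tsv"
    fasta_path = out / "cds.fasta"
    go_path = out / "go_terms.tsv"
    write_gene_table(annotation, genes_path, fasta=fasta_path)
    write_go_table(go_table, go_path)
    outputs = [genes_path, fasta_path, go_path]

    state["variants"] = {}
    for i, sample in enumerate(config.samples):
        calls, truth, blacklist = synthetic_data.simulate_variants(
            annotation, cn_maps[sample], sim, stream=i
        )
        state["variants"][sample] = calls
        vcf_path = out / f"{sample}.vcf"
        write_variants(calls, vcf_path)
        outputs.append(vcf_path)
    return outputs


def _stage_profile(config: PipelineConfig, out: Path, state: dict) -> list[Path]:
    sim = config.simulation
    tables = {}
    outputs = []
    for i, sample in enumerate(config.samples):
        medians = synthetic_data.simulate_gene_depths(
            state["annotation"], state["cn_maps"][sample], sim, stream=i
        )
        table = depth_profiling.normalize_depths(medians, sample_id=sample)
        tables[sample] = table
        path = out / f"{sample}.depths.tsv"
        pd.DataFrame({"raw": table.raw, "normalized": table.normalized}).to_csv(
            path, sep="\t", index_label="gene_id"
        )
        outputs.append(path)
    state["depth_tables"] = tables
    return outputs


def _stage_classify(config: PipelineConfig, out: Path, state: dict) -> list[Path]:
    tables = state["depth_tables"]
    reference = tables[config.reference_sample]
    profiles = {}
    outputs = []
    summary_rows = {}
    for sample, table in tables.items():
        profile = ploidy.classify_profile(table, reference, config.thresholds)
        profiles[sample] = profile
        path = out / f"{sample}.classes.tsv"
        pd.DataFrame(
            {"class": profile.classes, "normalized": profile.normalized}
        ).to_csv(path, sep="\t", index_label="gene_id")
        outputs.append(path)
        summary_rows[sample] = profile.summary()
    summary_path = out / "copy_number_summary.tsv"
    pd.DataFrame.from_dict(summary_rows, orient="index").to_csv(
        summary_path, sep="\t", index_label="sample"
    )
    outputs.append(summary_path)
    state["profiles"] = profiles
    return outputs


def _stage_snp(config: PipelineConfig, out: Path, state: dict) -> list[Path]:
    outputs = []
    spectrum_rows = {}
    for sample in config.samples:
        calls = state["variants"][sample]
        median_depth = float(state["depth_tables"][sample].raw.median())
        kept, rejections = snp_filters.filter_variants(
            calls, median_depth, config.snp_filter
        )
        vcf_path = out / f"{sample}.filtered.vcf"
        write_variants(calls, vcf_path, filters=rejections)
        outputs.append(vcf_path)
        spectrum = substitution_spectrum(c for c in kept if not c.is_indel)
        spectrum_rows[sample] = {
            "n_kept": len(kept),
            "gc_to_at": spectrum.gc_to_at,
            "at_to_gc": spectrum.at_to_gc,
            "ratio": spectrum.ratio,
        }
    path = out / "spectrum.tsv"
    pd.DataFrame.from_dict(spectrum_rows, orient="index").to_csv(
        path, sep="\t", index_label="sample"
    )
    outputs.append(path)
    return outputs


def _stage_phylo(config: PipelineConfig, out: Path, state: dict) -> list[Path]:
    tables = state["depth_tables"]
    if len(tables) < 3:
        log.warning("fewer than 3 samples; skipping phylogeny")
        return []
    tree, matrix = bootstrap_consensus(
        tables,
        n_replicates=config.n_bootstrap,
        seed=config.seed,
        cnv_diff=config.thresholds.cnv_diff,
    )
    tree_path = out / "cnv_tree.nwk"
    matrix_path = out / "cnv_distances.csv"
    write_newick(tree, tree_path)
    write_matrix(matrix, matrix_path)
    return [tree_path, matrix_path]


def _stage_signature(config: PipelineConfig, out: Path, state: dict) -> list[Path]:
    profiles = dict(state["profiles"])
    reference = profiles.pop(config.reference_sample)
    frame = ploidy.chromosome_signature(
        profiles, state["annotation"], reference, config.thresholds
    )
    path = out / "chromosome_signature.csv"
    frame.to_csv(path)
    return [path]


def _stage_go(config: PipelineConfig, out: Path, state: dict) -> list[Path]:
    profiles = dict(state["profiles"])
    reference = profiles.pop(config.reference_sample)
    frame = go_enrichment.enrichment_screen(
        profiles,
        reference,
        state["go_table"],
        p_cutoff=config.go_p_cutoff,
        thresholds=config.thresholds,
    )
    path = out / "go_enrichment.csv"
    frame.to_csv(path, index=False)
    return [path]
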