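"""End-to-end pipeline: genotypes -> blocks -> distances -> structure ->
stratified phenotype report, with a manifest of content hashes so a rerun
with the same configuration and seed is verifiably byte-identical."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

from . import asd as asd_mod
from . import blocks as blocks_mod
from . import io as io_mod
from . import structure as structure_mod
from .phenostats import PhenotypeTable, stratified_report
from .synthetic import CohortConfig, simulate_cohort


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input source: either the three real-data paths
    (genotypes + map + panel labels, optionally phenotypes) or a
    synthetic :class:`~haplostrat.synthetic.CohortConfig`.
    """

    out_dir: str | Path
    genotype_path: str | None = None
    map_path: str | None = None
    labels_path: str | None = None
    phenotype_path: str | None = None
    dialect: str = "tsv"
    synthetic: CohortConfig | None = None

    maf_min: float = 0.01
    call_rate_min: float = 0.90
    block_size: int = 4
    max_span_bp: int = 150_000
    max_gap_bp: int = 50_000
    min_valid_fraction: float = 0.5
    tie_band: float = 0.0
    episode_min_s: float = 10.0

    def __post_init__(self) -> None:
        real = self.genotype_path is not None
        if real == (self.synthetic is not None):
            raise ValueError(
                "exactly one of real input paths or a synthetic config is required"
            )
        if real and (self.map_path is None or self.labels_path is None):
            raise ValueError("real input needs genotype, map and labels paths")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["out_dir"] = str(d["out_dir"])
    if cfg.synthetic is not None:
        syn = dataclasses.asdict(cfg.synthetic)
        syn["af_rates"] = {f"{k[0]}/{k[1]}": v for k, v in syn["af_rates"].items()}
        syn["expression_shifts"] = {
            f"{k[0]}/{k[1]}/{k[2]}": v for k, v in syn["expression_shifts"].items()
        }
        d["synthetic"] = syn
    return d


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage in order and return the manifest (also written to
    ``manifest.json``).  A failing stage writes a ``FAILED`` marker naming
    the stage and re-raises; earlier artifacts are retained."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    stage = "setup"
    try:
        stage = "input"
        if cfg.synthetic is not None:
            cohort = simulate_cohort(cfg.synthetic)
            gm, smap, labels = cohort.genotypes, cohort.snp_map, cohort.labels
            pt = cohort.phenotypes
            io_mod.write_genotypes_tsv(
                gm, smap, out / "genotypes.tsv", out / "markers.tsv"
            )
            io_mod.write_panel_labels(labels, out / "panel_labels.tsv")
            pt.to_tsv(out / "phenotypes.tsv")
            artifacts += [
                out / "genotypes.tsv",
                out / "markers.tsv",
                out / "panel_labels.tsv",
                out / "phenotypes.tsv",
            ]
        else:
            gm, smap = io_mod.read_genotypes(
                cfg.genotype_path, cfg.map_path, dialect=cfg.dialect
            )
            labels = io_mod.read_panel_labels(cfg.labels_path)
            labels.validate_against(gm)
            pt = (
                PhenotypeTable.from_tsv(cfg.phenotype_path)
                if cfg.phenotype_path
                else None
            )

        stage = "filter"
        gm, smap, report = io_mod.filter_informative(
            gm, smap, cfg.maf_min, cfg.call_rate_min
        )
        (out / "filter_report.json").write_text(json.dumps(report, indent=2) + "\n")
        artifacts.append(out / "filter_report.json")

        stage = "blocks"
        bp = blocks_mod.partition_blocks(
            smap, cfg.block_size, cfg.max_span_bp, cfg.max_gap_bp
        )
        blocks_mod.write_blocks_bed(bp, out / "blocks.bed")
        stats = blocks_mod.block_coverage_stats(bp, smap)
        (out / "block_stats.json").write_text(json.dumps(stats, indent=2) + "\n")
        artifacts += [out / "blocks.bed", out / "block_stats.json"]

        stage = "asd"
        dm = asd_mod.asd_matrix(gm, bp, cfg.min_valid_fraction)
        io_mod.write_distance_matrix(dm, out / "distances.tsv")
        asd_mod.write_valid_fractions(dm, out / "valid_fractions.tsv")
        artifacts += [out / "distances.tsv", out / "valid_fractions.tsv"]

        stage = "mds"
        emb = structure_mod.classical_mds(dm, dims=2, panels=labels)
        structure_mod.write_embedding(emb, out / "mds.tsv")
        artifacts.append(out / "mds.tsv")

        stage = "upgma"
        tree = structure_mod.upgma(dm)
        (out / "tree.nwk").write_text(structure_mod.to_newick(tree) + "\n")
        artifacts.append(out / "tree.nwk")

        stage = "assign"
        ba = structure_mod.assign_breed(dm, labels, cfg.tie_band)
        structure_mod.write_assignment(ba, out / "assignment.tsv")
        artifacts.append(out / "assignment.tsv")

        stage = "stats"
        if pt is not None:
            rep = stratified_report(pt, ba, cfg.episode_min_s)
            rep.to_tsv(out / "stratified_report.tsv")
            (out / "stratified_report.txt").write_text(rep.to_text() + "\n")
            artifacts += [out / "stratified_report.tsv", out / "stratified_report.txt"]
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": _config_dict(cfg),
        "seed": cfg.synthetic.seed if cfg.synthetic is not None else None,
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
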