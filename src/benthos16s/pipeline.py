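"""End-to-end orchestration: taxonomy -> decontamination -> prevalence
filter -> aggregation -> clr -> {correlations, ordination, richness trends}.

A run is driven by a fully serialisable :class:`PipelineConfig`; the resolved
config is written next to the outputs, every stage writes its artifact, and a
JSON manifest records per-stage OTU/sample accounting. A single global seed
fans out to stage seeds through a fixed derivation (seed * 1000 + stage
index) so stages can be re-run in isolation; identical config and seed give
byte-identical TSV/JSON artifacts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import community, decontam, ordination, taxonomy, trends
from .io_model import (
    FilterConfig,
    read_env_table,
    read_hits,
    read_lineage_map,
    read_otu_table,
    write_assignments,
    write_otu_table,
)

__all__ = ["PipelineConfig", "run_all"]

logger = logging.getLogger("benthos16s.pipeline")

_STAGE_SEEDS = {"ordination": 1}


@dataclass
class PipelineConfig:
    hits_path: str = ""
    lineages_path: str = ""
    otu_table_path: str = ""
    roles_path: str = ""
    metadata_path: str = ""
    out_dir: str = "run"
    # taxonomy
    filter: dict = field(default_factory=dict)  # FilterConfig overrides
    # decontamination
    decontam_method: str = "subtract_scaled"
    pool_controls: bool = True
    # community
    min_prevalence: int = 3
    rank: str = "phylum"
    top_k: int = 12
    pseudocount_mode: str = "add_one"
    region_cuts: tuple[float, float, float, float] = (19.0, 21.5, 24.5, 27.5)
    # ordination
    candidates: list[str] = field(
        default_factory=lambda: ["latitude", "depth_m", "oxygen_saturation",
                                 "temperature", "salinity"]
    )
    alpha: float = 0.05
    n_perm: int = 999
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1000 + _STAGE_SEEDS.get(stage, 0)) % (2**31 - 1)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "region_cuts" in raw:
            raw["region_cuts"] = tuple(raw["region_cuts"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["region_cuts"] = list(self.region_cuts)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_all(config: PipelineConfig) -> Path:
    """Execute every stage, persisting each intermediate artifact.

    Returns the run directory. A stage failure aborts with the stage name;
    artifacts of completed stages remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    manifest: dict = {"stages": {}}
    stage = "setup"
    try:
        t0 = time.perf_counter()

        stage = "taxonomy"
        lineage_map = read_lineage_map(config.lineages_path)
        hits = read_hits(config.hits_path, lineage_map)
        grouped = taxonomy.group_hits_by_query(hits)
        fcfg = FilterConfig(**config.filter)
        assignments = taxonomy.assign_taxonomy(grouped, fcfg)
        write_assignments(assignments, out / "assignments.tsv")
        manifest["stages"]["taxonomy"] = {
            "n_hits": len(hits),
            "n_otus_with_hits": len(grouped),
            "n_assigned": sum(1 for a in assignments if a.lineage.depth > 0),
        }
        logger.info("taxonomy done in %.2fs", time.perf_counter() - t0)

        stage = "decontam"
        t0 = time.perf_counter()
        table = read_otu_table(config.otu_table_path, config.roles_path)
        manifest["stages"]["input"] = {
            "n_otus": len(table.otu_ids),
            "n_samples": len(table.true_sample_ids),
            "n_controls": len(table.control_ids),
        }
        clean, report = decontam.remove_contaminants(
            table, method=config.decontam_method, pool_controls=config.pool_controls
        )
        write_otu_table(clean, out / "clean_otu.tsv", out / "clean_roles.tsv")
        _write_json(report.to_dict(), out / "decontam_report.json")
        manifest["stages"]["decontam"] = {
            "n_otus": len(clean.otu_ids),
            "n_otus_removed": len(report.otus_removed),
            "reads_removed": int(sum(report.reads_removed_per_sample.values())),
        }
        logger.info("decontam done in %.2fs", time.perf_counter() - t0)

        stage = "prevalence_filter"
        t0 = time.perf_counter()
        filtered = community.prevalence_filter(clean, config.min_prevalence)
        write_otu_table(filtered, out / "filtered_otu.tsv")
        manifest["stages"]["prevalence_filter"] = {"n_otus": len(filtered.otu_ids)}

        stage = "aggregation"
        agg = community.aggregate_taxa(
            filtered, assignments, rank=config.rank, top_k=config.top_k
        )
        agg.to_csv(out / "aggregated.tsv", sep="\t")
        manifest["stages"]["aggregation"] = {"n_taxa": len(agg)}

        stage = "clr"
        clr = community.clr_transform(agg, config.pseudocount_mode)
        clr.values.to_csv(out / "clr.tsv", sep="\t", index_label="sample_id")
        logger.info("community done in %.2fs", time.perf_counter() - t0)

        stage = "correlations"
        t0 = time.perf_counter()
        env = read_env_table(config.metadata_path)
        scheme = community.RegionScheme(cuts=config.region_cuts)
        env_df = community.derive_env_labels(env.aligned_to(clr.sample_ids), scheme)
        grid = community.correlation_grid(
            clr,
            env_df,
            continuous=["latitude", "depth_m", "oxygen_saturation"],
            categories=["region_label", "depth_category"],
        )
        grid.r.to_csv(out / "correlations.tsv", sep="\t", index_label=config.rank)
        grid.n.to_csv(out / "correlations_n.tsv", sep="\t", index_label=config.rank)
        logger.info("correlations done in %.2fs", time.perf_counter() - t0)

        stage = "ordination"
        t0 = time.perf_counter()
        # oxygen enters the candidate set, so ordinate the oxygen-complete subset
        cand_cols = [c for c in config.candidates if c in env_df.columns]
        complete = env_df[cand_cols].dropna().index
        blocks = ordination.expand_candidates(env_df.loc[complete], cand_cols)
        rda_result = ordination.forward_select(
            clr.values.loc[complete],
            blocks,
            alpha=config.alpha,
            n_perm=config.n_perm,
            seed=config.stage_seed("ordination"),
        )
        _write_json(rda_result.to_dict(), out / "rda.json")
        manifest["stages"]["ordination"] = {
            "n_samples": int(len(complete)),
            "selected": rda_result.selected,
        }
        logger.info("ordination done in %.2fs", time.perf_counter() - t0)

        stage = "trends"
        t0 = time.perf_counter()
        richness = trends.otu_richness(filtered)
        fits = trends.stratified_regression(
            richness,
            env_df["latitude"],
            env_df["depth_category"],
        )
        reads = filtered.counts.sum(axis=0)
        sat = trends.saturation_fit(reads, richness)
        _write_json(
            {
                "regressions": [f.to_dict() for f in fits],
                "saturation": sat.to_dict(),
            },
            out / "trends.json",
        )
        manifest["stages"]["trends"] = {
            "strata": {f.stratum: f.n for f in fits},
        }
        logger.info("trends done in %.2fs", time.perf_counter() - t0)
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    _write_json(manifest, out / "manifest.json")
    return out
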