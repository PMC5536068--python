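"""End-to-end orchestration with a single config and deterministic seeds.

The pipeline runs: paired DE (genes and miRNAs) -> DE pathway enrichment ->
DC scoring -> DC enrichment (per-miRNA and miRNome modes) -> integrative
report, writing each stage's table plus a provenance manifest into a run
directory.  One parent seed deterministically derives per-stage seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .data_io import (
    load_study,
    map_collection_to_study,
    read_gmt,
    write_table,
)
from .dc_enrichment import attach_dc_mirnas, enrich_collection_dc
from .dc_scoring import dc_score_matrix
from .diffexpr import de_table
from .randomset import enrich_collection_de
from .reporting import expected_significant, overlap_fisher, rank_mirnas_by_de_pathways

logger = logging.getLogger(__name__)

STAGES = ("de", "enrich_de", "dc_scores", "enrich_dc_mirna",
          "enrich_dc_mirnome", "report")


@dataclass
class RunConfig:
    gene_path: str
    mirna_path: str
    metadata_path: str
    gmt_path: str
    out_dir: str
    B: int = 1000
    seed: int = 0
    alpha_de: float = 0.01        # pathway-level DE significance
    alpha_dc: float = 0.01        # per-(set, miRNA) DC significance
    alpha_feature: float = 0.05   # per-feature DE significance
    min_set_size: int = 5
    max_set_size: int | None = None
    df_mode: str = "paired"
    save_dc_matrices: bool = False
    known_mirnas: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        for name in ("alpha_de", "alpha_dc", "alpha_feature"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {a}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        # out_dir is excluded: where results land must not change them
        fields = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def stage_seeds(parent_seed: int, n: int = len(STAGES)) -> dict[str, int]:
    """Derive one child seed per stage from the parent seed (below 2^31)."""
    ss = np.random.SeedSequence(parent_seed)
    children = ss.generate_state(n, dtype=np.uint32)
    return {stage: int(s % (2**31)) for stage, s in zip(STAGES, children)}


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, write TSVs plus a manifest; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    meta = f"mirdc v{__version__} | config={config.config_hash()} | seed={config.seed}"
    manifest: dict = {
        "tool": "mirdc",
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stage_seeds": seeds,
        "stages": [],
        "outputs": {},
    }

    def done(stage, path=None):
        manifest["stages"].append(stage)
        if path is not None:
            manifest["outputs"][stage] = str(path)
        logger.info("stage %s complete", stage)

    try:
        study = load_study(config.gene_path, config.mirna_path, config.metadata_path)
        collection = map_collection_to_study(
            read_gmt(config.gmt_path), study,
            min_size=config.min_set_size,
            max_size=config.max_set_size,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'load': {exc}") from exc

    def run_stage(stage, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r}: {exc}") from exc

    # --- differential expression ---------------------------------------
    de_genes = run_stage("de", lambda: de_table(study, "genes", config.alpha_feature))
    de_mirnas = run_stage("de", lambda: de_table(study, "mirnas", config.alpha_feature))
    write_table(de_genes, out / "de_genes.tsv", meta)
    write_table(de_mirnas, out / "de_mirnas.tsv", meta)
    done("de", out / "de_genes.tsv")

    # --- DE pathway enrichment ------------------------------------------
    enr_de = run_stage("enrich_de", lambda: enrich_collection_de(
        study, collection, B=config.B, seed=seeds["enrich_de"],
        df_mode=config.df_mode,
    ))
    write_table(enr_de, out / "enrich_de.tsv", meta)
    done("enrich_de", out / "enrich_de.tsv")

    # --- DC scoring ------------------------------------------------------
    dc = run_stage("dc_scores", lambda: dc_score_matrix(study))
    if config.save_dc_matrices:
        import pandas as pd

        for tag, mat in (("rho_normal", dc.rho_normal),
                         ("rho_diseased", dc.rho_diseased), ("s", dc.s)):
            frame = pd.DataFrame(mat, index=study.gene_ids, columns=study.mirna_ids)
            frame.to_csv(out / f"dc_{tag}.tsv", sep="\t")
    done("dc_scores")

    # --- DC enrichment ----------------------------------------------------
    dc_mirna = run_stage("enrich_dc_mirna", lambda: enrich_collection_dc(
        study, collection, mode="mirna", B=config.B, seed=seeds["enrich_dc_mirna"],
    ))
    write_table(dc_mirna, out / "enrich_dc_mirna.tsv", meta)
    done("enrich_dc_mirna", out / "enrich_dc_mirna.tsv")

    dc_mirnome = run_stage("enrich_dc_mirnome", lambda: enrich_collection_dc(
        study, collection, mode="mirnome", B=config.B,
        seed=seeds["enrich_dc_mirnome"],
    ))
    dc_mirnome = attach_dc_mirnas(dc_mirnome, dc_mirna, config.alpha_dc)
    write_table(dc_mirnome, out / "enrich_dc_mirnome.tsv", meta)
    done("enrich_dc_mirnome", out / "enrich_dc_mirnome.tsv")

    # --- integrative report ----------------------------------------------
    def build_report():
        n_sets = len(collection)
        de_sig = set(enr_de.loc[enr_de["p_perm"] < config.alpha_de, "set_name"])
        dc_sig = set(dc_mirnome.loc[dc_mirnome["p_perm"] < config.alpha_de, "set_name"])
        overlap = overlap_fisher(n_sets, len(de_sig), len(dc_sig),
                                 len(de_sig & dc_sig))
        ranking = rank_mirnas_by_de_pathways(
            dc_mirna, enr_de, alpha_dc=config.alpha_dc, alpha_de=config.alpha_de
        )
        return overlap, ranking

    overlap, ranking = run_stage("report", build_report)
    write_table(ranking, out / "mirna_ranking.tsv", meta)
    report = {
        "n_sets": len(collection),
        "expected_by_chance": expected_significant(len(collection), config.alpha_de),
        "overlap": asdict(overlap),
    }
    if config.known_mirnas:
        from .reporting import validate_known_mirnas

        de_mirna_ids = set(
            de_mirnas.loc[de_mirnas["p"] < config.alpha_feature, "feature_id"]
        )
        report["validation"] = validate_known_mirnas(
            ranking, config.known_mirnas, de_mirnas=de_mirna_ids,
        )
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    done("report", out / "report.json")

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
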