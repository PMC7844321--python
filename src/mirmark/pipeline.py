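"""End-to-end orchestration: DE -> networks -> topology -> intersection ->
evaluation -> enrichment, from a single config, with a fully synthetic demo
mode and a JSON run manifest.

Every random draw flows from the config's single seed; re-running the same
config reproduces byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .diffexpr import (
    ExpressionMatrix,
    PROGRESSION,
    collapse_probes,
    de_table,
    occurrence_contrast,
    select_de,
    write_de_table,
)
from .enrichment import ora_test, read_gmt, write_enrichment
from .evaluation import cluster_samples, evaluate_candidates, prediction_precision, write_roc_table
from .network import (
    extract_condition_network,
    read_edge_list,
    write_edge_list,
)
from .synthetic import SyntheticConfig, generate_dataset
from .topology import mirna_feature_table, nominate_biomarkers, prioritize

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Inputs and knobs for one pipeline run.

    Either ``synthetic`` is set (demo mode: everything generated) or the
    four input paths are.  ``de_alpha`` is the adjusted-p cut for DE calls,
    ``prioritization_alpha`` the per-metric Wilcoxon cut.
    """

    outdir: str = "mirmark-run"
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    mirna_expression: str | None = None
    mirna_groups: str | None = None
    mrna_expression: str | None = None
    mrna_groups: str | None = None
    reference_network: str | None = None
    probe_map: str | None = None
    gene_sets: str | None = None
    known_biomarkers: str | None = None
    de_alpha: float = 0.05
    prioritization_alpha: float = 0.05
    wilcoxon_variant: str = "loo-signed-rank"
    shared_mode: str = "intersection"
    pool_metastatic: bool = True
    ora_mode: str = "fisher"
    write_outputs: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.de_alpha <= 1 or not 0 < self.prioritization_alpha < 1:
            raise ValueError("thresholds must lie in (0, 1) (de_alpha=1 disables the filter)")
        if self.synthetic is None and self.reference_network is None:
            raise ValueError("either a synthetic config or input paths are required")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        syn = raw.pop("synthetic", None)
        if syn is not None:
            if isinstance(syn, dict):
                syn.setdefault("seed", raw.get("seed", 0))
                syn = SyntheticConfig(**syn)
            elif syn == "default" or syn is True:
                syn = SyntheticConfig(seed=raw.get("seed", 0))
        return cls(synthetic=syn, **raw)


def _read_id_list(path) -> list:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and return the run manifest.

    The manifest carries the seed, package version and the counts at every
    stage (DE features, condition-network edges, prioritized and shared
    miRNAs, shared regulations, average AUCs).  With ``write_outputs`` the
    intermediate tables, networks, the manifest and a ``run.log`` are
    written under ``outdir``.
    """
    outdir = Path(config.outdir)
    pkg_logger = logging.getLogger("mirmark")
    handler = None
    prev_level = pkg_logger.level
    if config.write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(outdir / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        pkg_logger.addHandler(handler)
        if prev_level == logging.NOTSET or prev_level > logging.INFO:
            pkg_logger.setLevel(logging.INFO)
    try:
        return _run_pipeline(config, outdir)
    finally:
        if handler is not None:
            pkg_logger.removeHandler(handler)
            pkg_logger.setLevel(prev_level)
            handler.close()


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - stage-named abort is the contract
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return result
    return wrap


def _run_pipeline(config: RunConfig, outdir: Path) -> dict:
    truth = None
    if config.synthetic is not None:
        syn = dataclasses.replace(config.synthetic, seed=config.seed)
        mirna, mrna, reference, truth = _stage("simulate")(generate_dataset, syn)
        if config.write_outputs:
            mirna.write_tsv(outdir / "mirna_expression.tsv", outdir / "mirna_groups.tsv")
            mrna.write_tsv(outdir / "mrna_expression.tsv", outdir / "mrna_groups.tsv")
            write_edge_list(reference, outdir / "reference_network.tsv")
            truth.to_json(outdir / "ground_truth.json")
    else:
        def load():
            m = ExpressionMatrix.read_tsv(config.mirna_expression, config.mirna_groups)
            g = ExpressionMatrix.read_tsv(config.mrna_expression, config.mrna_groups)
            ref = read_edge_list(config.reference_network)
            return m, g, ref
        mirna, mrna, reference = _stage("load")(load)

    occ = occurrence_contrast(config.pool_metastatic)
    contrasts = {"occurrence": occ, "progression": PROGRESSION}

    # --- differential expression --------------------------------------------
    de_tables: dict = {}
    de_sets: dict = {}
    probe_map = None
    if config.probe_map:
        import csv
        with open(config.probe_map) as fh:
            probe_map = {r[0]: r[1] for r in csv.reader(fh, delimiter="\t") if len(r) >= 2}
    for rna, matrix in (("mirna", mirna), ("mrna", mrna)):
        for cname, contrast in contrasts.items():
            tab = _stage(f"de-{rna}-{cname}")(de_table, matrix, contrast, config.de_alpha)
            if rna == "mrna" and probe_map:
                tab = _stage(f"collapse-{cname}")(collapse_probes, tab, probe_map)
            de_tables[rna, cname] = tab
            de_sets[rna, cname] = select_de(tab, config.de_alpha)
            if config.write_outputs:
                write_de_table(tab, outdir / f"de_{rna}_{cname}.tsv")

    # --- condition-specific networks ----------------------------------------
    nets: dict = {}
    for cname in contrasts:
        nets[cname] = _stage(f"network-{cname}")(
            extract_condition_network,
            reference,
            set(de_sets["mirna", cname]),
            set(de_sets["mrna", cname]),
        )
        if config.write_outputs:
            write_edge_list(nets[cname], outdir / f"network_{cname}.tsv")

    # --- topology & prioritization ------------------------------------------
    features: dict = {}
    for cname in contrasts:
        feats = mirna_feature_table(nets[cname], condition=cname)
        features[cname] = _stage(f"prioritize-{cname}")(
            prioritize, feats, config.prioritization_alpha, config.wilcoxon_variant
        )
        if config.write_outputs:
            features[cname].to_csv(
                outdir / f"features_{cname}.tsv", sep="\t",
                index_label="mirna", float_format="%.6g",
            )
    result = _stage("intersect")(
        nominate_biomarkers,
        features["occurrence"], features["progression"],
        nets["occurrence"], nets["progression"],
        config.shared_mode,
    )
    if config.write_outputs:
        with open(outdir / "biomarkers.json", "w") as fh:
            json.dump(result.to_dict(), fh, indent=1, sort_keys=True)
        with open(outdir / "shared_regulations.tsv", "w") as fh:
            for m, g in result.shared_regulations:
                fh.write(f"{m}\t{g}\n")

    # --- evaluation ----------------------------------------------------------
    shared = list(result.shared_mirnas)
    roc_tables = []
    mean_auc: dict = {}
    clustering = None
    if shared:
        for cname, contrast in contrasts.items():
            roc = _stage(f"roc-{cname}")(evaluate_candidates, mirna, shared, contrast)
            roc_tables.append(roc)
            mean_auc[cname] = round(float(roc["auc_folded"].mean()), 4) if len(roc) else None
        if config.write_outputs and roc_tables:
            import pandas as pd
            write_roc_table(pd.concat(roc_tables), outdir / "roc.tsv")
        shared_in_matrix = [m for m in shared if m in mirna.values.index]
        if len(shared_in_matrix) >= 2:
            clustering = _stage("clustering")(cluster_samples, mirna, shared)
            if config.write_outputs:
                with open(outdir / "clustering.json", "w") as fh:
                    json.dump(
                        {
                            "linkage": clustering.linkage.tolist(),
                            "leaf_order": list(clustering.leaf_order),
                            "assignments": clustering.assignments,
                        },
                        fh, indent=1, sort_keys=True,
                    )

    precision = None
    if config.known_biomarkers and shared:
        known = _read_id_list(config.known_biomarkers)
        precision = prediction_precision(shared, known)

    # --- enrichment -----------------------------------------------------------
    n_enriched = None
    if config.gene_sets and result.shared_regulations:
        collection = read_gmt(config.gene_sets)
        targets = {g for _, g in result.shared_regulations}
        universe = set(reference.mrna_nodes)
        enr = _stage("enrichment")(ora_test, targets, collection, universe, config.ora_mode)
        n_enriched = int((enr["p_raw"] < 0.05).sum())
        if config.write_outputs:
            write_enrichment(enr, outdir / "enrichment.tsv")

    manifest = {
        "mirmark_version": __version__,
        "seed": config.seed,
        "de_alpha": config.de_alpha,
        "prioritization_alpha": config.prioritization_alpha,
        "wilcoxon_variant": config.wilcoxon_variant,
        "shared_mode": config.shared_mode,
        "counts": {
            "de_mirnas_occurrence": len(de_sets["mirna", "occurrence"]),
            "de_mirnas_progression": len(de_sets["mirna", "progression"]),
            "de_mrnas_occurrence": len(de_sets["mrna", "occurrence"]),
            "de_mrnas_progression": len(de_sets["mrna", "progression"]),
            "reference_edges": reference.n_edges,
            "edges_occurrence": nets["occurrence"].n_edges,
            "edges_progression": nets["progression"].n_edges,
            "prioritized_occurrence": len(result.occurrence_prioritized),
            "prioritized_progression": len(result.progression_prioritized),
            "shared_mirnas": len(result.shared_mirnas),
            "shared_regulations": len(result.shared_regulations),
            "shared_target_mrnas": result.n_target_mrnas,
        },
        "shared_mirnas": list(result.shared_mirnas),
        "mean_auc_folded": mean_auc or None,
        "prediction_precision": precision,
        "n_enriched_sets": n_enriched,
    }
    if truth is not None:
        manifest["planted_biomarkers"] = sorted(truth.planted_biomarkers)
        manifest["recovered_planted"] = sorted(
            set(result.shared_mirnas) & truth.planted_biomarkers
        )
    if config.write_outputs:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
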