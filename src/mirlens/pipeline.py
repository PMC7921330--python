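"""End-to-end orchestration: config parsing, staged run, report and manifest.

The run config is flat ``key: value`` text.  Required path keys:
``mirna_matrix``, ``groups``, ``mrna_de_p4``, ``mrna_de_p30``, ``targets``,
``isyte_p4``, ``isyte_p30``, ``gmt``, ``perturbation_manifest``; optional:
``qpcr_table``, ``qpcr_targets``, ``qpcr_references``, ``rules`` (tier-rule
file).  Thresholds (``fc``, ``alpha``, ``min_score``, ``expression_floor``,
``intensity_high``) default to 1.2, 0.05, 50, 100 and 500.  All stages are
deterministic given the config, so a rerun writes byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import de, enrich, network, prioritize, qpcr
from .core import (
    read_differential_table,
    read_enrichment_table,
    read_expression_matrix,
    read_gmt,
    read_group_map,
    read_target_predictions,
    write_differential_table,
)
from .pairing import filter_targets, pair_inverse, unique_mrna_count
from .prioritize import TierRuleSet

__all__ = ["RunConfig", "StageError", "run_all"]

logger = logging.getLogger(__name__)

REQUIRED_PATHS = (
    "mirna_matrix",
    "groups",
    "mrna_de_p4",
    "mrna_de_p30",
    "targets",
    "isyte_p4",
    "isyte_p30",
    "gmt",
    "perturbation_manifest",
)
OPTIONAL_PATHS = ("qpcr_table", "rules")
DEFAULT_THRESHOLDS = {
    "fc": 1.2,
    "alpha": 0.05,
    "min_score": 50.0,
    "expression_floor": 100.0,
    "intensity_high": 500.0,
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    paths: dict[str, Path]
    fc: float = 1.2
    alpha: float = 0.05
    min_score: float = 50.0
    expression_floor: float = 100.0
    intensity_high: float = 500.0
    qpcr_targets: tuple[str, ...] = ()
    qpcr_references: tuple[str, ...] = ()
    regulator: str = "Tdrd7"
    seed: int = 0

    def validate(self) -> None:
        for key in REQUIRED_PATHS:
            if key not in self.paths:
                raise ValueError(f"config missing required path {key!r}")
            if not self.paths[key].exists():
                raise ValueError(f"config path {key!r} does not exist: {self.paths[key]}")
        for key in OPTIONAL_PATHS:
            if key in self.paths and not self.paths[key].exists():
                raise ValueError(f"config path {key!r} does not exist: {self.paths[key]}")
        for name in DEFAULT_THRESHOLDS:
            if not getattr(self, name) > 0:
                raise ValueError(f"threshold {name!r} must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw: dict[str, str] = {}
        with path.open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if ":" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key: value'")
                key, value = (part.strip() for part in line.split(":", 1))
                raw[key] = value
        base = path.parent
        paths = {
            k: (base / raw[k] if not Path(raw[k]).is_absolute() else Path(raw[k]))
            for k in (*REQUIRED_PATHS, *OPTIONAL_PATHS)
            if k in raw
        }
        kwargs: dict = {"paths": paths}
        for name, default in DEFAULT_THRESHOLDS.items():
            kwargs[name] = float(raw.get(name, default))
        if "qpcr_targets" in raw:
            kwargs["qpcr_targets"] = tuple(s.strip() for s in raw["qpcr_targets"].split(",") if s.strip())
        if "qpcr_references" in raw:
            kwargs["qpcr_references"] = tuple(s.strip() for s in raw["qpcr_references"].split(",") if s.strip())
        if "regulator" in raw:
            kwargs["regulator"] = raw["regulator"]
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        config = cls(**kwargs)
        config.validate()
        return config


@dataclass
class RunResult:
    out_dir: Path
    summary: dict[str, object] = field(default_factory=dict)
    outputs: dict[str, Path] = field(default_factory=dict)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - abort with stage context
                raise StageError(name, exc) from exc
            logger.info("stage %-22s %.2fs", name, time.perf_counter() - t0)
            return result

        return inner

    return wrap


def _fmt(value: object) -> str:
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def run_all(config: RunConfig, out_dir: str | Path) -> RunResult:
    """Run every stage and write tables, graph exports, a summary and a manifest."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = RunResult(out_dir=out)
    summary = result.summary

    # --- differential miRNA expression ------------------------------------
    @_stage("normalize+de")
    def stage_de():
        groups = read_group_map(config.paths["groups"])
        matrix = read_expression_matrix(config.paths["mirna_matrix"], groups)
        normalized = de.quantile_normalize(matrix)
        records = de.differential_test(normalized, fc_threshold=config.fc, alpha=config.alpha)
        return normalized, records

    normalized, mirna_records = stage_de()
    result.outputs["mirna_de"] = out / "mirna_de.tsv"
    write_differential_table(mirna_records, result.outputs["mirna_de"])
    up = [r for r in mirna_records if r.direction == "up"]
    down = [r for r in mirna_records if r.direction == "down"]
    summary["n_mirnas_tested"] = len(mirna_records)
    summary["n_mirnas_up"] = len(up)
    summary["n_mirnas_down"] = len(down)

    @_stage("detection-summary")
    def stage_detect():
        return de.summarize_detection(normalized)

    detection = stage_detect()
    summary["n_detected"] = detection.n_detected
    summary["intensity_min"] = detection.intensity_min
    summary["intensity_max"] = detection.intensity_max

    @_stage("highly-expressed")
    def stage_high():
        return de.highly_expressed(mirna_records, intensity_threshold=config.intensity_high)

    catalog = stage_high()
    summary["n_highly_expressed"] = len(catalog)
    result.outputs["highly_expressed"] = out / "highly_expressed.tsv"
    write_differential_table(catalog, result.outputs["highly_expressed"])

    # --- pairing ----------------------------------------------------------
    @_stage("pairing")
    def stage_pair():
        targets = filter_targets(
            read_target_predictions(config.paths["targets"]), min_score=config.min_score
        )
        mrna_p4 = read_differential_table(config.paths["mrna_de_p4"])
        mrna_p30 = read_differential_table(config.paths["mrna_de_p30"])
        pairs = pair_inverse(mirna_records, mrna_p4, targets)
        prioritize.set_p30_directions(pairs, mrna_p30)
        return pairs, mrna_p4, mrna_p30

    pairs, mrna_p4, mrna_p30 = stage_pair()
    summary["n_pairs"] = len(pairs)
    summary["n_unique_mrnas"] = unique_mrna_count(pairs)
    for direction, key in (("up", "elevated"), ("down", "reduced")):
        sub = [p for p in pairs if p.mirna_direction == direction]
        summary[f"n_pairs_{key}"] = len(sub)
        summary[f"n_unique_mrnas_{key}"] = unique_mrna_count(sub)

    # --- prioritization ---------------------------------------------------
    @_stage("prioritize")
    def stage_prioritize():
        isyte_p4 = read_enrichment_table(config.paths["isyte_p4"], "p4")
        isyte_p30 = read_enrichment_table(config.paths["isyte_p30"], "p30")
        prioritize.enrichment_filter(pairs, isyte_p4, "p4", config.expression_floor)
        prioritize.enrichment_filter(pairs, isyte_p30, "p30", config.expression_floor)
        if "rules" in config.paths:
            rules = TierRuleSet.from_text(
                config.paths["rules"].read_text(encoding="utf-8"),
                expression_floor=config.expression_floor,
            )
        else:
            rules = TierRuleSet.default(expression_floor=config.expression_floor)
        prioritize.assign_tiers(pairs, rules)
        return rules

    stage_prioritize()
    pair_df = pd.DataFrame(
        {
            "mirna": [p.mirna_id for p in pairs],
            "mrna": [p.mrna_id for p in pairs],
            "mirna_direction": [p.mirna_direction for p in pairs],
            "mrna_direction_p4": [p.mrna_direction_p4 for p in pairs],
            "mrna_direction_p30": [p.mrna_direction_p30 for p in pairs],
            "score": [p.prediction_score for p in pairs],
            "enriched_p4": [p.enrichment_p4 is not None for p in pairs],
            "enriched_p30": [p.enrichment_p30 is not None for p in pairs],
            "tier": [p.tier for p in pairs],
        }
    )
    result.outputs["pairs"] = out / "pairs.tsv"
    pair_df.to_csv(result.outputs["pairs"], sep="\t", index=False)
    for direction, key in (("up", "elevated"), ("down", "reduced")):
        counts = prioritize.tier_counts(pairs, direction)
        for tier in ("top", "high", "promising", "unranked"):
            summary[f"n_{tier}_{key}"] = counts[tier]

    # --- inverse correlation ----------------------------------------------
    @_stage("correlation")
    def stage_corr() -> Optional[prioritize.CorrelationResult]:
        ranked = [p for p in pairs if p.tier != "unranked"]
        pool = ranked if len(ranked) >= 3 else pairs
        if len(pool) < 3:
            return None
        return prioritize.inverse_correlation(pool, mirna_records, mrna_p4)

    corr = stage_corr()
    if corr is not None:
        summary["pearson_r"] = corr.r
        summary["pearson_p"] = corr.p
        summary["pearson_n_pairs"] = corr.n_pairs

    # --- GO enrichment ----------------------------------------------------
    @_stage("enrichment")
    def stage_enrich():
        annotation = read_gmt(config.paths["gmt"])
        ranked_genes = sorted({p.mrna_id for p in pairs if p.tier != "unranked"})
        terms = enrich.term_enrichment(ranked_genes, annotation)
        clusters = enrich.cluster_terms(terms, annotation=annotation)
        return terms, clusters

    terms, clusters = stage_enrich()
    summary["n_terms_tested"] = len(terms)
    summary["n_top_clusters"] = len(enrich.top_clusters(clusters))
    term_df = pd.DataFrame(
        {
            "term": [t.term_id for t in terms],
            "name": [t.term_name for t in terms],
            "n_overlap": [t.n_overlap for t in terms],
            "n_term": [t.n_term for t in terms],
            "p": [t.p for t in terms],
            "q": [t.q for t in terms],
            "overlap_genes": [";".join(sorted(t.overlap_genes)) for t in terms],
        }
    )
    result.outputs["enrichment"] = out / "enrichment.tsv"
    term_df.to_csv(result.outputs["enrichment"], sep="\t", index=False)

    # --- regulatory network + concordance ---------------------------------
    @_stage("network")
    def stage_network():
        de_mirnas = [r for r in mirna_records if r.direction in ("up", "down")]
        edges = network.build_module(de_mirnas, pairs, regulator=config.regulator)
        network.export_graph(edges, out / "network.sif", format="sif")
        network.export_graph(edges, out / "network.graphml", format="graphml")
        manifest = pd.read_csv(config.paths["perturbation_manifest"], sep="\t")
        base = config.paths["perturbation_manifest"].parent
        datasets = []
        for row in manifest.itertuples(index=False):
            table = read_differential_table(base / str(row.path))
            datasets.append(
                network.PerturbationDataset(
                    dataset_id=str(row.dataset_id),
                    kind=str(row.perturbation_kind),
                    records=tuple(table),
                )
            )
        targets = sorted({p.mrna_id for p in pairs})
        reference = {p.mrna_id: p.mrna_direction_p4 for p in pairs}
        report = network.concordance(
            targets, datasets, reference, fc_threshold=config.fc, alpha=config.alpha
        )
        return edges, report

    edges, report = stage_network()
    result.outputs["network_sif"] = out / "network.sif"
    result.outputs["network_graphml"] = out / "network.graphml"
    summary["n_edges"] = len(edges)
    summary["n_network_targets"] = report.n_network_targets
    summary["n_misexpressed_targets"] = report.n_misexpressed
    summary["fraction_misexpressed"] = report.fraction_misexpressed
    summary["fraction_same_direction"] = report.fraction_same_direction

    # --- qPCR (optional) --------------------------------------------------
    if "qpcr_table" in config.paths and config.qpcr_targets and config.qpcr_references:

        @_stage("qpcr")
        def stage_qpcr():
            table = qpcr.read_qpcr_table(config.paths["qpcr_table"])
            return qpcr.analyze_assays(table, list(config.qpcr_targets), list(config.qpcr_references))

        results = stage_qpcr()
        qdf = pd.DataFrame(
            {
                "assay": [r.assay_id for r in results],
                "rel_expr": [r.rel_expr for r in results],
                "ddct": [r.ddct for r in results],
                "p": [r.p for r in results],
                "direction": [r.direction for r in results],
            }
        )
        result.outputs["qpcr"] = out / "qpcr_results.tsv"
        qdf.to_csv(result.outputs["qpcr"], sep="\t", index=False)
        summary["n_qpcr_assays"] = len(results)

    # --- report + manifest ------------------------------------------------
    report_path = out / "summary.txt"
    with report_path.open("w", encoding="utf-8") as fh:
        for key in sorted(summary):
            fh.write(f"{key}: {_fmt(summary[key])}\n")
    result.outputs["summary"] = report_path

    manifest_path = out / "run_manifest.txt"
    with manifest_path.open("w", encoding="utf-8") as fh:
        for key in sorted(result.outputs):
            digest = hashlib.sha256(result.outputs[key].read_bytes()).hexdigest()
            fh.write(f"{key}: {result.outputs[key].name} sha256:{digest}\n")
    result.outputs["manifest"] = manifest_path
    return result
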