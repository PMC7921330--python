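"""Synthetic pipeline inputs with planted ground truth.

Generates every input the pipeline consumes - a miRNA intensity matrix, two
stage-specific mRNA differential tables, a scored target map, two
lens-enrichment tables, seven perturbation differential tables, a gene-set
annotation and a qPCR Ct plate - together with ground-truth tables listing the
planted differential miRNAs, true target pairs (with their expected priority
tier under the default rules) and the planted concordance labels.

Defaults mirror the study conditions the pipeline is meant to reproduce:
three biological replicates per group, 700 miRNA features on an
intensity-scaled array (most below intensity 5), 22 planted differential
miRNAs (14 up, 8 down) whose effect magnitudes span 1.2-2.2, three of which
are absent from the target map, seven perturbation models of which one is a
gain-of-function, and a 0.8 direction-agreement rate.  Intensities carry
multiplicative log-normal noise, which preserves positivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .core import (
    ExpressionMatrix,
    write_expression_matrix,
)
from .prioritize import TierRuleSet

__all__ = ["SyntheticDesign", "SyntheticDataset", "generate", "generate_qpcr"]

# Planted effect magnitudes (signed-ratio |FC|) for the default design: 14
# elevated and 8 reduced miRNAs spanning the 1.2-2.2 range typical of a
# small-replicate lens array comparison.
DEFAULT_UP_EFFECTS: dict[str, float] = {
    "mir-3107": 1.2, "mir-378b": 1.3, "mir-339": 1.4, "mir-384": 1.4,
    "mir-138": 1.5, "mir-1224": 1.5, "mir-1935": 1.6, "mir-328": 1.6,
    "mir-3102": 1.6, "mir-19a": 1.7, "mir-345": 1.8, "mir-1946a": 1.9,
    "mir-467a": 2.1, "mir-15a": 2.2,
}
DEFAULT_DOWN_EFFECTS: dict[str, float] = {
    "mir-34c": 1.2, "let-7b": 1.3, "mir-298": 1.3, "mir-409": 1.4,
    "mir-3092": 1.4, "mir-1947": 1.5, "mir-382": 1.7, "mir-1198": 1.7,
}

# Perturbation models: one gain-of-function among seven, as in comparative
# lens perturbation panels.
DEFAULT_PERTURBATIONS: tuple[tuple[str, str], ...] = (
    ("dnBrg1", "loss"),
    ("E2f1-E2f2-E2f3", "loss"),
    ("Foxe3-OE", "gain"),
    ("Hsf4", "loss"),
    ("Klf4", "loss"),
    ("Mafg-Mafk", "loss"),
    ("Notch2", "loss"),
)

DEFAULT_QPCR_DDCT: dict[str, float] = {
    # ddCt = -log2(planted fold change): elevated targets get negative ddCt
    "mir-15a": -math.log2(2.2),
    "mir-328": -math.log2(1.6),
    "mir-382": math.log2(1.7),
    "mir-1198": math.log2(1.7),
    "mir-1947": math.log2(1.5),
}
DEFAULT_QPCR_REFERENCES: tuple[str, ...] = ("mir-17", "Gapdh", "Actb")


@dataclass
class SyntheticDesign:
    """Parameters of the planted-structure generator.

    ``planted_up_mirnas`` / ``planted_down_mirnas`` map miRNA id to effect
    magnitude (> 1, applied multiplicatively to the case group - up-planted
    features are elevated, down-planted suppressed).  ``sigma`` is the
    log-normal noise scale on intensities.  ``target_density`` is the
    probability that a (planted miRNA, pool mRNA) pair is a true target;
    ``inverse_coupling`` scales how strongly a true target's fold change
    mirrors its miRNA's effect.  ``agreement`` is the per-target probability
    that its perturbation-model calls go in the reference direction.
    """

    n_mirnas: int = 700
    n_mrnas: int = 4000
    n_samples_per_group: int = 3
    planted_up_mirnas: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_UP_EFFECTS))
    planted_down_mirnas: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DOWN_EFFECTS))
    sigma: float = 0.1
    target_density: float = 0.01
    true_score_range: tuple[float, float] = (50.0, 100.0)
    decoy_score_range: tuple[float, float] = (0.0, 49.9)
    decoy_fraction: float = 0.3
    inverse_coupling: float = 1.0
    fc_jitter: float = 0.1
    p30_de_fraction: float = 0.6
    p30_coverage: float = 0.9
    background_de_fraction: float = 0.02
    enrichment_fraction: float = 0.5
    enrichment_extra_genes: int = 400
    expression_floor: float = 100.0
    mirnas_without_predictions: tuple[str, ...] = ("mir-3107", "mir-1935", "mir-3092")
    perturbations: tuple[tuple[str, str], ...] = DEFAULT_PERTURBATIONS
    perturbation_coverage: float = 0.95
    misexpression_rate: float = 0.4
    agreement: float = 0.8
    n_annotation_terms: int = 20
    qpcr_ddct: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_QPCR_DDCT))
    qpcr_references: tuple[str, ...] = DEFAULT_QPCR_REFERENCES
    n_bio_replicates: int = 3
    n_tech_replicates: int = 3
    sigma_bio: float = 0.15
    sigma_tech: float = 0.1
    rep_offset_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name, effects in (("up", self.planted_up_mirnas), ("down", self.planted_down_mirnas)):
            bad = {k: v for k, v in effects.items() if not v > 1.0}
            if bad:
                raise ValueError(f"planted {name} effects must be > 1: {bad}")
        if not 0.0 < self.target_density <= 1.0:
            raise ValueError("target_density must be in (0, 1]")
        for n, label in (
            (self.n_mirnas, "n_mirnas"),
            (self.n_mrnas, "n_mrnas"),
            (self.n_samples_per_group, "n_samples_per_group"),
        ):
            if n < 1:
                raise ValueError(f"{label} must be >= 1")
        n_planted = len(self.planted_up_mirnas) + len(self.planted_down_mirnas)
        if n_planted > self.n_mirnas:
            raise ValueError("more planted miRNAs than features")


@dataclass
class SyntheticDataset:
    """In-memory view of one generated dataset plus the paths written."""

    design: SyntheticDesign
    paths: dict[str, Path]
    matrix: ExpressionMatrix
    truth_mirnas: pd.DataFrame  # mirna, direction, effect, in_target_map
    truth_pairs: pd.DataFrame  # mirna, mrna, score, fc_p4, de_p30, enriched_p4/30, expected_tier
    truth_concordance: pd.DataFrame  # target, reference_direction, concordant, n_misexpressed


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def _mirna_matrix(design: SyntheticDesign) -> ExpressionMatrix:
    rng = _rng(design.seed, 0)
    planted = {**{m: ("up", e) for m, e in design.planted_up_mirnas.items()},
               **{m: ("down", e) for m, e in design.planted_down_mirnas.items()}}
    n_bg = design.n_mirnas - len(planted)
    feature_ids = sorted(planted) + [f"mir-b{i:04d}" for i in range(1, n_bg + 1)]
    # Intensity baselines: log10-exponential tail so most features sit at low
    # intensity, a few reach the thousands; planted features floored at 5 so
    # they are comfortably detected.
    base = 1.2 * 10 ** rng.exponential(scale=0.49, size=design.n_mirnas)
    base[: len(planted)] = np.maximum(base[: len(planted)], 5.0)
    n = design.n_samples_per_group
    samples = [f"KO{i + 1}" for i in range(n)] + [f"C{i + 1}" for i in range(n)]
    groups = {s: ("case" if s.startswith("KO") else "control") for s in samples}
    effect_col = np.ones(design.n_mirnas)
    for i, fid in enumerate(feature_ids[: len(planted)]):
        direction, e = planted[fid]
        effect_col[i] = e if direction == "up" else 1.0 / e
    noise = rng.lognormal(mean=0.0, sigma=design.sigma, size=(design.n_mirnas, 2 * n))
    values = base[:, None] * noise
    values[:, :n] *= effect_col[:, None]
    df = pd.DataFrame(np.round(values, 6), index=feature_ids, columns=samples)
    return ExpressionMatrix(values=df, group_of=groups)


def _plant_targets(design: SyntheticDesign) -> pd.DataFrame:
    """True-target table: one row per (planted miRNA with predictions, mRNA)."""
    rng = _rng(design.seed, 1)
    genes = [f"gene-{i:04d}" for i in range(1, design.n_mrnas + 1)]
    half = design.n_mrnas // 2
    pools = {"up": genes[:half], "down": genes[half:]}
    skip = set(design.mirnas_without_predictions)
    rows = []
    for direction, effects in (("up", design.planted_up_mirnas), ("down", design.planted_down_mirnas)):
        pool = pools[direction]
        for mirna in sorted(effects):
            if mirna in skip:
                continue
            hits = rng.random(len(pool)) < design.target_density
            for gene in np.array(pool)[hits]:
                # target fold change mirrors the miRNA effect, opposite sign
                mag = 1.0 + design.inverse_coupling * (effects[mirna] - 1.0)
                mag += rng.uniform(-design.fc_jitter, design.fc_jitter)
                mag = max(mag, 1.2)
                fc = -mag if direction == "up" else mag
                rows.append(
                    {
                        "mirna": mirna,
                        "mrna": str(gene),
                        "mirna_direction": direction,
                        "fc_p4": round(fc, 4),
                        "score": round(rng.uniform(*design.true_score_range), 1),
                    }
                )
    return pd.DataFrame(rows, columns=["mirna", "mrna", "mirna_direction", "fc_p4", "score"])


def _target_map(design: SyntheticDesign, truth_pairs: pd.DataFrame) -> pd.DataFrame:
    rng = _rng(design.seed, 2)
    genes = [f"gene-{i:04d}" for i in range(1, design.n_mrnas + 1)]
    true_keys = set(zip(truth_pairs["mirna"], truth_pairs["mrna"]))
    n_true = len(true_keys)
    n_decoys = round(n_true * design.decoy_fraction / max(1e-9, 1.0 - design.decoy_fraction))
    mirnas = sorted(set(truth_pairs["mirna"]))
    decoys = []
    lo, hi = design.decoy_score_range
    while len(decoys) < n_decoys and mirnas:
        mirna = mirnas[int(rng.integers(len(mirnas)))]
        gene = genes[int(rng.integers(len(genes)))]
        if (mirna, gene) not in true_keys:
            decoys.append({"mirna": mirna, "mrna": gene, "score": round(rng.uniform(lo, hi), 1)})
            true_keys.add((mirna, gene))  # no duplicate decoys either
    table = pd.concat(
        [truth_pairs[["mirna", "mrna", "score"]], pd.DataFrame(decoys, columns=["mirna", "mrna", "score"])],
        ignore_index=True,
    )
    return table.sort_values(["mirna", "mrna"], kind="stable").reset_index(drop=True)


def _mrna_tables(design: SyntheticDesign, truth_pairs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """P4 and P30 differential tables plus per-gene planted truth flags."""
    rng = _rng(design.seed, 3)
    genes = [f"gene-{i:04d}" for i in range(1, design.n_mrnas + 1)]
    fc_p4 = pd.Series(0.0, index=genes)
    # one planted fold change per gene (targets of several miRNAs of the same
    # direction group share the gene's single fold change: take the first)
    per_gene = truth_pairs.drop_duplicates("mrna").set_index("mrna")
    fc_p4.loc[per_gene.index] = per_gene["fc_p4"]
    de_p30 = pd.Series(False, index=genes)
    planted_genes = list(per_gene.index)
    de_p30.loc[per_gene.index] = rng.random(len(planted_genes)) < design.p30_de_fraction

    def build_table(stage: str) -> pd.DataFrame:
        rows = []
        for gene in genes:
            planted_fc = fc_p4.loc[gene]
            is_de = planted_fc != 0.0 if stage == "p4" else bool(de_p30.loc[gene]) and planted_fc != 0.0
            # background DE only touches non-planted genes so planted tier
            # evidence stays exactly as recorded in the ground truth
            if not is_de and planted_fc == 0.0 and rng.random() < design.background_de_fraction:
                mag = rng.uniform(1.2, 2.0)
                fc = mag if rng.random() < 0.5 else -mag
                p = rng.uniform(0.001, 0.049)
                direction = "up" if fc > 0 else "down"
            elif is_de:
                fc = float(planted_fc)
                p = rng.uniform(0.001, 0.04)
                direction = "up" if fc > 0 else "down"
            else:
                mag = rng.uniform(1.0, 1.15)
                fc = mag if rng.random() < 0.5 else -mag
                p = rng.uniform(0.06, 1.0)
                direction = "unchanged"
            mean_control = rng.uniform(50, 2000)
            mean_case = mean_control * abs(fc) if fc > 0 else mean_control / abs(fc)
            rows.append(
                {
                    "feature": gene,
                    "mean_case": round(mean_case, 3),
                    "mean_control": round(mean_control, 3),
                    "fc": round(fc, 4),
                    "p": round(p, 5),
                    "q": "",
                    "direction": direction,
                }
            )
        return pd.DataFrame(rows)

    table_p4 = build_table("p4")
    table_p30 = build_table("p30")
    keep = rng.random(len(table_p30)) < design.p30_coverage
    # planted P30-differential genes stay covered; coverage gaps hit the rest
    keep |= table_p30["feature"].isin(de_p30.index[de_p30]).to_numpy()
    table_p30 = table_p30[keep].reset_index(drop=True)
    gene_truth = pd.DataFrame({"mrna": genes, "fc_p4": fc_p4.to_numpy(), "de_p30": de_p30.to_numpy()})
    return table_p4, table_p30, gene_truth


def _enrichment_tables(design: SyntheticDesign, truth_genes: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    rng = _rng(design.seed, 4)
    planted = truth_genes[truth_genes["fc_p4"] != 0.0]["mrna"].tolist()
    others = truth_genes[truth_genes["fc_p4"] == 0.0]["mrna"].tolist()
    extra_n = min(design.enrichment_extra_genes, len(others))
    extra = list(rng.choice(others, size=extra_n, replace=False)) if extra_n else []
    flags = {}
    tables = {}
    for stage in ("p4", "p30"):
        enriched = rng.random(len(planted)) < design.enrichment_fraction
        flags[stage] = dict(zip(planted, enriched))
        rows = []
        for gene, is_enriched in zip(planted, enriched):
            if is_enriched:
                rows.append(
                    {
                        "gene": gene,
                        "enrichment_fc": round(rng.uniform(1.5, 8.0), 3),
                        "expression_intensity": round(rng.uniform(design.expression_floor, 3000), 2),
                    }
                )
            elif rng.random() < 0.5:
                # present but failing a criterion: low expression or depletion
                low_expr = rng.random() < 0.5
                rows.append(
                    {
                        "gene": gene,
                        "enrichment_fc": round(rng.uniform(1.5, 4.0) if low_expr else rng.uniform(0.2, 1.0), 3),
                        "expression_intensity": round(
                            rng.uniform(1, design.expression_floor * 0.99)
                            if low_expr
                            else rng.uniform(design.expression_floor, 2000),
                            2,
                        ),
                    }
                )
        for gene in extra:
            rows.append(
                {
                    "gene": gene,
                    "enrichment_fc": round(rng.uniform(0.2, 6.0), 3),
                    "expression_intensity": round(rng.uniform(1, 3000), 2),
                }
            )
        tables[stage] = (
            pd.DataFrame(rows, columns=["gene", "enrichment_fc", "expression_intensity"])
            .sort_values("gene", kind="stable")
            .reset_index(drop=True)
        )
    flag_df = pd.DataFrame(
        {
            "mrna": planted,
            "enriched_p4": [flags["p4"][g] for g in planted],
            "enriched_p30": [flags["p30"][g] for g in planted],
        }
    )
    return tables["p4"], tables["p30"], flag_df


def _perturbation_tables(
    design: SyntheticDesign, truth_genes: pd.DataFrame
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    rng = _rng(design.seed, 5)
    planted = truth_genes[truth_genes["fc_p4"] != 0.0]
    targets = planted["mrna"].tolist()
    ref_direction = {g: ("down" if fc < 0 else "up") for g, fc in zip(planted["mrna"], planted["fc_p4"])}
    concordant = dict(zip(targets, rng.random(len(targets)) < design.agreement))
    tables: dict[str, pd.DataFrame] = {}
    mis_count = {g: 0 for g in targets}
    for dataset_id, kind in design.perturbations:
        rows = []
        for gene in targets:
            if rng.random() >= design.perturbation_coverage:
                continue
            if rng.random() < design.misexpression_rate:
                intended = ref_direction[gene] if concordant[gene] else (
                    "up" if ref_direction[gene] == "down" else "down"
                )
                written = intended if kind == "loss" else ("up" if intended == "down" else "down")
                mag = rng.uniform(1.3, 3.0)
                fc = mag if written == "up" else -mag
                p = rng.uniform(0.0005, 0.04)
                direction = written
                mis_count[gene] += 1
            else:
                mag = rng.uniform(1.0, 1.15)
                fc = mag if rng.random() < 0.5 else -mag
                p = rng.uniform(0.06, 1.0)
                direction = "unchanged"
            mean_control = rng.uniform(50, 2000)
            mean_case = mean_control * abs(fc) if fc > 0 else mean_control / abs(fc)
            rows.append(
                {
                    "feature": gene,
                    "mean_case": round(mean_case, 3),
                    "mean_control": round(mean_control, 3),
                    "fc": round(fc, 4),
                    "p": round(p, 5),
                    "q": "",
                    "direction": direction,
                }
            )
        tables[dataset_id] = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {
            "target": targets,
            "reference_direction": [ref_direction[g] for g in targets],
            "concordant": [bool(concordant[g]) for g in targets],
            "n_misexpressed": [mis_count[g] for g in targets],
        }
    )
    return tables, truth


def _annotation(design: SyntheticDesign, truth_genes: pd.DataFrame) -> dict[str, tuple[str, list[str]]]:
    rng = _rng(design.seed, 6)
    genes = truth_genes["mrna"].tolist()
    planted = truth_genes[truth_genes["fc_p4"] != 0.0]["mrna"].tolist()
    terms: dict[str, tuple[str, list[str]]] = {}
    for i in range(design.n_annotation_terms):
        term_id = f"TERM:{i + 1:04d}"
        if i < 3 and planted:
            # planted-signal terms: mostly true-target genes
            k = min(len(planted), int(rng.integers(10, 30)))
            members = list(rng.choice(planted, size=k, replace=False))
            members += list(rng.choice(genes, size=max(2, k // 4), replace=False))
            name = f"planted process {i + 1}"
        else:
            k = int(rng.integers(10, 80))
            members = list(rng.choice(genes, size=min(k, len(genes)), replace=False))
            name = f"background process {i + 1}"
        terms[term_id] = (name, sorted(set(members)))
    return terms


def generate_qpcr(
    design: SyntheticDesign,
    planted_ddct: Optional[Mapping[str, float]] = None,
    seed_stream: int = 7,
) -> pd.DataFrame:
    """Simulate a long-format qPCR Ct table with nested replicate structure.

    Per well: ct = assay baseline + ddCt (case group, target assays only)
    + replicate-wide offset (RNA input, shared by all assays of a biological
    replicate, cancels in dCt) + per-assay biological effect (sd ``sigma_bio``)
    + technical noise (sd ``sigma_tech``).  Reference assays carry no group
    offset by construction.
    """
    ddct = dict(design.qpcr_ddct if planted_ddct is None else planted_ddct)
    refs = list(design.qpcr_references)
    if not refs:
        raise ValueError("at least one reference assay is required")
    overlap = set(refs) & set(ddct)
    if overlap:
        raise ValueError(f"reference assays cannot carry a planted ddCt: {sorted(overlap)}")
    rng = _rng(design.seed, seed_stream)
    assays = refs + sorted(ddct)
    baselines = {a: rng.uniform(18.0, 28.0) for a in assays}
    rows = []
    for group in ("case", "control"):
        for b in range(1, design.n_bio_replicates + 1):
            rep_offset = rng.normal(0.0, design.rep_offset_sd)
            for assay in assays:
                bio_effect = rng.normal(0.0, design.sigma_bio)
                shift = ddct.get(assay, 0.0) if group == "case" else 0.0
                for t in range(1, design.n_tech_replicates + 1):
                    ct = (
                        baselines[assay]
                        + shift
                        + rep_offset
                        + bio_effect
                        + rng.normal(0.0, design.sigma_tech)
                    )
                    rows.append(
                        {
                            "assay": assay,
                            "group": group,
                            "bio_rep": f"{group[0]}{b}",
                            "tech_rep": f"t{t}",
                            "ct": round(ct, 4),
                        }
                    )
    return pd.DataFrame(rows)


def _expected_tier(row: pd.Series, rules: TierRuleSet) -> str:
    flags = {
        "de_p4": True,
        "de_p30": bool(row["de_p30"]),
        "enriched_p4": bool(row["enriched_p4"]),
        "enriched_p30": bool(row["enriched_p30"]),
    }
    return rules.classify(flags)


def generate(design: SyntheticDesign, out_dir: str | Path) -> SyntheticDataset:
    """Write all pipeline inputs plus ground truth into ``out_dir``.

    Identical designs (including seed) produce bit-identical files.  Returns
    the dataset with in-memory truth tables; the manifest file lists every
    output with the design parameters.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    matrix = _mirna_matrix(design)
    truth_pairs = _plant_targets(design)
    target_map = _target_map(design, truth_pairs)
    table_p4, table_p30, gene_truth = _mrna_tables(design, truth_pairs)
    isyte_p4, isyte_p30, enr_flags = _enrichment_tables(design, gene_truth)
    pert_tables, truth_concordance = _perturbation_tables(design, gene_truth)
    annotation = _annotation(design, gene_truth)
    qpcr = generate_qpcr(design)

    paths: dict[str, Path] = {}

    paths["mirna_matrix"] = out / "mirna_matrix.tsv"
    write_expression_matrix(matrix, paths["mirna_matrix"])
    paths["groups"] = out / "groups.tsv"
    with paths["groups"].open("w", encoding="utf-8") as fh:
        for sample in matrix.sample_ids:
            fh.write(f"{sample}\t{matrix.group_of[sample]}\n")

    paths["mrna_de_p4"] = out / "mrna_de_p4.tsv"
    table_p4.to_csv(paths["mrna_de_p4"], sep="\t", index=False)
    paths["mrna_de_p30"] = out / "mrna_de_p30.tsv"
    table_p30.to_csv(paths["mrna_de_p30"], sep="\t", index=False)

    paths["targets"] = out / "target_map.tsv"
    target_map.to_csv(paths["targets"], sep="\t", index=False)

    paths["isyte_p4"] = out / "isyte_p4.tsv"
    isyte_p4.to_csv(paths["isyte_p4"], sep="\t", index=False)
    paths["isyte_p30"] = out / "isyte_p30.tsv"
    isyte_p30.to_csv(paths["isyte_p30"], sep="\t", index=False)

    paths["gmt"] = out / "annotation.gmt"
    with paths["gmt"].open("w", encoding="utf-8") as fh:
        for term_id in sorted(annotation):
            name, members = annotation[term_id]
            fh.write("\t".join([term_id, name, *members]) + "\n")

    manifest_rows = []
    for dataset_id, kind in design.perturbations:
        p = out / f"perturbation_{dataset_id}.tsv"
        pert_tables[dataset_id].to_csv(p, sep="\t", index=False)
        paths[f"perturbation_{dataset_id}"] = p
        manifest_rows.append({"dataset_id": dataset_id, "perturbation_kind": kind, "path": p.name})
    paths["perturbation_manifest"] = out / "perturbations.tsv"
    pd.DataFrame(manifest_rows).to_csv(paths["perturbation_manifest"], sep="\t", index=False)

    paths["qpcr"] = out / "qpcr_ct.tsv"
    qpcr.to_csv(paths["qpcr"], sep="\t", index=False)

    # ground truth
    rules = TierRuleSet.default()
    truth_pairs = truth_pairs.merge(gene_truth[["mrna", "de_p30"]], on="mrna", how="left")
    truth_pairs = truth_pairs.merge(enr_flags, on="mrna", how="left")
    for col in ("enriched_p4", "enriched_p30"):
        truth_pairs[col] = truth_pairs[col].fillna(False).astype(bool)
    truth_pairs["expected_tier"] = truth_pairs.apply(lambda r: _expected_tier(r, rules), axis=1)

    planted = {**{m: ("up", e) for m, e in design.planted_up_mirnas.items()},
               **{m: ("down", e) for m, e in design.planted_down_mirnas.items()}}
    truth_mirnas = pd.DataFrame(
        {
            "mirna": sorted(planted),
            "direction": [planted[m][0] for m in sorted(planted)],
            "effect": [planted[m][1] for m in sorted(planted)],
            "in_target_map": [m not in set(design.mirnas_without_predictions) for m in sorted(planted)],
        }
    )
    paths["truth_mirnas"] = out / "truth_mirnas.tsv"
    truth_mirnas.to_csv(paths["truth_mirnas"], sep="\t", index=False)
    paths["truth_pairs"] = out / "truth_pairs.tsv"
    truth_pairs.to_csv(paths["truth_pairs"], sep="\t", index=False)
    paths["truth_concordance"] = out / "truth_concordance.tsv"
    truth_concordance.to_csv(paths["truth_concordance"], sep="\t", index=False)

    manifest = out / "manifest.txt"
    with manifest.open("w", encoding="utf-8") as fh:
        for key in sorted(paths):
            fh.write(f"{key}: {paths[key].name}\n")
        for key, value in sorted(vars(design).items()):
            fh.write(f"design.{key}: {value}\n")
    paths["manifest"] = manifest

    return SyntheticDataset(
        design=design,
        paths=paths,
        matrix=matrix,
        truth_mirnas=truth_mirnas,
        truth_pairs=truth_pairs,
        truth_concordance=truth_concordance,
    )
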