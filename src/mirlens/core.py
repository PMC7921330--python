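"""Shared domain types, file I/O and the signed fold-change convention.

All downstream stages (differential calling, target pairing, prioritization,
network derivation) exchange the small value types defined here.  Fold changes
follow the signed-ratio convention common in microarray reporting: the ratio of
group means, printed as +ratio for up-regulation and -(1/ratio inverted) for
down-regulation, so the magnitude is always >= 1 (a gene halved reads -2.0, not
0.5).  Log transforms, where needed, are applied locally by the consumer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "DifferentialRecord",
    "TargetPrediction",
    "LensEnrichmentRecord",
    "AnnotationSet",
    "ParseError",
    "normalize_id",
    "signed_fold_change",
    "signed_log2",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_group_map",
    "read_gmt",
    "write_gmt",
    "read_differential_table",
    "write_differential_table",
    "read_target_predictions",
    "read_enrichment_table",
]

GROUPS = ("case", "control")


class ParseError(ValueError):
    """A malformed input file; the message names the offending line."""


def normalize_id(identifier: str) -> str:
    """Canonical form used for identifier matching.

    Identifiers are matched case-insensitively after trimming whitespace, but
    stored case-preserved: mixed-case gene symbols are common and occasionally
    inconsistent between sources, yet no fuzzy correction is attempted.
    """
    return identifier.strip().casefold()


def signed_fold_change(mean_case: float, mean_control: float) -> float:
    """Signed ratio fold change between two positive group means.

    Returns ``mean_case / mean_control`` when the case mean is the larger
    (up-regulation, positive sign) and ``-(mean_control / mean_case)`` when the
    control mean is the larger (down-regulation, negative sign).  The magnitude
    is always >= 1; equal means give +1.0.

    Raises
    ------
    ValueError
        If either mean is not strictly positive (the ratio is undefined on the
        intensity scale otherwise).
    """
    if not (mean_case > 0 and mean_control > 0):
        raise ValueError(
            f"signed_fold_change requires strictly positive means, "
            f"got case={mean_case!r} control={mean_control!r}"
        )
    if not (math.isfinite(mean_case) and math.isfinite(mean_control)):
        raise ValueError("signed_fold_change requires finite means")
    if mean_case >= mean_control:
        return mean_case / mean_control
    return -(mean_control / mean_case)


def signed_log2(fc: float) -> float:
    """Map a signed-ratio fold change to a symmetric log2 scale.

    +2.0 -> +1.0 and -2.0 -> -1.0, so up- and down-regulation of equal
    magnitude are equidistant from zero.  |fc| must be >= 1.
    """
    if abs(fc) < 1.0:
        raise ValueError(f"signed-ratio fold change must have |fc| >= 1, got {fc!r}")
    return math.copysign(math.log2(abs(fc)), fc)


@dataclass
class ExpressionMatrix:
    """Feature x sample intensity table with a two-group sample labelling.

    ``values`` is a pandas DataFrame indexed by feature id with one column per
    sample; intensities are finite and non-negative.  ``group_of`` maps every
    sample id to ``"case"`` or ``"control"``.
    """

    values: pd.DataFrame
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and (not np.all(np.isfinite(arr)) or (arr < 0).any()):
            raise ValueError("intensities must be finite and >= 0")
        for sample in self.values.columns:
            grp = self.group_of.get(sample)
            if grp not in GROUPS:
                raise ValueError(f"sample {sample!r} has no valid group (got {grp!r})")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group_of[s] == group]

    def require_replication(self, minimum: int = 2) -> None:
        """Every statistical operation needs >= ``minimum`` samples per group."""
        for group in GROUPS:
            n = len(self.samples_in(group))
            if n < minimum:
                raise ValueError(
                    f"group {group!r} has {n} samples; >= {minimum} required"
                )

    def group_means(self) -> pd.DataFrame:
        """Per-feature mean intensity per group, columns 'case' and 'control'."""
        return pd.DataFrame(
            {g: self.values[self.samples_in(g)].mean(axis=1) for g in GROUPS}
        )


@dataclass
class DifferentialRecord:
    """Per-feature two-group comparison result.

    ``fc`` follows the signed-ratio convention (|fc| >= 1).  ``direction`` is
    "up" when fc >= +threshold at p <= alpha, "down" when fc <= -threshold at
    p <= alpha, otherwise "unchanged".  ``p`` may be None for records built
    from intensity catalogs that carry no test (e.g. printed tables).
    """

    feature_id: str
    mean_case: float
    mean_control: float
    fc: float
    p: Optional[float]
    direction: str = "unchanged"
    q: Optional[float] = None

    def __post_init__(self) -> None:
        if self.p is not None and not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value out of [0,1]: {self.p!r}")
        if self.direction not in ("up", "down", "unchanged"):
            raise ValueError(f"invalid direction {self.direction!r}")


def call_direction(fc: float, p: Optional[float], fc_threshold: float, alpha: float) -> str:
    """Apply the direction rule: up iff fc >= +threshold and p <= alpha, etc."""
    if p is not None and p <= alpha:
        if fc >= fc_threshold:
            return "up"
        if fc <= -fc_threshold:
            return "down"
    return "unchanged"


@dataclass(frozen=True)
class TargetPrediction:
    """One predicted miRNA -> mRNA targeting relation with a confidence score.

    Scores live in [0, 100], the convention of sequence-based target
    prediction databases; downstream filtering keeps score >= 50 by default.
    """

    mirna_id: str
    mrna_id: str
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 100.0):
            raise ValueError(f"prediction score out of [0,100]: {self.score!r}")


@dataclass(frozen=True)
class LensEnrichmentRecord:
    """Lens-enriched-expression evidence for one gene at one postnatal stage.

    ``enrichment_fc`` is the fold-change of lens expression over a reference
    body-tissue pool; ``expression_intensity`` is the absolute lens expression
    level (fluorescence-intensity units).
    """

    gene_id: str
    stage: str
    enrichment_fc: float
    expression_intensity: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.expression_intensity) and self.expression_intensity >= 0):
            raise ValueError("expression_intensity must be finite and >= 0")


@dataclass
class AnnotationSet:
    """Gene-set annotation (term id -> name + member genes) over a universe."""

    terms: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)
    universe: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for term_id, (_, members) in self.terms.items():
            stray = members - self.universe
            if stray:
                raise ValueError(
                    f"term {term_id!r} has members outside the universe: {sorted(stray)[:5]}"
                )

    def members(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]

    def name(self, term_id: str) -> str:
        return self.terms[term_id][0]

    def __len__(self) -> int:
        return len(self.terms)


# ---------------------------------------------------------------------------
# File I/O.  The matrix reader is deliberately line-based so that malformed
# input is reported with its line number, which bulk CSV readers cannot do
# uniformly for ragged rows, non-numeric cells and duplicate ids.
# ---------------------------------------------------------------------------


def read_expression_matrix(path: str | Path, group_map: Mapping[str, str]) -> ExpressionMatrix:
    """Read a TSV intensity matrix (header = sample ids, first column = feature ids).

    ``group_map`` assigns every sample column to "case" or "control"; sample
    ids are matched case-insensitively after trimming.
    """
    path = Path(path)
    norm_groups = {normalize_id(k): v for k, v in group_map.items()}
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            raise ParseError(f"{path}:1: empty file")
        cols = header.rstrip("\n").split("\t")
        sample_ids = [c.strip() for c in cols[1:]]
        if not sample_ids:
            raise ParseError(f"{path}:1: header has no sample columns")
        groups: dict[str, str] = {}
        for s in sample_ids:
            if normalize_id(s) not in norm_groups:
                raise ParseError(f"{path}:1: sample {s!r} not present in group map")
            groups[s] = norm_groups[normalize_id(s)]
        n = len(sample_ids)
        feature_ids: list[str] = []
        seen: set[str] = set()
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {n + 1} fields, got {len(fields)}"
                )
            fid = fields[0].strip()
            key = normalize_id(fid)
            if key in seen:
                raise ParseError(f"{path}:{lineno}: duplicate feature id {fid!r}")
            seen.add(key)
            try:
                rows.append([float(v) for v in fields[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            feature_ids.append(fid)
    values = pd.DataFrame(rows, index=feature_ids, columns=sample_ids, dtype=float)
    try:
        return ExpressionMatrix(values=values, group_of=groups)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix as plain ASCII TSV (round-trips bit-identically)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("feature\t" + "\t".join(matrix.sample_ids) + "\n")
        for fid, row in matrix.values.iterrows():
            fh.write(fid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV of sample id -> group ('case'/'control')."""
    path = Path(path)
    out: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields")
            sample, group = fields[0].strip(), fields[1].strip()
            if group not in GROUPS:
                raise ParseError(f"{path}:{lineno}: unknown group {group!r}")
            out[sample] = group
    return out


def read_gmt(path: str | Path, universe: Optional[Iterable[str]] = None) -> AnnotationSet:
    """Read a GMT gene-set file (term, description, then member genes).

    The universe defaults to the union of all members unless supplied.
    An empty file yields a valid empty annotation.
    """
    path = Path(path)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    all_members: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            term_id, description = fields[0].strip(), fields[1].strip()
            members = frozenset(g.strip() for g in fields[2:] if g.strip())
            terms[term_id] = (description, members)
            all_members |= members
    uni = frozenset(universe) if universe is not None else frozenset(all_members)
    return AnnotationSet(terms=terms, universe=uni)


def write_gmt(annotation: AnnotationSet, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for term_id in sorted(annotation.terms):
            name, members = annotation.terms[term_id]
            fh.write("\t".join([term_id, name, *sorted(members)]) + "\n")


_DE_COLUMNS = ["feature", "mean_case", "mean_control", "fc", "p", "q", "direction"]


def write_differential_table(records: Sequence[DifferentialRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "feature": [r.feature_id for r in records],
            "mean_case": [r.mean_case for r in records],
            "mean_control": [r.mean_control for r in records],
            "fc": [r.fc for r in records],
            "p": [r.p if r.p is not None else np.nan for r in records],
            "q": [r.q if r.q is not None else np.nan for r in records],
            "direction": [r.direction for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_differential_table(path: str | Path) -> list[DifferentialRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("feature", "fc", "direction") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        p = getattr(row, "p", np.nan)
        q = getattr(row, "q", np.nan)
        records.append(
            DifferentialRecord(
                feature_id=str(row.feature),
                mean_case=float(getattr(row, "mean_case", np.nan)),
                mean_control=float(getattr(row, "mean_control", np.nan)),
                fc=float(row.fc),
                p=None if pd.isna(p) else float(p),
                direction=str(row.direction),
                q=None if pd.isna(q) else float(q),
            )
        )
    return records


def read_target_predictions(path: str | Path) -> list[TargetPrediction]:
    """Read a target map TSV with columns mirna, mrna, score."""
    df = pd.read_csv(path, sep="\t")
    for col in ("mirna", "mrna", "score"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return [
        TargetPrediction(str(r.mirna), str(r.mrna), float(r.score))
        for r in df.itertuples(index=False)
    ]


def read_enrichment_table(path: str | Path, stage: str) -> dict[str, LensEnrichmentRecord]:
    """Read a lens-enrichment TSV (gene, enrichment_fc, expression_intensity).

    Returns a mapping keyed by normalized gene id; the stored record keeps the
    original case.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "enrichment_fc", "expression_intensity"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    out: dict[str, LensEnrichmentRecord] = {}
    for r in df.itertuples(index=False):
        rec = LensEnrichmentRecord(
            gene_id=str(r.gene),
            stage=stage,
            enrichment_fc=float(r.enrichment_fc),
            expression_intensity=float(r.expression_intensity),
        )
        out[normalize_id(rec.gene_id)] = rec
    return out
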