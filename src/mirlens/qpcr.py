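"""Relative quantification (2^-ddCt) and two-level nested ANOVA for qPCR plates.

Each assay is normalized within a biological replicate against the arithmetic
mean of the reference-assay Ct values (equivalent to the geometric mean of
their linear quantities), giving a dCt per replicate; ddCt is the difference
of group mean dCt (case minus control) and relative expression is 2^-ddCt.

Significance uses the two-level nested design: technical replicates are
nested in biological replicates, and the group effect is tested against the
biological-replicate(group) mean square, the error stratum at which animals -
not wells - are the unit of replication.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GROUPS, ParseError, normalize_id

__all__ = [
    "QpcrTable",
    "RelativeExpressionResult",
    "NestedAnovaResult",
    "read_qpcr_table",
    "delta_delta_ct",
    "nested_anova",
    "analyze_assays",
]


@dataclass
class QpcrTable:
    """Long-format Ct measurements: (assay, group, bio rep, tech rep, ct)."""

    data: pd.DataFrame  # columns: assay, group, bio_rep, tech_rep, ct

    def __post_init__(self) -> None:
        required = {"assay", "group", "bio_rep", "tech_rep", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"qPCR table missing columns {sorted(missing)}")
        bad = set(self.data["group"].unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown groups {sorted(bad)}")
        if not np.all(np.isfinite(self.data["ct"].to_numpy(dtype=float))):
            raise ValueError("Ct values must be finite")

    def assays(self) -> list[str]:
        return sorted(self.data["assay"].unique())

    def subset(self, assay: str) -> pd.DataFrame:
        mask = self.data["assay"].map(normalize_id) == normalize_id(assay)
        return self.data[mask]


@dataclass
class RelativeExpressionResult:
    assay_id: str
    rel_expr: float  # 2^-ddCt
    ddct: float
    p: float | None
    direction: str

    def __post_init__(self) -> None:
        if not self.rel_expr > 0:
            raise ValueError("relative expression must be > 0")


@dataclass
class NestedAnovaResult:
    """Variance decomposition for dCt ~ group + bio_rep(group) + residual."""

    ss_group: float
    ss_bio: float
    ss_resid: float
    df_group: int
    df_bio: int
    df_resid: int
    f_group: float
    p_group: float

    @property
    def ss_total(self) -> float:
        return self.ss_group + self.ss_bio + self.ss_resid


def read_qpcr_table(path: str | Path) -> QpcrTable:
    df = pd.read_csv(path, sep="\t", dtype={"assay": str, "group": str, "bio_rep": str, "tech_rep": str})
    try:
        return QpcrTable(df)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def _reference_means(table: QpcrTable, reference_assays: Sequence[str]) -> pd.Series:
    """Mean reference Ct per (group, bio_rep): each reference's technical mean,
    then the arithmetic mean across references."""
    per_ref = []
    for ref in reference_assays:
        sub = table.subset(ref)
        if sub.empty:
            raise ValueError(f"reference assay {ref!r} missing from the table")
        per_ref.append(sub.groupby(["group", "bio_rep"])["ct"].mean().rename(ref))
    combined = pd.concat(per_ref, axis=1)
    if combined.isna().any().any():
        raise ValueError("a reference assay is missing for some (group, bio_rep) stratum")
    return combined.mean(axis=1)


def _delta_ct(table: QpcrTable, target_assay: str, reference_assays: Sequence[str]) -> pd.DataFrame:
    """Per-technical-replicate dCt for the target (ct minus stratum reference mean)."""
    target = table.subset(target_assay)
    if target.empty:
        raise ValueError(f"target assay {target_assay!r} missing from the table")
    for group in GROUPS:
        if group not in set(target["group"]):
            raise ValueError(f"target assay {target_assay!r} has no {group!r} measurements")
    refs = _reference_means(table, reference_assays)
    out = target.copy()
    keys = list(zip(out["group"], out["bio_rep"]))
    missing = [k for k in keys if k not in refs.index]
    if missing:
        raise ValueError(f"no reference measurements for strata {sorted(set(missing))}")
    out["dct"] = out["ct"].to_numpy(dtype=float) - refs.loc[keys].to_numpy(dtype=float)
    return out


def delta_delta_ct(
    table: QpcrTable,
    target_assay: str,
    reference_assays: Sequence[str],
    fc_threshold_log2: float = 0.0,
) -> RelativeExpressionResult:
    """Point estimate of relative expression for one assay.

    dCt per biological replicate is the technical-mean target Ct minus the
    combined reference Ct of that replicate; ddCt = mean dCt(case) - mean
    dCt(control); relative expression = 2^-ddCt (higher Ct = less template,
    hence the sign).  ``direction`` is up/down by the sign of log2(rel_expr)
    against ``fc_threshold_log2``.  The p-value slot is filled by
    :func:`analyze_assays`.
    """
    dct = _delta_ct(table, target_assay, reference_assays)
    bio_means = dct.groupby(["group", "bio_rep"])["dct"].mean()
    group_means = bio_means.groupby(level="group").mean()
    ddct = float(group_means["case"] - group_means["control"])
    rel = float(2.0 ** (-ddct))
    log2_rel = -ddct
    if log2_rel > fc_threshold_log2:
        direction = "up"
    elif log2_rel < -fc_threshold_log2:
        direction = "down"
    else:
        direction = "unchanged"
    return RelativeExpressionResult(
        assay_id=target_assay, rel_expr=rel, ddct=ddct, p=None, direction=direction
    )


def nested_anova(
    table: QpcrTable,
    target_assay: str,
    reference_assays: Sequence[str] | None = None,
) -> NestedAnovaResult:
    """Two-level nested ANOVA on dCt (or raw Ct when no references given).

    Model: response ~ group + bio_rep(group), technical replicates as the
    residual stratum.  The group F statistic uses MS_bio(group) as its error
    term; for unbalanced designs the group df is g-1 and the nested df is
    sum(b_i) - g.  Requires >= 2 biological replicates per group and >= 2
    technical replicates in at least one biological replicate (else the
    residual stratum is empty, which is allowed for the group test itself).
    """
    if reference_assays:
        data = _delta_ct(table, target_assay, reference_assays)
        response = data["dct"].to_numpy(dtype=float)
    else:
        data = table.subset(target_assay)
        if data.empty:
            raise ValueError(f"target assay {target_assay!r} missing from the table")
        response = data["ct"].to_numpy(dtype=float)

    groups = data["group"].to_numpy()
    bio = data["bio_rep"].astype(str).to_numpy()
    for g in GROUPS:
        n_bio = len(set(bio[groups == g]))
        if n_bio < 2:
            raise ValueError(
                f"group {g!r} has {n_bio} biological replicate(s); >= 2 required "
                f"for the nested error term"
            )

    grand = response.mean()
    ss_group = 0.0
    ss_bio = 0.0
    ss_resid = 0.0
    n_bio_total = 0
    for g in sorted(set(groups)):
        gmask = groups == g
        gmean = response[gmask].mean()
        ss_group += gmask.sum() * (gmean - grand) ** 2
        for b in sorted(set(bio[gmask])):
            bmask = gmask & (bio == b)
            bmean = response[bmask].mean()
            ss_bio += bmask.sum() * (bmean - gmean) ** 2
            ss_resid += float(((response[bmask] - bmean) ** 2).sum())
            n_bio_total += 1
    n_groups = len(set(groups))
    df_group = n_groups - 1
    df_bio = n_bio_total - n_groups
    df_resid = len(response) - n_bio_total
    ms_group = ss_group / df_group
    ms_bio = ss_bio / df_bio
    if ms_bio == 0.0:
        f_group = float("inf") if ms_group > 0 else 0.0
        p_group = 0.0 if ms_group > 0 else 1.0
    else:
        f_group = ms_group / ms_bio
        p_group = float(stats.f.sf(f_group, df_group, df_bio))
    return NestedAnovaResult(
        ss_group=float(ss_group),
        ss_bio=float(ss_bio),
        ss_resid=float(ss_resid),
        df_group=df_group,
        df_bio=df_bio,
        df_resid=df_resid,
        f_group=float(f_group),
        p_group=p_group,
    )


def analyze_assays(
    table: QpcrTable,
    target_assays: Sequence[str],
    reference_assays: Sequence[str],
) -> list[RelativeExpressionResult]:
    """Relative expression + nested-ANOVA p for each target assay."""
    results = []
    for assay in target_assays:
        res = delta_delta_ct(table, assay, reference_assays)
        res.p = nested_anova(table, assay, reference_assays).p_group
        results.append(res)
    return results
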