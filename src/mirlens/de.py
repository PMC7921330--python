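"""Normalization, differential miRNA calling, detection summary, high-expression catalog.

The pipeline ingests feature-level intensity matrices (probe summarization and
background correction happen upstream) and offers between-array quantile
normalization.  Differential calling uses Welch's unequal-variance t-test on
log2 intensities with the signed-ratio fold change computed on the linear
intensity scale; an optional variance-shrinkage weight pools per-feature
variances toward the global mean for small-replicate designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import (
    DifferentialRecord,
    ExpressionMatrix,
    call_direction,
    signed_fold_change,
)

__all__ = [
    "DetectionSummary",
    "quantile_normalize",
    "differential_test",
    "summarize_detection",
    "highly_expressed",
]

DEFAULT_BIN_EDGES = (5.0, 10.0, 50.0, 100.0, 500.0)


@dataclass
class DetectionSummary:
    """Detected-feature count and intensity histogram over control-group means."""

    n_detected: int
    intensity_min: float
    intensity_max: float
    bin_edges: tuple[float, ...]
    bin_counts: tuple[int, ...]

    def fraction_at_or_below(self, intensity: float) -> float:
        """Fraction of detected features with control mean <= ``intensity``."""
        if self.n_detected == 0:
            return float("nan")
        return self._n_at_or_below / self.n_detected

    _n_at_or_below: int = 0


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Between-array quantile normalization.

    After normalization every sample's sorted intensity vector equals the
    cross-sample mean of sorted vectors; within-sample feature ranks are
    preserved.  Ties receive the mean of the reference values they span
    (average-rank interpolation), so a matrix whose columns are already
    identical is a fixed point.
    """
    if len(matrix.sample_ids) < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    x = matrix.values.to_numpy(dtype=float)
    n = x.shape[0]
    if n == 0:
        return ExpressionMatrix(values=matrix.values.copy(), group_of=dict(matrix.group_of))
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(x.shape[1]):
        ranks = stats.rankdata(x[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, reference)
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values=values, group_of=dict(matrix.group_of))


def differential_test(
    matrix: ExpressionMatrix,
    fc_threshold: float = 1.2,
    alpha: float = 0.05,
    shrink: float = 0.0,
) -> list[DifferentialRecord]:
    """Two-group differential test per feature.

    Group means are taken on the linear intensity scale and converted to a
    signed-ratio fold change; the p-value comes from a two-sided Welch t-test
    on log2(intensity + eps).  ``shrink`` in [0, 1] optionally pulls each
    feature's within-group variances toward the across-feature mean variance
    before the t statistic is formed (0 = plain Welch).  Features with zero
    variance in both groups and equal means get p = 1 by convention.

    BH-adjusted q-values are reported alongside, but the direction call uses
    the raw p (no multiple-testing correction in the default call).
    """
    matrix.require_replication(2)
    if not 0.0 <= shrink <= 1.0:
        raise ValueError("shrink must be in [0, 1]")
    case_cols = matrix.samples_in("case")
    ctrl_cols = matrix.samples_in("control")
    lin = matrix.values
    eps = 1e-9
    log_case = np.log2(lin[case_cols].to_numpy(dtype=float) + eps)
    log_ctrl = np.log2(lin[ctrl_cols].to_numpy(dtype=float) + eps)

    if shrink == 0.0:
        with warnings.catch_warnings():
            # near-constant features trip scipy's precision warning; their
            # p-values are overwritten by the zero-variance convention below
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(log_case, log_ctrl, axis=1, equal_var=False)
        pvals = np.asarray(res.pvalue, dtype=float)
    else:
        pvals = _shrunken_welch_p(log_case, log_ctrl, shrink)

    mean_case_log = log_case.mean(axis=1)
    mean_ctrl_log = log_ctrl.mean(axis=1)
    var_zero = (log_case.var(axis=1) == 0) & (log_ctrl.var(axis=1) == 0)
    pvals = np.where(
        np.isnan(pvals) | var_zero,
        np.where(np.isclose(mean_case_log, mean_ctrl_log), 1.0, 0.0),
        pvals,
    )
    pvals = np.clip(pvals, 0.0, 1.0)
    qvals = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else np.array([])

    means = matrix.group_means()
    records: list[DifferentialRecord] = []
    floor = 1e-12  # ratio undefined at zero intensity; guard degenerate features
    for i, fid in enumerate(matrix.feature_ids):
        mc = float(means["case"].iloc[i])
        mo = float(means["control"].iloc[i])
        fc = signed_fold_change(max(mc, floor), max(mo, floor))
        p = float(pvals[i])
        records.append(
            DifferentialRecord(
                feature_id=fid,
                mean_case=mc,
                mean_control=mo,
                fc=fc,
                p=p,
                q=float(qvals[i]),
                direction=call_direction(fc, p, fc_threshold, alpha),
            )
        )
    return records


def _shrunken_welch_p(a: np.ndarray, b: np.ndarray, w: float) -> np.ndarray:
    """Welch t with per-feature variances shrunk toward their across-feature mean."""
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    va = (1 - w) * va + w * va.mean()
    vb = (1 - w) * vb + w * vb.mean()
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2.0 * stats.t.sf(np.abs(t), df)


def summarize_detection(
    matrix: ExpressionMatrix,
    detect_floor: float = 1.0,
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> DetectionSummary:
    """Count detected features and bin them by control-group mean intensity.

    A feature is detected when its control-group mean exceeds ``detect_floor``.
    ``bin_edges`` are the strictly increasing internal edges; bin k collects
    means <= edge k (first bin) or in (edge k-1, edge k], with a final
    open-ended bin above the last edge.
    """
    edges = tuple(float(e) for e in bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin_edges must be strictly increasing")
    means = matrix.group_means()["control"].to_numpy(dtype=float)
    detected = means[means > detect_floor]
    if detected.size == 0:
        return DetectionSummary(0, float("nan"), float("nan"), edges, (0,) * (len(edges) + 1))
    full_edges = np.array([-np.inf, *edges, np.inf])
    counts, _ = np.histogram(detected, bins=full_edges)
    summary = DetectionSummary(
        n_detected=int(detected.size),
        intensity_min=float(detected.min()),
        intensity_max=float(detected.max()),
        bin_edges=edges,
        bin_counts=tuple(int(c) for c in counts),
    )
    summary._n_at_or_below = int((detected <= edges[0]).sum())
    return summary


def highly_expressed(
    records: Sequence[DifferentialRecord],
    intensity_threshold: float = 500.0,
    alpha: float = 0.05,
    detection_p: Optional[dict[str, float]] = None,
) -> list[DifferentialRecord]:
    """Catalog of robustly expressed features in the control-group lens.

    Keeps records with control mean >= ``intensity_threshold``, sorted by
    descending intensity with ties broken by feature id for a stable order.
    The significance clause of the catalog definition refers to confident
    detection above array background, not to the two-group test (robustly
    expressed features are typically unaltered): when a per-feature detection
    p-value map is supplied it is applied at ``alpha``; the differential p
    carried on the records is never used here.
    """
    kept = [
        r
        for r in records
        if r.mean_control >= intensity_threshold
        and (detection_p is None or detection_p.get(r.feature_id, 0.0) <= alpha)
    ]
    return sorted(kept, key=lambda r: (-r.mean_control, r.feature_id))
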