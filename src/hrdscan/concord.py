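"""Concordance statistics: AUROC (DeLong CI), AUPRC, rank correlations.

AUROC is the Mann-Whitney estimator (ties count one half) with a 95% CI
from the DeLong structural-components variance; an AUROC whose CI does not
overlap 0.5 indicates a directional relationship.  AUPRC follows the
average-precision (step-wise) convention and is reported next to its
baseline, the positive-class prevalence.  Spearman and Pearson coefficients
carry Fisher-z confidence intervals with standard error ``1/sqrt(n - 3)``.

:func:`run_concordance_panel` applies the battery per platform and metric
against binary labels and a continuous reference score, joining samples
pairwise-complete (missing samples are dropped, never imputed, with the
drop counts logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score

logger = logging.getLogger(__name__)

__all__ = [
    "AurocResult",
    "AuprcResult",
    "CorrelationResult",
    "auroc",
    "auprc",
    "correlations",
    "run_concordance_panel",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class AurocResult:
    estimate: float
    ci_low: float
    ci_high: float
    n: int
    n_positive: int

    @property
    def overlaps_half(self) -> bool:
        """True when the CI covers 0.5 (no directional call possible)."""
        return self.ci_low <= 0.5 <= self.ci_high


@dataclass(frozen=True)
class AuprcResult:
    estimate: float
    baseline: float
    n: int
    n_positive: int


@dataclass(frozen=True)
class CorrelationResult:
    spearman: float
    spearman_ci: tuple[float, float]
    pearson: float
    pearson_ci: tuple[float, float]
    n: int


def _check_binary(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(scores) != len(labels):
        raise ValueError("scores and labels differ in length")
    if len(scores) < 2:
        raise ValueError("need at least 2 observations")
    if labels.min() == labels.max():
        raise ValueError("degenerate labels: both classes must be present")
    return scores, labels


def auroc(scores, labels) -> AurocResult:
    """Mann-Whitney AUROC with DeLong 95% CI.

    Per-observation placements: for each positive, the fraction of negatives
    scored below it (ties one half), and symmetrically for negatives.  The
    estimate is the mean placement; the variance combines the two placement
    sample variances (DeLong, Biometrics 1988).
    """
    scores, labels = _check_binary(scores, labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)

    ranks = stats.rankdata(scores)  # midranks handle ties
    est = (ranks[labels == 1].sum() - m * (m + 1) / 2.0) / (m * n)

    # structural components
    v10 = np.empty(m)
    for i, x in enumerate(pos):
        v10[i] = (np.count_nonzero(neg < x) + 0.5 * np.count_nonzero(neg == x)) / n
    v01 = np.empty(n)
    for j, y in enumerate(neg):
        v01[j] = (np.count_nonzero(pos > y) + 0.5 * np.count_nonzero(pos == y)) / m
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    half = _Z95 * np.sqrt(var)
    return AurocResult(
        estimate=float(est),
        ci_low=float(max(0.0, est - half)),
        ci_high=float(min(1.0, est + half)),
        n=m + n,
        n_positive=m,
    )


def auprc(scores, labels) -> AuprcResult:
    """Average precision with the prevalence baseline."""
    scores, labels = _check_binary(scores, labels)
    return AuprcResult(
        estimate=float(average_precision_score(labels, scores)),
        baseline=float(labels.mean()),
        n=len(labels),
        n_positive=int(labels.sum()),
    )


def _fisher_ci(r: float, n: int) -> tuple[float, float]:
    if n <= 3 or abs(r) >= 1.0:
        return (float(r), float(r))
    z = np.arctanh(r)
    half = _Z95 / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def correlations(x, y) -> CorrelationResult:
    """Spearman (average-rank ties) and Pearson with Fisher-z 95% CIs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: constant input vector")
    rho = float(stats.spearmanr(x, y).statistic)
    r = float(stats.pearsonr(x, y).statistic)
    return CorrelationResult(
        spearman=rho,
        spearman_ci=_fisher_ci(rho, len(x)),
        pearson=r,
        pearson_ci=_fisher_ci(r, len(x)),
        n=len(x),
    )


SCAR_METRICS = ("loh", "tai", "lst", "hrd_sum")


def _aligned(a: pd.DataFrame, b: pd.DataFrame, what: str) -> pd.DataFrame:
    merged = a.merge(b, on="sample_id", how="inner")
    dropped = max(len(a), len(b)) - len(merged)
    if dropped:
        logger.info("%s: dropped %d unmatched samples (pairwise-complete)", what, dropped)
    if merged.empty:
        raise ValueError(f"{what}: empty intersection of sample IDs")
    return merged


def run_concordance_panel(
    platform_scores: Mapping[str, pd.DataFrame],
    reference: pd.DataFrame,
    labels: pd.DataFrame | None = None,
    cutoff: int = 42,
) -> pd.DataFrame:
    """Concordance battery per platform and scar metric.

    Parameters
    ----------
    platform_scores
        platform name -> DataFrame with columns ``sample_id, loh, tai, lst,
        hrd_sum``.
    reference
        DataFrame with columns ``sample_id, score`` (continuous reference
        metric); it is also dichotomized at ``cutoff`` as a binary
        comparator.
    labels
        Optional DataFrame with columns ``sample_id, label`` (0/1), e.g. a
        mutation-status annotation.

    Returns a tidy table: one row per (platform, metric, comparator, kind)
    with estimate, CI bounds, baseline and sample counts.
    """
    comparators: list[tuple[str, pd.DataFrame]] = []
    ref = reference.rename(columns={"score": "reference_score"})
    dichot = ref[["sample_id"]].copy()
    dichot["label"] = (ref["reference_score"] >= cutoff).astype(int)
    comparators.append(("reference_positive", dichot))
    if labels is not None:
        comparators.append(("class_label", labels[["sample_id", "label"]]))

    rows = []
    for platform, table in platform_scores.items():
        for metric in SCAR_METRICS:
            scores = table[["sample_id", metric]]
            for comp_name, comp in comparators:
                merged = _aligned(scores, comp, f"{platform}/{metric} vs {comp_name}")
                roc = auroc(merged[metric], merged["label"])
                pr = auprc(merged[metric], merged["label"])
                rows.append(
                    (platform, metric, comp_name, "auroc", roc.estimate, roc.ci_low,
                     roc.ci_high, np.nan, roc.n, roc.n_positive)
                )
                rows.append(
                    (platform, metric, comp_name, "auprc", pr.estimate, np.nan, np.nan,
                     pr.baseline, pr.n, pr.n_positive)
                )
            merged = _aligned(scores, ref, f"{platform}/{metric} vs reference")
            corr = correlations(merged[metric], merged["reference_score"])
            rows.append(
                (platform, metric, "reference_score", "spearman", corr.spearman,
                 corr.spearman_ci[0], corr.spearman_ci[1], np.nan, corr.n, np.nan)
            )
            rows.append(
                (platform, metric, "reference_score", "pearson", corr.pearson,
                 corr.pearson_ci[0], corr.pearson_ci[1], np.nan, corr.n, np.nan)
            )
    return pd.DataFrame(
        rows,
        columns=["platform", "metric", "comparator", "kind", "estimate", "ci_low",
                 "ci_high", "baseline", "n", "n_positive"],
    )
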