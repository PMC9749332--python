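"""Marker-downsampling experiment: score stability versus SNP density.

Markers are subsampled uniformly at random (the design's "randomly") to a
fixed grid of fourteen proportions, ten seeded replicates per proportion.
Each replicate reruns the full pipeline (GC correction, joint segmentation,
purity/ploidy fit, integer calling, scar scoring) on every sample and
records the Spearman correlation of the resulting HRD sums against a fixed
external reference score across the samples that remained evaluable, plus
the evaluable fraction.  The per-proportion summary statistic is the median
over the ten replicates.  The optimal proportion is the smallest one
attaining the maximum median correlation among proportions whose median
evaluability clears a configurable floor.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import gc_ascn, scars
from .genome import GenomeBuild
from .simulate import MarkerSignal

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_PROPORTIONS",
    "DownsamplingCurve",
    "downsample_markers",
    "run_downsampling_experiment",
    "select_optimal_proportion",
]

#: the prespecified proportion grid (0.25% .. 90%)
DEFAULT_PROPORTIONS = (
    0.0025, 0.005, 0.01, 0.025, 0.05, 0.10, 0.20,
    0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90,
)
DEFAULT_N_REPS = 10
DEFAULT_EVALUABILITY_FLOOR = 0.95


def _replicate_seed(base_seed: int, proportion: float, rep: int) -> int:
    """Deterministic, platform-stable replicate seed (< 2^31)."""
    tag = f"{proportion:.6g}:{rep}".encode()
    return (int(base_seed) * 1_000_003 + zlib.crc32(tag)) % (2**31)


def downsample_markers(
    signal: MarkerSignal, proportion: float, seed: int | np.random.Generator
) -> MarkerSignal:
    """Uniform random marker subset of size ``round(proportion * n)``,
    order preserved; deterministic under ``seed``."""
    if not 0 < proportion <= 1:
        raise ValueError("proportion must be in (0, 1]")
    n = signal.n_markers
    k = int(round(proportion * n))
    if k >= n:
        return MarkerSignal(signal.sample_id, signal.frame.copy())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=k, replace=False))
    n_chrom = signal.frame["chrom"].nunique()
    if k < 2 * n_chrom:
        logger.warning(
            "%s: only %d markers kept (< 2 per chromosome on average); "
            "sample may become unevaluable",
            signal.sample_id, k,
        )
    return MarkerSignal(signal.sample_id, signal.frame.iloc[keep].reset_index(drop=True))


@dataclass(frozen=True)
class DownsamplingCurve:
    """Replicate-level results plus the per-proportion median summary."""

    replicates: pd.DataFrame = field(repr=False)  # proportion, rep, rho, evaluable_frac
    summary: pd.DataFrame = field(repr=False)  # proportion, median_rho, median_evaluable
    optimal_proportion: float | None


def _score_replicate(
    signals: Sequence[MarkerSignal],
    build: GenomeBuild,
    proportion: float,
    seed: int,
    pipeline_kwargs: dict,
) -> tuple[dict[str, int], float]:
    """HRD sums of evaluable samples for one downsampling draw."""
    rng = np.random.default_rng(seed)
    hrd: dict[str, int] = {}
    n_ok = 0
    for signal in signals:
        sub = downsample_markers(signal, proportion, rng)
        try:
            result = gc_ascn.process_sample(sub, build, **pipeline_kwargs)
        except gc_ascn.UninformativeSampleError:
            continue
        sc = scars.score_sample(result.profile, build)
        hrd[signal.sample_id] = sc.hrd_sum
        n_ok += 1
    return hrd, n_ok / max(len(signals), 1)


def run_downsampling_experiment(
    signals: Sequence[MarkerSignal],
    build: GenomeBuild,
    reference: Mapping[str, float],
    proportions: Sequence[float] = DEFAULT_PROPORTIONS,
    n_reps: int = DEFAULT_N_REPS,
    base_seed: int = 0,
    evaluability_floor: float = DEFAULT_EVALUABILITY_FLOOR,
    **pipeline_kwargs,
) -> DownsamplingCurve:
    """The full proportion x replicate grid with median summaries.

    ``reference`` maps sample_id to the fixed continuous reference score
    (truth HRD sums in simulation mode, or any user-supplied column).
    Replicates with fewer than 3 evaluable samples record an undefined
    (NaN) correlation; per-proportion medians skip undefined replicates.
    """
    rows = []
    for proportion in proportions:
        for rep in range(n_reps):
            seed = _replicate_seed(base_seed, proportion, rep)
            hrd, evaluable = _score_replicate(
                signals, build, proportion, seed, pipeline_kwargs
            )
            ids = [s for s in hrd if s in reference]
            if len(ids) >= 3:
                x = np.array([hrd[s] for s in ids], dtype=float)
                y = np.array([reference[s] for s in ids], dtype=float)
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    rho = np.nan
                else:
                    rho = float(stats.spearmanr(x, y).statistic)
            else:
                rho = np.nan
            rows.append((proportion, rep, rho, evaluable))
    replicates = pd.DataFrame(rows, columns=["proportion", "rep", "rho", "evaluable_frac"])
    summary = (
        replicates.groupby("proportion", as_index=False)
        .agg(median_rho=("rho", "median"), median_evaluable=("evaluable_frac", "median"))
        .sort_values("proportion", ignore_index=True)
    )
    optimal = select_optimal_proportion(summary, evaluability_floor)
    return DownsamplingCurve(replicates=replicates, summary=summary, optimal_proportion=optimal)


def select_optimal_proportion(
    summary: pd.DataFrame, evaluability_floor: float = DEFAULT_EVALUABILITY_FLOOR
) -> float | None:
    """Smallest proportion maximizing median rho, subject to evaluability.

    Ties (exact equality of the median) break toward the smaller proportion;
    returns None when no proportion clears the floor with a defined rho.
    """
    ok = summary[
        (summary["median_evaluable"] >= evaluability_floor) & summary["median_rho"].notna()
    ]
    if ok.empty:
        return None
    best = ok["median_rho"].max()
    return float(ok.loc[ok["median_rho"] >= best - 1e-12, "proportion"].min())
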