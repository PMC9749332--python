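"""Top-level pipeline: simulate -> correct -> segment -> fit -> call -> score
-> concordance (and optionally the downsampling experiment), with a run
manifest making every artifact auditable.

All randomness flows from the config seed; rerunning the same config
produces byte-identical outputs (the manifest carries no timestamps).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__, concord, downsample, gc_ascn, scars
from .genome import GenomeBuild, make_marker_map
from .simulate import simulate_cohort
from .io import (
    PipelineConfig,
    write_build_tsv,
    write_marker_tsv,
    write_scores_tsv,
    write_seg_tsv,
)

logger = logging.getLogger(__name__)

__all__ = ["pipeline_run"]


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def pipeline_run(config: PipelineConfig, out_dir) -> dict:
    """Execute the configured pipeline into ``out_dir``; returns the manifest.

    On stage failure the partial outputs are moved under ``failed/`` and the
    error re-raised with the failing stage named.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    stage = "setup"
    try:
        manifest: dict = {
            "version": __version__,
            "config": config.to_dict(),
            "stages": {},
        }

        stage = "simulate"
        build = GenomeBuild.hg19()
        write_build_tsv(build, out / "build.tsv")
        marker_map = make_marker_map(build, config.n_markers, config.seed)
        params = config.simulation_params()
        cohort = simulate_cohort(build, marker_map, params)
        (out / "markers").mkdir(exist_ok=True)
        (out / "truth").mkdir(exist_ok=True)
        cohort_rows = []
        for s in cohort:
            write_marker_tsv(s.signal, out / "markers" / f"{s.sample_id}.tsv")
            write_seg_tsv(s.truth_profile, out / "truth" / f"{s.sample_id}.seg.tsv")
            cohort_rows.append(
                {
                    "sample_id": s.sample_id,
                    "class": s.class_label,
                    "purity": round(s.purity, 6),
                    "truth_loh": s.truth_scores.loh,
                    "truth_tai": s.truth_scores.tai,
                    "truth_lst": s.truth_scores.lst,
                    "truth_hrd": s.truth_scores.hrd_sum,
                }
            )
        cohort_frame = pd.DataFrame(cohort_rows)
        cohort_frame.to_csv(out / "cohort.tsv", sep="\t", index=False)
        manifest["stages"]["simulate"] = {"n_samples": len(cohort), "n_markers": config.n_markers}
        logger.info("simulate: %d samples, %d markers", len(cohort), config.n_markers)

        stage = "segment_call_score"
        (out / "segments").mkdir(exist_ok=True)
        fits: dict[str, dict] = {}
        sample_scores: list[scars.ScarScores] = []
        evaluable = []
        for s in cohort:
            try:
                result = gc_ascn.process_sample(s.signal, build, **config.pipeline_kwargs())
            except gc_ascn.UninformativeSampleError as exc:
                logger.info("%s dropped: %s", s.sample_id, exc)
                continue
            write_seg_tsv(result.profile, out / "segments" / f"{s.sample_id}.seg.tsv")
            fits[s.sample_id] = {
                "purity": result.fit.purity,
                "ploidy": result.fit.ploidy,
                "goodness": round(result.fit.goodness, 6),
            }
            sample_scores.append(
                scars.score_sample(result.profile, build, **config.scar_kwargs())
            )
            evaluable.append(s.sample_id)
        _write_json(fits, out / "fits.json")
        write_scores_tsv(sample_scores, out / "scores.tsv", cutoff=config.cutoff)
        manifest["stages"]["segment_call_score"] = {
            "n_input": len(cohort), "n_evaluable": len(evaluable),
        }
        logger.info("pipeline evaluable: %d / %d samples", len(evaluable), len(cohort))

        stage = "concordance"
        pipeline_scores = pd.DataFrame(
            [
                {"sample_id": sc.sample_id, "loh": sc.loh, "tai": sc.tai,
                 "lst": sc.lst, "hrd_sum": sc.hrd_sum}
                for sc in sample_scores
            ]
        )
        reference = cohort_frame.rename(columns={"truth_hrd": "score"})[["sample_id", "score"]]
        labels = cohort_frame[["sample_id"]].copy()
        labels["label"] = (cohort_frame["class"] == "hrd").astype(int)
        if len(pipeline_scores) >= 3 and labels["label"].nunique() > 1:
            panel = concord.run_concordance_panel(
                {"pipeline": pipeline_scores}, reference, labels, cutoff=config.cutoff
            )
            panel.to_csv(out / "concordance.tsv", sep="\t", index=False, float_format="%.6f")
            manifest["stages"]["concordance"] = {"n_rows": len(panel)}
        else:
            logger.info("concordance skipped: too few evaluable samples or one class")
            manifest["stages"]["concordance"] = {"skipped": "insufficient samples"}

        if config.run_downsampling:
            stage = "downsampling"
            ref_map = dict(zip(cohort_frame["sample_id"], cohort_frame["truth_hrd"]))
            curve = downsample.run_downsampling_experiment(
                [s.signal for s in cohort],
                build,
                ref_map,
                proportions=config.proportions,
                n_reps=config.n_reps,
                base_seed=config.seed,
                evaluability_floor=config.evaluability_floor,
                **config.pipeline_kwargs(),
            )
            curve.replicates.to_csv(out / "curve.tsv", sep="\t", index=False, float_format="%.6f")
            curve.summary.to_csv(
                out / "curve_summary.tsv", sep="\t", index=False, float_format="%.6f"
            )
            manifest["stages"]["downsampling"] = {
                "n_proportions": len(config.proportions),
                "n_reps": config.n_reps,
                "optimal_proportion": curve.optimal_proportion,
            }

        stage = "manifest"
        _write_json(manifest, out / "manifest.json")
        return manifest
    except Exception:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        (failed / "stage.txt").write_text(stage + "\n", encoding="utf-8")
        logger.error("pipeline failed at stage %r", stage)
        raise
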