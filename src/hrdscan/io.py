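"""Tabular I/O and run configuration.

One tabular dialect everywhere: tab-delimited, header row, UTF-8, '.'
decimal, reals written to 6 decimals.  Segment files carry a comment line
stating the coordinate convention (0-based, half-open).  Readers validate
schema and coordinate invariants and report the offending file and line.
"""

from __future__ import annotations

import dataclasses
import difflib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome import GenomeBuild, MarkerMap
from .scars import ScarScores
from .simulate import ASCNProfile, MarkerSignal, SimulationParams

__all__ = [
    "TsvValidationError",
    "PipelineConfig",
    "load_config",
    "read_build_tsv", "write_build_tsv",
    "read_marker_map_tsv", "write_marker_map_tsv",
    "read_marker_tsv", "write_marker_tsv",
    "read_seg_tsv", "write_seg_tsv",
    "read_scores_tsv", "write_scores_tsv",
]

_COORD_COMMENT = "# coordinates: 0-based, half-open [start, end), bp"
_FLOAT_FMT = "%.6f"


class TsvValidationError(ValueError):
    """Schema or invariant violation in a tabular file, with location."""


def _require_columns(frame: pd.DataFrame, required: set[str], path) -> None:
    missing = required - set(frame.columns)
    if missing:
        raise TsvValidationError(f"{path}: missing columns {sorted(missing)}")


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", comment="#")


def _data_line(path, row_index: int) -> int:
    """1-based file line of a data row, counting comment + header lines."""
    n_comments = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                n_comments += 1
            else:
                break
    return n_comments + 1 + row_index + 1  # comments + header + 1-based row


# -- genome build -----------------------------------------------------------

def write_build_tsv(build: GenomeBuild, path) -> None:
    build.to_frame().to_csv(path, sep="\t", index=False)


def read_build_tsv(path) -> GenomeBuild:
    return GenomeBuild.from_frame(_read_tsv(path))


# -- marker maps and marker signals ----------------------------------------

def write_marker_map_tsv(marker_map: MarkerMap, path) -> None:
    marker_map.frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_marker_map_tsv(path, platform_name: str | None = None) -> MarkerMap:
    frame = _read_tsv(path)
    _require_columns(frame, {"chrom", "pos", "gc"}, path)
    return MarkerMap(platform_name or Path(path).stem, frame)


def write_marker_tsv(signal: MarkerSignal, path) -> None:
    signal.frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_marker_tsv(path, sample_id: str | None = None) -> MarkerSignal:
    frame = _read_tsv(path)
    _require_columns(frame, {"chrom", "pos", "lrr", "baf", "gc"}, path)
    baf = frame["baf"].to_numpy()
    bad = np.nonzero((baf < 0) | (baf > 1))[0]
    if len(bad):
        raise TsvValidationError(
            f"{path}, line {_data_line(path, int(bad[0]))}: baf outside [0, 1]"
        )
    return MarkerSignal(sample_id or Path(path).stem, frame)


# -- segment tables ---------------------------------------------------------

def write_seg_tsv(profile: ASCNProfile, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(_COORD_COMMENT + "\n")
        profile.frame.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_seg_tsv(path, sample_id: str | None = None, build: GenomeBuild | None = None) -> ASCNProfile:
    frame = _read_tsv(path)
    _require_columns(frame, {"chrom", "start", "end", "cn_major", "cn_minor"}, path)
    start, end = frame["start"].to_numpy(), frame["end"].to_numpy()
    bad = np.nonzero(end <= start)[0]
    if len(bad):
        raise TsvValidationError(
            f"{path}, line {_data_line(path, int(bad[0]))}: segment end <= start"
        )
    for chrom, grp in frame.groupby("chrom", sort=False):
        s, e = grp["start"].to_numpy(), grp["end"].to_numpy()
        overlap = np.nonzero(s[1:] < e[:-1])[0]
        if len(overlap):
            row = int(grp.index[int(overlap[0]) + 1])
            raise TsvValidationError(
                f"{path}, line {_data_line(path, row)}: overlapping segments on {chrom}"
            )
    profile = ASCNProfile(sample_id or Path(path).stem.replace(".seg", ""), frame)
    if build is not None:
        profile.validate_tiling(build)
    return profile


# -- score tables -----------------------------------------------------------

def write_scores_tsv(scores: list[ScarScores], path, cutoff: int | None = None) -> None:
    from .scars import classify_hrd

    rows = []
    for s in scores:
        row = {
            "sample_id": s.sample_id, "loh": s.loh, "tai": s.tai,
            "lst": s.lst, "hrd_sum": s.hrd_sum,
        }
        if cutoff is not None:
            row["hrd_status"] = classify_hrd(s, cutoff)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_scores_tsv(path) -> pd.DataFrame:
    frame = _read_tsv(path)
    _require_columns(frame, {"sample_id", "loh", "tai", "lst", "hrd_sum"}, path)
    mismatch = np.nonzero(
        frame["hrd_sum"].to_numpy() != (frame["loh"] + frame["tai"] + frame["lst"]).to_numpy()
    )[0]
    if len(mismatch):
        raise TsvValidationError(
            f"{path}, line {_data_line(path, int(mismatch[0]))}: hrd_sum != loh + tai + lst"
        )
    return frame


# -- configuration ----------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every stage parameter with its documented default.

    Units: lengths in Mb where suffixed ``_mb``; noise SDs in channel units;
    ``penalty`` None means the self-tuning default.
    """

    seed: int = 0
    log_level: str = "INFO"

    # synthetic cohort
    n_samples: int = 40
    n_markers: int = 20_000
    class_mix: float = 0.5
    purity_min: float = 0.4
    purity_max: float = 0.9
    base_ploidy: int = 2
    hrd_multiplier: float = 10.0
    noise_sd_lrr: float = 0.15
    noise_sd_baf: float = 0.03
    gc_wave_amplitude: float = 0.1
    hom_fraction: float = 0.6

    # estimation stage
    gamma: float = 0.55
    smoother_span: float = 0.3
    penalty: float | None = None
    het_baf_low: float = 0.15
    het_baf_high: float = 0.85
    min_het: int = 5

    # scar thresholds and classification
    loh_min_mb: float = 15.0
    lst_flank_mb: float = 10.0
    lst_filter_mb: float = 3.0
    tai_min_mb: float = 0.0
    cutoff: int = 42

    # downsampling experiment
    run_downsampling: bool = False
    proportions: tuple[float, ...] = (
        0.0025, 0.005, 0.01, 0.025, 0.05, 0.10, 0.20,
        0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90,
    )
    n_reps: int = 10
    evaluability_floor: float = 0.95

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            key = sorted(unknown)[0]
            hint = difflib.get_close_matches(key, known, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown config key {key!r}{suggestion}")
        cfg = cls(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in raw.items()})
        cfg.simulation_params()  # trigger parameter validation early
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["proportions"] = list(d["proportions"])
        return d

    def simulation_params(self) -> SimulationParams:
        return SimulationParams(
            n_samples=self.n_samples,
            class_mix=self.class_mix,
            purity_range=(self.purity_min, self.purity_max),
            base_ploidy=self.base_ploidy,
            hrd_multiplier=self.hrd_multiplier,
            noise_sd_lrr=self.noise_sd_lrr,
            noise_sd_baf=self.noise_sd_baf,
            gc_wave_amplitude=self.gc_wave_amplitude,
            hom_fraction=self.hom_fraction,
            gamma=self.gamma,
            seed=self.seed,
        )

    def pipeline_kwargs(self) -> dict:
        return {
            "span": self.smoother_span,
            "penalty": self.penalty,
            "gamma": self.gamma,
            "het_band": (self.het_baf_low, self.het_baf_high),
            "min_het": self.min_het,
        }

    def scar_kwargs(self) -> dict:
        return {
            "loh_min_mb": self.loh_min_mb,
            "tai_min_mb": self.tai_min_mb,
            "lst_flank_mb": self.lst_flank_mb,
            "lst_filter_mb": self.lst_filter_mb,
        }


def load_config(path) -> PipelineConfig:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(text) or {}
    else:
        raw = json.loads(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return PipelineConfig.from_dict(raw)
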