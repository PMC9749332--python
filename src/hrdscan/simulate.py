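"""Synthetic SNP-array tumor cohorts with known allele-specific truth.

The generator produces, per sample, (1) a *truth* allele-specific
copy-number profile built by injecting discrete rearrangement events onto a
balanced background, (2) an event ledger recording how many injected events
qualify under each scar metric's rules, and (3) marker-level LRR/BAF signals
obtained by pushing the truth profile through the standard ASCAT-style
signal model with tumor-purity dilution, an additive GC-content wave, and
Gaussian channel noise.

Event classes are chosen so each scar metric can be dosed independently:

* ``interstitial_loh`` — loss of the minor allele away from both chromosome
  ends (doses LOH; its two breakpoints also dose LST when long enough),
* ``telomeric_ai`` — a single-copy gain anchored at a chromosome terminus
  and stopped before the centromere (doses TAI, one LST breakpoint),
* ``interstitial_gain`` — a short interior gain (doses LST only),
* ``whole_chrom_loh`` — copy-neutral LOH of an entire chromosome, which by
  the scar definitions qualifies for nothing (a deliberate negative class).

Events are placed with a 12 Mb buffer from each other, from centromere
edges, and from chromosome ends (except a telomeric event's anchored end),
so every event's qualification is decidable in isolation at injection time
and the ledger totals equal the scar scores of the truth profile exactly.
Default event-length bounds stay >= 2 Mb clear of every scar threshold so
that segmentation-boundary jitter cannot flip a qualification.

Signal model (per marker in a segment with allele copies ``(nA, nB)``,
purity ``rho``, platform compression ``gamma``)::

    nT  = nA + nB
    LRR = gamma * log2( (rho*nT + 2*(1-rho)) / (rho*psi + 2*(1-rho)) )
    BAF = (rho*nB + (1-rho)) / (rho*nT + 2*(1-rho))      (heterozygous)

with ``psi`` the profile's length-weighted mean total copy number — the
array normalization that makes LRR 0 at the sample's own average ploidy,
as allele-specific copy-number callers assume.  ``baseline="diploid"``
replaces ``psi`` by 2 (absolute diploid calibration).  A configurable
fraction of markers is homozygous (BAF near 0/1); the allele measured as
"B" is randomized per marker; the GC wave adds
``amplitude * (gc - mean gc)/sd(gc)`` to LRR; noise is Gaussian with BAF
clipped (truncated) to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import scars
from .genome import GenomeBuild, MarkerMap

logger = logging.getLogger(__name__)

__all__ = [
    "ASCNProfile",
    "MarkerSignal",
    "SimulationParams",
    "Event",
    "CohortSample",
    "sample_events",
    "realize_events",
    "simulate_truth_profile",
    "render_markers",
    "simulate_cohort",
]

#: minimum clearance (bp) between events, centromere edges and chromosome ends
PLACEMENT_BUFFER = 12_000_000

EVENT_CLASSES = ("interstitial_loh", "telomeric_ai", "interstitial_gain", "whole_chrom_loh")

_MB = 1e6


@dataclass(frozen=True)
class ASCNProfile:
    """Allele-specific integer copy-number segments tiling each autosome.

    Frame columns: chrom, start, end (bp, 0-based half-open), cn_major,
    cn_minor with ``cn_major >= cn_minor >= 0``.
    """

    sample_id: str
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        f = self.frame
        required = {"chrom", "start", "end", "cn_major", "cn_minor"}
        missing = required - set(f.columns)
        if missing:
            raise ValueError(f"profile missing columns: {sorted(missing)}")
        if np.any(f["start"].to_numpy() >= f["end"].to_numpy()):
            raise ValueError("profile has segment with end <= start")
        maj, mino = f["cn_major"].to_numpy(), f["cn_minor"].to_numpy()
        if np.any(mino < 0) or np.any(maj < mino):
            raise ValueError("profile requires cn_major >= cn_minor >= 0")
        for chrom, grp in f.groupby("chrom", sort=False):
            s, e = grp["start"].to_numpy(), grp["end"].to_numpy()
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"{chrom}: overlapping or unsorted segments")

    def validate_tiling(self, build: GenomeBuild) -> None:
        """Assert every base of every autosome is covered exactly once."""
        seen = set()
        for chrom, grp in self.frame.groupby("chrom", sort=False):
            c = build[str(chrom)]
            s, e = grp["start"].to_numpy(), grp["end"].to_numpy()
            if s[0] != 0 or e[-1] != c.length or np.any(s[1:] != e[:-1]):
                raise ValueError(f"{chrom}: segments do not tile the chromosome")
            seen.add(str(chrom))
        missing = set(build.names) - seen
        if missing:
            raise ValueError(f"chromosomes not covered: {sorted(missing)}")

    def mean_ploidy(self) -> float:
        """Length-weighted mean total copy number across the genome."""
        f = self.frame
        length = (f["end"] - f["start"]).to_numpy(dtype=float)
        total = (f["cn_major"] + f["cn_minor"]).to_numpy(dtype=float)
        return float((length * total).sum() / length.sum())


@dataclass(frozen=True)
class MarkerSignal:
    """Per-marker assay signals: chrom, pos, lrr, baf, gc (one row per marker)."""

    sample_id: str
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "lrr", "baf", "gc"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"marker signal missing columns: {sorted(missing)}")
        baf = self.frame["baf"].to_numpy()
        if np.any((baf < 0) | (baf > 1)):
            raise ValueError("baf outside [0, 1]")

    @property
    def n_markers(self) -> int:
        return len(self.frame)


def _default_rates() -> dict[str, float]:
    return {
        "interstitial_loh": 1.0,
        "telomeric_ai": 1.0,
        "interstitial_gain": 1.0,
        "whole_chrom_loh": 0.3,
    }


def _default_length_bounds() -> dict[str, tuple[float, float]]:
    # >= 2 Mb clear of the 15/10/3 Mb scar thresholds on either side
    return {
        "interstitial_loh": (17e6, 45e6),
        "telomeric_ai": (12e6, 40e6),
        "interstitial_gain": (12e6, 25e6),
    }


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for a synthetic cohort.

    ``event_rates`` are expected event counts per genome for the scar-poor
    ("stable") class; "HRD-like" samples multiply every rate by
    ``hrd_multiplier``.  Lengths are drawn log-uniformly within per-class
    bounds.  Noise SDs are per-channel Gaussian; ``gc_wave_amplitude`` is in
    LRR units per SD of marker GC.
    """

    n_samples: int = 40
    class_mix: float = 0.5
    purity_range: tuple[float, float] = (0.4, 0.9)
    base_ploidy: int = 2
    event_rates: dict[str, float] = field(default_factory=_default_rates)
    hrd_multiplier: float = 10.0
    event_length_bounds: dict[str, tuple[float, float]] = field(
        default_factory=_default_length_bounds
    )
    noise_sd_lrr: float = 0.15
    noise_sd_baf: float = 0.03
    gc_wave_amplitude: float = 0.1
    hom_fraction: float = 0.6
    gamma: float = 0.55
    baseline: str = "ploidy"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.class_mix <= 1:
            raise ValueError("class_mix must be in [0, 1]")
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("purity_range must lie within (0, 1]")
        if any(r < 0 for r in self.event_rates.values()):
            raise ValueError("event rates must be >= 0")
        if self.noise_sd_lrr < 0 or self.noise_sd_baf < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.base_ploidy not in (2, 4):
            raise ValueError("base_ploidy must be 2 or 4 (balanced background)")
        if self.baseline not in ("ploidy", "diploid"):
            raise ValueError("baseline must be 'ploidy' or 'diploid'")


@dataclass(frozen=True)
class Event:
    """One injected rearrangement: class, interval, and resulting state."""

    chrom: str
    start: int
    end: int
    event_class: str

    @property
    def length(self) -> int:
        return self.end - self.start


def _event_state(event_class: str, bg: tuple[int, int]) -> tuple[int, int]:
    maj, mino = bg
    if event_class == "interstitial_loh":
        return (maj, 0)
    if event_class == "whole_chrom_loh":
        return (maj + mino, 0)
    if event_class in ("telomeric_ai", "interstitial_gain"):
        return (maj + 1, mino)
    raise ValueError(f"unknown event class {event_class!r}")


def _qualify(event: Event, build: GenomeBuild) -> tuple[int, int, int]:
    """(loh, tai, lst) qualification of a buffered, non-interacting event.

    Direct application of each metric's rule to the event in isolation; valid
    because placement guarantees >= 10 Mb smoothed flanks around every
    breakpoint and a balanced background.
    """
    length = event.length
    cls = event.event_class
    if cls == "whole_chrom_loh":
        return (0, 0, 0)  # whole chromosome: excluded by every rule
    if cls == "interstitial_loh":
        loh = int(length > scars.LOH_MIN_MB * _MB)
        lst = 2 if length >= scars.LST_FLANK_MB * _MB else 0
        return (loh, 0, lst)
    if cls == "telomeric_ai":
        lst = 1 if length >= scars.LST_FLANK_MB * _MB else 0
        return (0, 1, lst)
    if cls == "interstitial_gain":
        lst = 2 if length >= scars.LST_FLANK_MB * _MB else 0
        return (0, 0, lst)
    raise ValueError(f"unknown event class {cls!r}")


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    if lo == hi:
        return lo
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _clear_of(occupied: list[tuple[int, int]], start: int, end: int, buffer: int) -> bool:
    return all(end <= s - buffer or start >= e + buffer for s, e in occupied)


def sample_events(
    build: GenomeBuild,
    params: SimulationParams,
    rate_multiplier: float,
    rng: np.random.Generator,
    max_attempts: int = 200,
) -> list[Event]:
    """Draw Poisson event counts per class and place them without interaction.

    Rejection sampling enforces the 12 Mb buffers; an event that cannot be
    placed within ``max_attempts`` draws is skipped with a warning.
    """
    buf = PLACEMENT_BUFFER
    occupied: dict[str, list[tuple[int, int]]] = {c.name: [] for c in build}
    blocked: set[str] = set()
    events: list[Event] = []

    counts = {
        cls: int(rng.poisson(rate * rate_multiplier))
        for cls, rate in params.event_rates.items()
    }

    n_whole = min(counts.get("whole_chrom_loh", 0), len(build))
    if n_whole:
        chosen = rng.choice(len(build), size=n_whole, replace=False)
        for idx in np.sort(chosen):
            c = build.chromosomes[int(idx)]
            events.append(Event(c.name, 0, c.length, "whole_chrom_loh"))
            blocked.add(c.name)

    lengths = np.array([c.length for c in build], dtype=float)
    weights = lengths / lengths.sum()

    for cls in ("interstitial_loh", "interstitial_gain", "telomeric_ai"):
        lo, hi = params.event_length_bounds.get(cls, (12e6, 25e6))
        for _ in range(counts.get(cls, 0)):
            placed = False
            for _attempt in range(max_attempts):
                ci = int(rng.choice(len(build), p=weights))
                c = build.chromosomes[ci]
                if c.name in blocked:
                    continue
                length = int(_log_uniform(rng, lo, hi))
                if cls == "telomeric_ai":
                    side = "p" if rng.random() < 0.5 else "q"
                    if side == "p":
                        start, end = 0, length
                        if end > c.cen_start - buf:
                            continue
                    else:
                        start, end = c.length - length, c.length
                        if start < c.cen_end + buf:
                            continue
                else:
                    start = int(rng.integers(0, max(1, c.length - length)))
                    end = start + length
                    in_p = start >= buf and end <= c.cen_start - buf
                    in_q = start >= c.cen_end + buf and end <= c.length - buf
                    if not (in_p or in_q):
                        continue
                if not _clear_of(occupied[c.name], start, end, buf):
                    continue
                occupied[c.name].append((start, end))
                events.append(Event(c.name, start, end, cls))
                placed = True
                break
            if not placed:
                logger.warning("could not place %s event after %d attempts; skipped", cls, max_attempts)
    return events


def realize_events(
    build: GenomeBuild,
    events: list[Event],
    base_ploidy: int = 2,
    sample_id: str = "sample",
) -> tuple[ASCNProfile, pd.DataFrame]:
    """Tile the genome around the given events and compute their ledger.

    Returns the truth profile plus a ledger with one row per event and its
    per-metric qualifying counts (columns ``loh``, ``tai``, ``lst``).
    """
    bg = ((base_ploidy + 1) // 2, base_ploidy // 2)
    by_chrom: dict[str, list[Event]] = {c.name: [] for c in build}
    for ev in events:
        by_chrom[ev.chrom].append(ev)

    rows = []
    ledger_rows = []
    for c in build:
        evs = sorted(by_chrom[c.name], key=lambda e: e.start)
        cursor = 0
        for ev in evs:
            if ev.start < cursor:
                raise ValueError(f"{c.name}: overlapping events at {ev.start}")
            if ev.start > cursor:
                rows.append((c.name, cursor, ev.start, *bg))
            state = _event_state(ev.event_class, bg)
            rows.append((c.name, ev.start, ev.end, *state))
            cursor = ev.end
            loh_q, tai_q, lst_q = _qualify(ev, build)
            ledger_rows.append(
                (sample_id, c.name, ev.start, ev.end, ev.event_class, loh_q, tai_q, lst_q)
            )
        if cursor < c.length:
            rows.append((c.name, cursor, c.length, *bg))
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "cn_major", "cn_minor"])
    ledger = pd.DataFrame(
        ledger_rows,
        columns=["sample_id", "chrom", "start", "end", "event_class", "loh", "tai", "lst"],
    )
    profile = ASCNProfile(sample_id=sample_id, frame=frame)
    profile.validate_tiling(build)
    return profile, ledger


def simulate_truth_profile(
    build: GenomeBuild,
    params: SimulationParams,
    sample_class: str,
    seed: int | np.random.Generator,
    sample_id: str = "sample",
) -> tuple[ASCNProfile, pd.DataFrame]:
    """Truth profile + event ledger for one sample of the given class."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mult = params.hrd_multiplier if sample_class == "hrd" else 1.0
    events = sample_events(build, params, mult, rng)
    return realize_events(build, events, params.base_ploidy, sample_id=sample_id)


def render_markers(
    profile: ASCNProfile,
    marker_map: MarkerMap,
    purity: float,
    params: SimulationParams,
    seed: int | np.random.Generator,
) -> MarkerSignal:
    """Render marker-level LRR/BAF from a truth profile (signal model above)."""
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rho, gamma = purity, params.gamma
    psi = profile.mean_ploidy() if params.baseline == "ploidy" else 2.0
    denom_ref = rho * psi + 2.0 * (1.0 - rho)

    out = []
    for chrom, markers in marker_map.frame.groupby("chrom", sort=False):
        seg = profile.frame[profile.frame["chrom"] == chrom]
        if seg.empty:
            raise AssertionError(f"profile does not cover {chrom}")
        pos = markers["pos"].to_numpy()
        idx = np.searchsorted(seg["end"].to_numpy(), pos, side="right")
        if idx.max(initial=-1) >= len(seg):
            raise AssertionError(f"{chrom}: marker beyond last segment")
        maj = seg["cn_major"].to_numpy()[idx].astype(float)
        mino = seg["cn_minor"].to_numpy()[idx].astype(float)
        nt = maj + mino
        n = len(pos)

        total = rho * nt + 2.0 * (1.0 - rho)
        lrr = gamma * np.log2(total / denom_ref)

        het = rng.random(n) >= params.hom_fraction
        b_is_minor = rng.random(n) < 0.5
        nb = np.where(b_is_minor, mino, maj)
        with np.errstate(invalid="ignore", divide="ignore"):
            baf_het = np.where(total > 0, (rho * nb + (1.0 - rho)) / total, 0.5)
        baf_hom = (rng.random(n) < 0.5).astype(float)
        baf = np.where(het, baf_het, baf_hom)

        out.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "lrr": lrr,
                    "baf": baf,
                    "gc": markers["gc"].to_numpy(),
                }
            )
        )
    frame = pd.concat(out, ignore_index=True)

    gc = frame["gc"].to_numpy()
    if params.gc_wave_amplitude > 0 and gc.std() > 0:
        frame["lrr"] += params.gc_wave_amplitude * (gc - gc.mean()) / gc.std()
    if params.noise_sd_lrr > 0:
        frame["lrr"] += rng.normal(0.0, params.noise_sd_lrr, size=len(frame))
    if params.noise_sd_baf > 0:
        frame["baf"] += rng.normal(0.0, params.noise_sd_baf, size=len(frame))
    frame["baf"] = frame["baf"].clip(0.0, 1.0)
    return MarkerSignal(sample_id=profile.sample_id, frame=frame)


@dataclass(frozen=True)
class CohortSample:
    """One simulated sample: signals plus all truth needed for evaluation."""

    sample_id: str
    class_label: str
    purity: float
    truth_profile: ASCNProfile
    truth_ledger: pd.DataFrame
    truth_scores: scars.ScarScores
    signal: MarkerSignal


def simulate_cohort(
    build: GenomeBuild,
    marker_map: MarkerMap,
    params: SimulationParams,
) -> list[CohortSample]:
    """Simulate ``params.n_samples`` samples with deterministic per-sample seeds.

    Exactly ``round(class_mix * n)`` samples are HRD-like; class order is
    shuffled.  Truth scar scores are computed on the truth profile.
    """
    n = params.n_samples
    master = np.random.default_rng(params.seed)
    n_hrd = int(round(params.class_mix * n))
    labels = np.array(["hrd"] * n_hrd + ["stable"] * (n - n_hrd))
    master.shuffle(labels)

    children = np.random.SeedSequence(params.seed).spawn(n)
    lo, hi = params.purity_range
    cohort: list[CohortSample] = []
    for i in range(n):
        rng = np.random.default_rng(children[i])
        sample_id = f"S{i + 1:03d}"
        purity = float(rng.uniform(lo, hi))
        profile, ledger = simulate_truth_profile(
            build, params, str(labels[i]), rng, sample_id=sample_id
        )
        truth_scores = scars.score_sample(profile, build)
        signal = render_markers(profile, marker_map, purity, params, rng)
        cohort.append(
            CohortSample(
                sample_id=sample_id,
                class_label=str(labels[i]),
                purity=purity,
                truth_profile=profile,
                truth_ledger=ledger,
                truth_scores=truth_scores,
                signal=signal,
            )
        )
    return cohort
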