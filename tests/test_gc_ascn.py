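import numpy as np
import pandas as pd
import pytest

import hrdscan as h
from hrdscan import gc_ascn
from hrdscan.simulate import MarkerSignal

from conftest import profile_from_segments
import oracles

MB = 1_000_000


def make_signal(lrr, baf, gc=None, chrom="chr1", spacing=100_000):
    n = len(lrr)
    pos = np.arange(n) * spacing + 1000
    if gc is None:
        gc = np.full(n, 0.42)
    return MarkerSignal(
        "t",
        pd.DataFrame({"chrom": chrom, "pos": pos, "lrr": lrr, "baf": baf, "gc": gc}),
    )


class TestGcCorrect:
    def test_linear_wave_removed(self):
        rng = np.random.default_rng(0)
        gc = rng.uniform(0.3, 0.6, size=5000)
        lrr = 1.0 * gc + rng.normal(0, 0.05, size=5000)
        out = gc_ascn.gc_correct(make_signal(lrr, np.full(5000, 0.5), gc))
        assert abs(np.corrcoef(out.frame["lrr"], gc)[0, 1]) < 0.05

    def test_median_lrr_preserved(self):
        rng = np.random.default_rng(1)
        gc = rng.uniform(0.3, 0.6, size=3000)
        lrr = 0.3 - 0.8 * gc + rng.normal(0, 0.1, size=3000)
        out = gc_ascn.gc_correct(make_signal(lrr, np.full(3000, 0.5), gc))
        assert np.median(out.frame["lrr"]) == pytest.approx(np.median(lrr), abs=1e-9)

    def test_idempotent_on_noise_free_input(self):
        rng = np.random.default_rng(2)
        gc = rng.uniform(0.3, 0.6, size=2000)
        lrr = 0.5 * gc - 0.2
        once = gc_ascn.gc_correct(make_signal(lrr, np.full(2000, 0.5), gc))
        twice = gc_ascn.gc_correct(once)
        assert np.max(np.abs(once.frame["lrr"] - twice.frame["lrr"])) < 1e-6

    def test_constant_gc_is_noop(self, caplog):
        lrr = np.random.default_rng(3).normal(size=500)
        sig = make_signal(lrr, np.full(500, 0.5), np.full(500, 0.4))
        with caplog.at_level("WARNING"):
            out = gc_ascn.gc_correct(sig)
        assert np.array_equal(out.frame["lrr"], lrr)
        assert any("no-op" in r.message for r in caplog.records)


class TestSegmentJoint:
    def test_single_jump_found_exactly(self, one_chrom_build):
        lrr = np.zeros(1000)
        lrr[500:] = 1.0
        sig = make_signal(lrr, np.full(1000, 0.5))
        res = gc_ascn.segment_joint(sig, one_chrom_build, penalty=0.5)
        f = res.frame
        assert len(f) == 2
        assert f["n_markers"].tolist() == [500, 500]
        assert f["mean_lrr"].tolist() == [0.0, 1.0]
        # bp bounds tile the chromosome
        assert f["start"].iloc[0] == 0 and f["end"].iloc[1] == one_chrom_build["chr1"].length

    def test_constant_series_single_segment(self, one_chrom_build):
        sig = make_signal(np.full(800, 0.25), np.full(800, 0.5))
        for penalty in (0.01, 1.0, 100.0):
            res = gc_ascn.segment_joint(sig, one_chrom_build, penalty=penalty)
            assert len(res.frame) == 1

    def test_tiny_chromosome_single_segment(self, one_chrom_build):
        sig = make_signal(np.array([0.1]), np.array([0.5]))
        res = gc_ascn.segment_joint(sig, one_chrom_build, penalty=1.0)
        assert len(res.frame) == 1
        assert res.frame["n_markers"].iloc[0] == 1

    def test_baf_only_change_detected(self, one_chrom_build):
        """Copy-neutral LOH is invisible in LRR; the folded-BAF channel finds it."""
        lrr = np.zeros(600)
        baf = np.full(600, 0.5)
        baf[300:] = np.tile([0.25, 0.75], 150)  # imbalanced heterozygous cluster
        res = gc_ascn.segment_joint(make_signal(lrr, baf), one_chrom_build, penalty=0.5)
        f = res.frame
        assert len(f) == 2
        assert f["n_markers"].tolist() == [300, 300]
        assert f["mean_baf"].iloc[1] == pytest.approx(0.75)

    def test_matches_naive_dp_oracle(self, one_chrom_build):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(30, 120))
            lrr = rng.normal(0, 0.2, size=n) + np.repeat(
                rng.choice([0.0, 0.5, -0.4], size=4), n // 4 + 1
            )[:n]
            baf = np.clip(rng.normal(0.5, 0.1, size=n), 0, 1)
            penalty = float(rng.uniform(0.1, 2.0))
            sig = make_signal(lrr, baf)
            res = gc_ascn.segment_joint(sig, one_chrom_build, penalty=penalty)
            folded = np.maximum(baf, 1 - baf)
            het = (baf >= 0.15) & (baf <= 0.85)
            expect = oracles.naive_optimal_partition(lrr, folded, het, penalty)
            got = np.cumsum([0] + res.frame["n_markers"].tolist())[:-1].tolist()
            assert got == expect

    def test_matches_full_enumeration_tiny(self, one_chrom_build):
        rng = np.random.default_rng(6)
        for _ in range(10):
            n = int(rng.integers(4, 11))
            lrr = rng.normal(size=n)
            baf = np.clip(rng.normal(0.5, 0.15, size=n), 0, 1)
            penalty = float(rng.uniform(0.2, 3.0))
            sig = make_signal(lrr, baf)
            res = gc_ascn.segment_joint(sig, one_chrom_build, penalty=penalty)
            folded = np.maximum(baf, 1 - baf)
            het = (baf >= 0.15) & (baf <= 0.85)
            expect = oracles.enumerate_optimal_partition(lrr, folded, het, penalty)
            got = np.cumsum([0] + res.frame["n_markers"].tolist())[:-1].tolist()
            assert got == expect


def simulate_one(build, purity=0.7, seed=0, n_markers=8000, **params_kw):
    defaults = dict(
        n_samples=1, noise_sd_lrr=0.0, noise_sd_baf=0.0, gc_wave_amplitude=0.0, seed=seed
    )
    defaults.update(params_kw)
    params = h.SimulationParams(**defaults)
    mm = h.make_marker_map(build, n_markers, seed=seed + 1)
    profile, _ = h.simulate_truth_profile(build, params, "hrd", seed=seed + 2)
    signal = h.render_markers(profile, mm, purity, params, seed=seed + 3)
    return profile, signal, params


class TestPurityPloidyFit:
    def test_pure_diploid_unrearranged_is_exact(self, hg19):
        params = h.SimulationParams(
            n_samples=1, noise_sd_lrr=0.0, noise_sd_baf=0.0, gc_wave_amplitude=0.0,
            event_rates={"interstitial_loh": 0.0},
        )
        profile, _ = h.simulate_truth_profile(hg19, params, "stable", seed=0)
        mm = h.make_marker_map(hg19, 3000, seed=1)
        sig = h.render_markers(profile, mm, 1.0, params, seed=2)
        seg = gc_ascn.segment_joint(sig, hg19)
        fit = gc_ascn.fit_purity_ploidy(seg)
        assert (fit.purity, fit.ploidy) == (1.0, 2.0)
        assert fit.goodness == pytest.approx(0.0, abs=1e-12)

    def test_noise_free_parameter_recovery(self, hg19):
        profile, signal, _ = simulate_one(hg19, purity=0.7, seed=10)
        res = gc_ascn.process_sample(signal, hg19)
        assert res.fit.purity == pytest.approx(0.7, abs=0.05)
        assert res.fit.ploidy == pytest.approx(profile.mean_ploidy(), abs=0.1)

    def test_all_homozygous_sample_uninformative(self, hg19):
        profile, signal, _ = simulate_one(hg19, purity=0.8, seed=11, hom_fraction=1.0)
        seg = gc_ascn.segment_joint(signal, hg19)
        with pytest.raises(gc_ascn.UninformativeSampleError):
            gc_ascn.fit_purity_ploidy(seg)

    def test_grid_is_retained_for_diagnostics(self, hg19):
        _, signal, _ = simulate_one(hg19, purity=0.6, seed=12, n_markers=4000)
        res = gc_ascn.process_sample(signal, hg19)
        g = res.fit.grid
        assert len(g) == 91 * 81
        reported = g[
            np.isclose(g["purity"], res.fit.purity) & np.isclose(g["ploidy"], res.fit.ploidy)
        ]
        assert reported["distance"].iloc[0] == pytest.approx(res.fit.goodness)


class TestIntegerCalling:
    def test_rounding_toward_nearest_nonnegative(self):
        seg = gc_ascn.SegmentationResult(
            "t",
            pd.DataFrame(
                {
                    "chrom": ["chr1", "chr1"],
                    "start": [0, 50 * MB],
                    "end": [50 * MB, 100 * MB],
                    # purity 1, ploidy 2: lrr/baf of (2,0) and (1,1)
                    "mean_lrr": [0.0, 0.0],
                    "mean_baf": [0.985, 0.5],
                    "n_markers": [100, 100],
                    "n_het": [0, 40],
                }
            ),
        )
        fit = gc_ascn.PurityPloidyFit(1.0, 2.0, 0.0, pd.DataFrame())
        profile = gc_ascn.call_integer_ascn(seg, fit)
        assert profile.frame[["cn_major", "cn_minor"]].values.tolist() == [[2, 0], [1, 1]]

    def test_adjacent_identical_calls_merge(self):
        seg = gc_ascn.SegmentationResult(
            "t",
            pd.DataFrame(
                {
                    "chrom": ["chr1"] * 3,
                    "start": [0, 30 * MB, 60 * MB],
                    "end": [30 * MB, 60 * MB, 90 * MB],
                    "mean_lrr": [0.0, 0.001, 0.32],
                    "mean_baf": [0.5, 0.5, 2 / 3],
                    "n_markers": [50, 50, 50],
                    "n_het": [20, 20, 20],
                }
            ),
        )
        fit = gc_ascn.PurityPloidyFit(1.0, 2.0, 0.0, pd.DataFrame())
        profile = gc_ascn.call_integer_ascn(seg, fit)
        assert len(profile.frame) == 2
        assert profile.frame["end"].iloc[0] == 60 * MB

    def test_noise_free_end_to_end_recovers_truth(self, hg19):
        for seed in (20, 21):
            profile, signal, _ = simulate_one(hg19, purity=1.0, seed=seed)
            res = gc_ascn.process_sample(signal, hg19)
            got = h.score_sample(res.profile, hg19)
            want = h.score_sample(profile, hg19)
            assert (got.loh, got.tai, got.lst) == (want.loh, want.tai, want.lst)
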