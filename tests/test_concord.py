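import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import hrdscan as h
from hrdscan import concord

import oracles


class TestAuroc:
    def test_perfect_separation(self):
        r = h.auroc([0.9, 0.8, 0.3, 0.1], [1, 1, 0, 0])
        assert r.estimate == 1.0
        assert r.n_positive == 2

    def test_half_concordant_pairs(self):
        # 2 concordant of the 4 positive-negative pairs
        assert h.auroc([0.9, 0.8, 0.3, 0.4], [1, 0, 1, 0]).estimate == 0.5

    def test_all_tied_scores(self):
        r = h.auroc([1.0, 1.0, 1.0, 1.0], [1, 0, 1, 0])
        assert r.estimate == 0.5
        assert r.overlaps_half

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            h.auroc([0.1, 0.2], [1, 1])

    def test_ci_brackets_estimate_and_stays_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(10, 60))
            s = rng.normal(size=n)
            lab = (rng.random(n) < 0.4).astype(int)
            if lab.min() == lab.max():
                continue
            r = h.auroc(s, lab)
            assert 0.0 <= r.ci_low <= r.estimate <= r.ci_high <= 1.0

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(4, 50))
            s = np.round(rng.normal(size=n), 1)  # induce ties
            lab = (rng.random(n) < 0.5).astype(int)
            if lab.min() == lab.max():
                continue
            assert h.auroc(s, lab).estimate == pytest.approx(
                oracles.auroc_pairs(s, lab), abs=1e-12
            )

    def test_negation_symmetry_exact(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(4, 50))
            s = rng.normal(size=n)
            lab = (rng.random(n) < 0.5).astype(int)
            if lab.min() == lab.max():
                continue
            assert h.auroc(s, lab).estimate + h.auroc(-s, lab).estimate == 1.0


class TestAuprc:
    def test_perfect_separation(self):
        r = h.auprc([0.9, 0.8, 0.3, 0.1], [1, 1, 0, 0])
        assert r.estimate == 1.0
        assert r.baseline == 0.5

    def test_hand_computed_step_integration(self):
        # ranked desc: 0.9(+), 0.8(-), 0.4(-), 0.3(+) -> (1/2)(1 + 2/4) = 0.75
        r = h.auprc([0.9, 0.8, 0.3, 0.4], [1, 0, 1, 0])
        assert r.estimate == pytest.approx(0.75)

    def test_single_positive_ranked_last(self):
        scores = np.arange(10, 0, -1).astype(float)
        labels = np.zeros(10, dtype=int)
        labels[-1] = 1  # lowest score
        r = h.auprc(scores, labels)
        assert r.baseline == pytest.approx(0.1)
        assert r.estimate == pytest.approx(0.1)

    def test_matches_step_oracle_on_tie_free_data(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(4, 50))
            s = rng.normal(size=n)
            lab = (rng.random(n) < 0.4).astype(int)
            if lab.min() == lab.max():
                continue
            assert h.auprc(s, lab).estimate == pytest.approx(
                oracles.average_precision_steps(s, lab), abs=1e-12
            )


class TestCorrelations:
    def test_linear_relationship(self):
        x = np.array([1.0, 2.0, 5.0, 7.0, 11.0])
        r = h.correlations(x, 2 * x + 1)
        assert r.pearson == pytest.approx(1.0)
        assert r.spearman == pytest.approx(1.0)

    def test_monotone_nonlinear(self):
        x = np.linspace(0, 3, 20)
        r = h.correlations(x, np.exp(x))
        assert r.spearman == pytest.approx(1.0)
        assert r.pearson < 1.0

    def test_hand_computed_spearman(self):
        # d = (-1, 1, -1, 1): 1 - 6*4/(4*15) = 0.6
        r = h.correlations([1, 2, 3, 4], [2, 1, 4, 3])
        assert r.spearman == pytest.approx(0.6)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            h.correlations([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        r = h.correlations(x, y)
        lo, hi = r.spearman_ci
        assert lo <= r.spearman <= hi

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.integers(-10_000, 10_000), min_size=5, max_size=30, unique=True))
    def test_spearman_invariant_under_monotone_transform(self, xs):
        x = np.array(xs, dtype=float)
        rng = np.random.default_rng(0)
        y = rng.permutation(x)
        r1 = h.correlations(x, y).spearman
        r2 = h.correlations(x**3, y).spearman  # strictly monotone, exact on ints
        assert r1 == pytest.approx(r2, abs=1e-12)


def _scores_frame(rng, n, ids=None):
    ids = ids or [f"S{i:03d}" for i in range(n)]
    return pd.DataFrame(
        {
            "sample_id": ids,
            "loh": rng.integers(0, 20, n),
            "tai": rng.integers(0, 20, n),
            "lst": rng.integers(0, 30, n),
        }
    ).assign(hrd_sum=lambda d: d.loh + d.tai + d.lst)


class TestPanel:
    def test_reference_separates_its_own_dichotomization(self):
        rng = np.random.default_rng(5)
        table = _scores_frame(rng, 30)
        reference = table[["sample_id"]].assign(score=table["hrd_sum"].astype(float))
        panel = h.run_concordance_panel({"p": table}, reference, cutoff=20)
        row = panel[
            (panel.metric == "hrd_sum") & (panel.comparator == "reference_positive")
            & (panel.kind == "auroc")
        ]
        assert row["estimate"].iloc[0] == 1.0

    def test_independent_scores_near_null(self):
        rng = np.random.default_rng(6)
        table = _scores_frame(rng, 200)
        reference = pd.DataFrame(
            {"sample_id": table["sample_id"], "score": rng.normal(size=200)}
        )
        labels = pd.DataFrame(
            {"sample_id": table["sample_id"], "label": (rng.random(200) < 0.5).astype(int)}
        )
        panel = h.run_concordance_panel({"p": table}, reference, labels, cutoff=0.5)
        null_auroc = panel[
            (panel.comparator == "class_label") & (panel.kind == "auroc")
        ]["estimate"]
        assert ((null_auroc > 0.4) & (null_auroc < 0.6)).all()

    def test_empty_intersection_rejected(self):
        rng = np.random.default_rng(7)
        table = _scores_frame(rng, 5)
        reference = pd.DataFrame({"sample_id": ["X1", "X2"], "score": [1.0, 2.0]})
        with pytest.raises(ValueError, match="empty intersection"):
            h.run_concordance_panel({"p": table}, reference)

    def test_lst_orders_above_loh_on_simulated_truth(self, hg19):
        """The largest-dynamic-range component separates classes best:
        median over seeds of (LST AUROC - LOH AUROC) is non-negative."""
        diffs = []
        for seed in range(20):
            params = h.SimulationParams(n_samples=30, seed=300 + seed)
            labels, loh, lst = [], [], []
            for i in range(params.n_samples):
                lab = "hrd" if i % 2 == 0 else "stable"
                profile, _ = h.simulate_truth_profile(
                    hg19, params, lab, seed=7000 + 100 * seed + i
                )
                sc = h.score_sample(profile, hg19)
                labels.append(int(lab == "hrd"))
                loh.append(sc.loh)
                lst.append(sc.lst)
            diffs.append(h.auroc(lst, labels).estimate - h.auroc(loh, labels).estimate)
        assert np.median(diffs) >= 0
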