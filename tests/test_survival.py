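"""Clustering, Kaplan–Meier, log-rank, and signature-scan tests."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from smadpipe.study import cohort_spec
from smadpipe.survival import (
    CohortData,
    cluster,
    km_estimate,
    logrank_test,
    mean_center,
    random_signature_control,
    signature_scan,
)
from smadpipe.synthetic import generate_cohort

from oracles import average_linkage_bruteforce, km_bruteforce, logrank_bruteforce


class TestMeanCenter:
    def test_simple_row(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        assert mean_center(m).loc["g"].tolist() == [-1.0, 0.0, 1.0]

    def test_matches_subtract_mean_oracle(self, rng):
        m = pd.DataFrame(rng.normal(size=(20, 10)))
        centered = mean_center(m)
        assert np.allclose(centered.to_numpy(),
                           m.to_numpy() - m.to_numpy().mean(1, keepdims=True))
        assert np.allclose(centered.mean(axis=1), 0.0)


class TestCluster:
    def test_anticorrelated_blocks_recovered(self, rng):
        base = rng.normal(size=12)
        rows = [base + rng.normal(0, 0.05, 12) for _ in range(5)]
        rows += [-base + rng.normal(0, 0.05, 12) for _ in range(5)]
        m = pd.DataFrame(rows, index=[f"g{i}" for i in range(10)])
        part = cluster(m, k=2)
        labels = part.labels
        assert labels.iloc[:5].nunique() == 1
        assert labels.iloc[5:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[9]

    def test_k_equals_items_gives_singletons(self, rng):
        m = pd.DataFrame(rng.normal(size=(6, 8)))
        part = cluster(m, k=6)
        assert part.labels.nunique() == 6

    def test_constant_item_rejected(self):
        m = pd.DataFrame([[1.0] * 5, [1, 2, 3, 4, 5]], index=["c", "g"])
        with pytest.raises(ValueError, match="constant"):
            cluster(m, k=2)

    def test_matches_naive_average_linkage_oracle(self, rng):
        # planted 4-block correlation structure over 30 items
        blocks = []
        for b in range(4):
            base = rng.normal(size=16)
            for _ in range(7 if b < 2 else 8):
                blocks.append(base + rng.normal(0, 0.2, 16))
        m = pd.DataFrame(blocks)
        part = cluster(m, k=4)
        oracle = average_linkage_bruteforce(m.to_numpy(), 4)
        oracle_labels = np.empty(len(m), dtype=int)
        for gi, members in enumerate(oracle):
            for i in members:
                oracle_labels[i] = gi
        assert adjusted_rand_score(part.labels.to_numpy(), oracle_labels) == 1.0


class TestKaplanMeier:
    def test_all_censored_flat_curve(self):
        res = km_estimate([5.0, 8.0, 12.0], [0, 0, 0])
        assert (res.curves["survival"] >= 1.0 - 1e-12).all()
        assert np.isnan(res.medians[0])

    def test_three_events_product_limit(self):
        res = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        curve = res.curves.set_index("time")["survival"]
        assert curve.loc[1.0] == pytest.approx(2 / 3)
        assert curve.loc[2.0] == pytest.approx(1 / 3)
        assert curve.loc[3.0] == pytest.approx(0.0)
        assert res.medians[0] == 2.0

    def test_censoring_risk_set_arithmetic(self):
        # censor at t=2: S(1)=3/4, S(3)=3/8 by hand product-limit
        times = [1.0, 2.0, 3.0, 4.0]
        events = [1, 0, 1, 1]
        res = km_estimate(times, events)
        curve = res.curves.set_index("time")["survival"]
        oracle = dict(km_bruteforce(times, events))
        for t, s in oracle.items():
            assert curve.loc[t] == pytest.approx(s)
        assert curve.loc[3.0] == pytest.approx(3 / 8)

    def test_matches_empirical_survival_without_censoring(self, rng):
        times = rng.exponential(10, size=40).round(3)
        events = [1] * 40
        res = km_estimate(times, events)
        curve = res.curves.set_index("time")["survival"]
        for t, s in km_bruteforce(times, events):
            assert curve.loc[t] == pytest.approx(s)
            assert s == pytest.approx(np.mean(times > t))

    def test_curves_monotone_per_group(self, rng):
        times = rng.exponential(10, size=30)
        events = rng.integers(0, 2, size=30)
        groups = rng.integers(0, 2, size=30)
        res = km_estimate(times, events, groups)
        for _, grp in res.curves.groupby("group"):
            assert (np.diff(grp["survival"]) <= 1e-12).all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        times = [2.0, 4.0, 6.0, 2.0, 4.0, 6.0]
        events = [1, 1, 0, 1, 1, 0]
        groups = ["a", "a", "a", "b", "b", "b"]
        stat, p = logrank_test(times, events, groups)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_textbook_oracle_small_fixture(self):
        times = [1.0, 3.0, 5.0, 7.0, 9.0, 2.0, 4.0, 6.0, 8.0, 10.0]
        events = [1, 1, 0, 1, 1, 1, 1, 1, 0, 1]
        groups = ["a"] * 5 + ["b"] * 5
        stat, p = logrank_test(times, events, groups)
        o_stat, o_p = logrank_bruteforce(times, events, groups)
        assert stat == pytest.approx(o_stat)
        assert p == pytest.approx(o_p)

    def test_label_swap_invariance(self, rng):
        times = rng.exponential(10, 16)
        events = rng.integers(0, 2, 16)
        groups = ["a"] * 8 + ["b"] * 8
        swapped = ["b"] * 8 + ["a"] * 8
        assert logrank_test(times, events, groups)[0] == pytest.approx(
            logrank_test(times, events, swapped)[0]
        )

    def test_requires_two_nonempty_groups(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], ["a", "a"])

    def test_likelihood_ratio_variant_runs(self, rng):
        times = np.concatenate([rng.exponential(5, 20), rng.exponential(15, 20)])
        events = np.ones(40)
        groups = ["a"] * 20 + ["b"] * 20
        stat, p = logrank_test(times, events, groups, method="likelihood-ratio")
        assert stat > 0 and p < 0.05


class TestSignatureScan:
    def test_planted_group_selected(self):
        cohort = generate_cohort(cohort_spec(seed=5))
        scan = signature_scan(cohort)
        planted = set(cohort.truth["prognostic_genes"])
        assert planted <= set(scan.selected_genes)
        assert scan.per_group["p"].min() < 0.05

    def test_k_patient_one_reports_no_test(self):
        cohort = generate_cohort(cohort_spec(seed=6))
        scan = signature_scan(cohort, k_patient=1)
        assert scan.selected_group is None
        assert scan.per_group["p"].isna().all()

    def test_incomplete_survival_excluded(self):
        cohort = generate_cohort(cohort_spec(seed=7))
        cohort.time.iloc[:5] = np.nan
        assert len(cohort.complete_cases()) == 55
        scan = signature_scan(cohort)  # must not raise
        assert scan.selected_group is not None


class TestRandomSignatureControl:
    def test_zero_size_rejected(self):
        cohort = generate_cohort(cohort_spec(seed=8))
        with pytest.raises(ValueError):
            random_signature_control(cohort, 0, set(), seed=1)

    def test_same_seed_same_draw(self):
        cohort = generate_cohort(cohort_spec(seed=8))
        g1, _, _ = random_signature_control(cohort, 10, set(), seed=3)
        g2, _, _ = random_signature_control(cohort, 10, set(), seed=3)
        assert g1 == g2

    def test_control_weaker_than_planted_signature(self):
        cohort = generate_cohort(cohort_spec(seed=9))
        scan = signature_scan(cohort)
        sig_p = scan.per_group["p"].min()
        control_ps = []
        for seed in range(5):
            _, _, p = random_signature_control(
                cohort, len(scan.selected_genes),
                set(scan.selected_genes), seed=seed,
            )
            control_ps.append(p)
        assert np.median(control_ps) > sig_p
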