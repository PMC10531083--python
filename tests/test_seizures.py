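"""Seizure metrics, exact tests, effect sizes and the group battery."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tbiscreen.seizures import (
    AnimalRecord,
    SeizureEvent,
    cohens_delta,
    cohens_delta_from_samples,
    epoch_metrics,
    fisher_exact_2x2,
    group_battery,
    latency_to_first,
    occurrence,
    within_group_evolution,
)


class TestPerAnimalMetrics:
    def test_occurrence_counts(self, toy_records):
        k, n, prop = occurrence(toy_records)
        assert (k, n) == (2, 3)
        assert prop == pytest.approx(2 / 3)
        assert occurrence([AnimalRecord("x", "G", [])])[2] == 0.0

    def test_published_occurrence_proportion(self):
        recs = [AnimalRecord(f"a{i}", "VEH", [SeizureEvent(1.0, 10.0)] if i < 13 else [])
                for i in range(16)]
        assert occurrence(recs)[2] == pytest.approx(0.8125)

    def test_latency_is_min_onset_and_undefined_when_event_free(self, toy_records):
        assert latency_to_first(toy_records[0]) == pytest.approx(9.0)
        assert latency_to_first(toy_records[1]) is None

    def test_group_latency_mean_matches_hand_enumeration(self, toy_records):
        lat = [latency_to_first(r) for r in toy_records]
        observed = np.mean([v for v in lat if v is not None])
        assert observed == pytest.approx((9.0 + 50.0) / 2)

    def test_epoch_boundary_24h_falls_in_second_epoch(self):
        rec = AnimalRecord("a", "G", [SeizureEvent(24.0, 10.0)])
        per_epoch, total = epoch_metrics(rec)
        assert [e.count for e in per_epoch] == [0, 1, 0]
        assert total.count == 1

    def test_epoch_cumulative_durations(self):
        rec = AnimalRecord("a", "G", [SeizureEvent(10.0, 60.0), SeizureEvent(50.0, 40.0)])
        per_epoch, total = epoch_metrics(rec)
        assert [e.cumulative_duration_s for e in per_epoch] == [60.0, 0.0, 40.0]
        assert total.cumulative_duration_s == 100.0

    def test_event_free_animal_contributes_zero_durations(self):
        per_epoch, total = epoch_metrics(AnimalRecord("a", "G", []))
        assert total.mean_duration_s == 0.0 and total.cumulative_duration_s == 0.0

    def test_unknown_racine_excluded_from_mean(self):
        rec = AnimalRecord("a", "G", [
            SeizureEvent(1.0, 5.0, 3), SeizureEvent(2.0, 5.0, None), SeizureEvent(3.0, 5.0, 1),
        ])
        _, total = epoch_metrics(rec)
        assert total.mean_racine == pytest.approx(2.0)  # (3 + 1) / 2 graded

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.floats(0, 72), st.floats(0, 600), st.sampled_from([None, 0, 1, 2, 3, 4, 5])),
        max_size=40,
    ))
    def test_epoch_decomposition_conserves_totals(self, raw_events):
        rec = AnimalRecord("a", "G", [SeizureEvent(t, d, r) for t, d, r in raw_events])
        per_epoch, total = epoch_metrics(rec)
        assert sum(e.count for e in per_epoch) == total.count == len(raw_events)
        assert sum(e.cumulative_duration_s for e in per_epoch) == pytest.approx(
            total.cumulative_duration_s
        )


class TestFisherExact:
    def test_published_contrasts(self):
        assert fisher_exact_2x2(13, 3, 4, 6) == pytest.approx(0.0461410443, abs=1e-9)
        assert fisher_exact_2x2(13, 3, 7, 13) == pytest.approx(0.0079085579, abs=1e-9)

    def test_symmetric_null_table_p_one(self):
        assert fisher_exact_2x2(5, 5, 5, 5) == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [(13, 3, 4, 6), (13, 3, 7, 13), (2, 8, 7, 3), (0, 5, 5, 0)])
    def test_agrees_with_independent_implementation(self, table):
        a, b, c, d = table
        ours = fisher_exact_2x2(a, b, c, d)
        ref = stats.fisher_exact([[a, b], [c, d]]).pvalue
        assert ours == pytest.approx(ref, rel=1e-9)

    def test_pmf_sums_to_one_over_all_margins(self):
        """Hypergeometric enumeration self-check for every margin, n <= 40."""
        for n in range(1, 41):
            for r in range(n + 1):
                for k in range(n + 1):
                    lo, hi = max(0, r + k - n), min(r, k)
                    support = np.arange(lo, hi + 1)
                    total = stats.hypergeom.pmf(support, n, r, k).sum()
                    assert total == pytest.approx(1.0, abs=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)


class TestCohensDelta:
    def test_published_effect_sizes(self):
        assert cohens_delta(727, 688, 16, 42, 64, 10) == pytest.approx(1.256, abs=1e-3)
        assert cohens_delta(2183, 166, 3, 5183, 3256, 10) == pytest.approx(-1.018, abs=1e-3)

    def test_equal_means_zero(self):
        assert cohens_delta(5, 1, 10, 5, 2, 10) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(-100, 100), st.floats(0.1, 50), st.integers(2, 40),
        st.floats(-100, 100), st.floats(0.1, 50), st.integers(2, 40),
        st.floats(0.01, 100),
    )
    def test_antisymmetry_and_scale_invariance(self, m1, s1, n1, m2, s2, n2, c):
        d = cohens_delta(m1, s1, n1, m2, s2, n2)
        assert cohens_delta(m2, s2, n2, m1, s1, n1) == pytest.approx(-d, abs=1e-9)
        assert cohens_delta(c * m1, c * s1, n1, c * m2, c * s2, n2) == pytest.approx(
            d, abs=1e-6
        )

    def test_zero_pooled_sd_raises(self):
        with pytest.raises(ZeroDivisionError):
            cohens_delta(1, 0, 5, 2, 0, 5)


def _exact_mannwhitney_oracle(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration (tie-free data)."""
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    center = n1 * len(y) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = sum(1 for xi in xs for yj in ys if xi > yj)
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
    return count / total


class TestGroupBattery:
    def _groups(self, arrays):
        out = {}
        for name, vals in arrays.items():
            out[name] = [
                AnimalRecord(f"{name}{i}", name,
                             [SeizureEvent(1.0, float(v))] if v > 0 else [])
                for i, v in enumerate(vals)
            ]
        return out

    def test_identical_groups_p_one_convention(self):
        groups = self._groups({"VEH": [0, 0, 0], "T": [0, 0, 0]})
        batt = group_battery(groups, "cumulative_duration")
        assert batt[0].p == 1.0 and math.isnan(batt[0].statistic)
        assert batt[1].p == 1.0

    def test_small_vectors_match_enumeration_oracle(self):
        x = [12.0, 7.0, 3.0, 30.0, 22.0]
        y = [1.0, 2.0, 5.0, 8.0]
        groups = self._groups({"VEH": x, "T": y})
        batt = group_battery(groups, "cumulative_duration")
        pair = [b for b in batt if b.test == "mann-whitney"][0]
        assert pair.p == pytest.approx(_exact_mannwhitney_oracle(x, y), rel=1e-9)

    def test_bonferroni_family_size(self):
        groups = self._groups({"VEH": [1, 2, 3], "A": [4, 5, 6], "B": [1, 3, 2]})
        batt = group_battery(groups, "cumulative_duration")
        pairs = [b for b in batt if b.test == "mann-whitney"]
        assert all(b.family_size == 2 for b in pairs)
        for b in pairs:
            assert b.p_adjusted == pytest.approx(min(1.0, b.p * 2))

    def test_planted_shift_detected_with_high_power(self):
        """One strongly shifted group out of three, n=50: omnibus p < 0.001."""
        rng = np.random.default_rng(0)
        hits = 0
        n_sims = 200
        for _ in range(n_sims):
            groups = self._groups({
                "VEH": rng.lognormal(4.0, 0.5, 50),
                "A": rng.lognormal(4.0, 0.5, 50),
                "B": rng.lognormal(1.5, 0.5, 50),
            })
            if group_battery(groups, "cumulative_duration")[0].p < 0.001:
                hits += 1
        assert hits >= 0.95 * n_sims

    def test_vehicle_minus_treatment_delta_sign(self):
        groups = self._groups({"VEH": [100, 120, 110, 90], "T": [10, 20, 15, 5]})
        pair = group_battery(groups, "cumulative_duration")[1]
        assert pair.cohens_delta > 0  # suppression = favorable = positive


class TestWithinGroupEvolution:
    @staticmethod
    def _animal(name, durations):
        events = [SeizureEvent(t, d) for t, d in zip([1.0, 30.0, 60.0], durations) if d > 0]
        return AnimalRecord(name, "G", events)

    def test_constant_across_epochs_p_one(self):
        recs = [self._animal(f"a{i}", [10, 10, 10]) for i in range(4)]
        res = within_group_evolution(recs)
        assert res[0].p == 1.0

    def test_friedman_statistic_matches_hand_rank_formula(self):
        data = np.array([[10.0, 5.0, 1.0], [20.0, 8.0, 2.0], [15.0, 9.0, 3.0], [30.0, 7.0, 4.0]])
        recs = [self._animal(f"a{i}", row) for i, row in enumerate(data)]
        res = within_group_evolution(recs)
        # hand computation: every animal ranks epochs 3 > 2 > 1
        n, k = 4, 3
        rank_sums = [3 * n, 2 * n, 1 * n]
        expected = 12 / (n * k * (k + 1)) * sum(r**2 for r in rank_sums) - 3 * n * (k + 1)
        assert res[0].statistic == pytest.approx(expected)

    def test_planted_monotone_decay_detected(self):
        rng = np.random.default_rng(1)
        recs = [
            self._animal(f"a{i}", [rng.lognormal(4, 0.3), rng.lognormal(3, 0.3), rng.lognormal(2, 0.3)])
            for i in range(50)
        ]
        res = within_group_evolution(recs)
        assert res[0].p < 1e-6
        # post hoc sign tests are Bonferroni-corrected over the 3 pairs
        post = [r for r in res if r.test == "sign"]
        assert all(r.family_size == 3 for r in post)
        assert all(r.p_adjusted < 0.01 for r in post)

    def test_too_few_animals_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            within_group_evolution([self._animal("a", [1, 1, 1])] * 2)
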