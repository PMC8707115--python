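"""Karyomorphometric statistics: arm ratios, Levan classes, aggregation."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from attakaryo import karyomorphometry as km
from attakaryo.synthetic import TrueKaryotype, simulate_spreads

from conftest import MORPH_NAME_TO_CODE, spread_from_table


class TestArmRatio:
    @pytest.mark.parametrize(
        "long_arm, short_arm, expected",
        [
            (4.90, 2.00, 2.45),   # M. goeldii chromosome 4
            (3.0, 3.0, 1.0),
            (1.63, 1.20, 1.3583),  # rounds to the printed 1.36
            (1.20, 1.63, 1.3583),  # orientation normalized
        ],
    )
    def test_examples(self, long_arm, short_arm, expected):
        assert km.arm_ratio(long_arm, short_arm) == pytest.approx(expected, abs=1e-4)

    @pytest.mark.parametrize("bad", [(0.0, 1.0), (-1.0, 2.0), (2.0, 0.0)])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(km.InvalidMeasurementError):
            km.arm_ratio(*bad)

    @given(
        st.floats(min_value=0.01, max_value=50, allow_nan=False),
        st.floats(min_value=0.01, max_value=50, allow_nan=False),
    )
    def test_always_at_least_one(self, a, b):
        assert km.arm_ratio(a, b) >= 1.0


class TestClassifyLevan:
    @pytest.mark.parametrize(
        "r, expected",
        [
            (1.0, "m"),
            (1.19, "m"),
            (1.70, "sm"),  # boundary closed on the submetacentric side
            (2.28, "sm"),
            (3.0, "st"),
            (6.99, "st"),
            (7.0, "t"),
            (25.0, "t"),
        ],
    )
    def test_cutoffs(self, r, expected):
        assert km.classify_levan(r) == expected

    def test_invalid_ratio(self):
        with pytest.raises(km.InvalidMeasurementError):
            km.classify_levan(0.9)

    @given(
        st.floats(min_value=1.0, max_value=30, allow_nan=False),
        st.floats(min_value=1.0, max_value=30, allow_nan=False),
    )
    def test_monotone_in_r(self, r1, r2):
        order = {label: i for i, label in enumerate(km.MORPHOLOGY_ORDER)}
        r1, r2 = sorted((r1, r2))
        assert order[km.classify_levan(r1)] <= order[km.classify_levan(r2)]


class TestRelativeLength:
    def test_printed_example(self):
        # chromosome 1 of the M. goeldii table: 8.79 on a 55.97 µm karyotype
        tls = [8.79, 8.37, 4.82, 4.64, 8.02, 7.76, 6.90, 6.67]
        assert round(km.relative_length(8.79, tls), 2) == 15.70

    def test_single_and_equal(self):
        assert km.relative_length(5.0, [5.0]) == 100.0
        assert km.relative_length(2.0, [2.0] * 4) == 25.0

    def test_membership_required(self):
        with pytest.raises(km.InvalidMeasurementError):
            km.relative_length(1.0, [2.0, 3.0])

    @given(
        st.lists(st.floats(min_value=0.1, max_value=20), min_size=1, max_size=60)
    )
    def test_sums_to_100_per_spread(self, tls):
        total = sum(km.relative_length(t, tls) for t in tls)
        assert math.isclose(total, 100.0, rel_tol=1e-9)


class TestAggregateSpreads:
    def test_single_spread_means_equal_raw_and_sd_zero(self, karyotables):
        spread = spread_from_table(karyotables["apterostigma_madidiense"])
        profiles = km.aggregate_spreads([spread])
        assert all(p.sd_TL == 0 and p.sd_r == 0 for p in profiles)
        # all metacentric: display order is TL-descending, matching the table
        table_tls = sorted(
            (m.total_length for m in spread.measurements), reverse=True
        )
        assert [p.mean_TL for p in profiles] == pytest.approx(table_tls)
        assert {p.morphology for p in profiles} == {"m"}

    def test_noise_free_spread_reproduces_coinciding_r(self, karyotables):
        # where the printed mean r equals mean_L/mean_S at 2 dp, a
        # noise-free spread reproduces the printed class
        df = karyotables["mycocepurus_goeldii"]
        spread = spread_from_table(df)
        profiles = km.aggregate_spreads([spread])
        for row in df.itertuples():
            if round(row.mean_L / row.mean_S, 2) != round(row.mean_r, 2):
                continue  # mean-of-ratios differs from ratio-of-means
            # match the profile by nearest total length (printed TL can be
            # off mean_L + mean_S by one rounding unit)
            profile = min(profiles, key=lambda p: abs(p.mean_TL - row.mean_TL))
            assert profile.mean_r == pytest.approx(row.mean_r, abs=0.015)

    def test_unequal_counts_rejected_with_ids(self):
        s1 = km.MetaphaseSpread("a", (km.ArmMeasurement(2, 1),) * 4)
        s2 = km.MetaphaseSpread("b", (km.ArmMeasurement(2, 1),) * 6)
        with pytest.raises(km.InconsistentSpreadsError) as err:
            km.aggregate_spreads([s1, s2])
        assert err.value.counts == {"a": 4, "b": 6}

    def test_simulated_mean_tl_recovery(self):
        truth = TrueKaryotype(pairs=((9.0, 1.2), (6.5, 2.2), (4.0, 1.4)))
        spreads = simulate_spreads(
            truth, 50, condensation_sd=0.05, arm_noise_sd=0.02, seed=11
        )
        profiles = km.aggregate_spreads(spreads)
        firsts = sorted(
            (p for p in profiles if p.homologue == 0),
            key=lambda p: -p.mean_TL,
        )
        true_sorted = sorted(truth.pairs, key=lambda p: -p[0])
        for profile, (tl_true, _) in zip(firsts, true_sorted):
            # condensation noise of 5% over 50 spreads: SE ~ tl*0.05/sqrt(50)
            se = tl_true * 0.05 / math.sqrt(50)
            assert abs(profile.mean_TL - tl_true) < 3 * se + 0.05


class TestFundamentalNumber:
    @pytest.mark.parametrize(
        "formula, expected",
        [
            ({"m": 30, "sm": 14, "st": 6}, 100),  # S. parvulus
            ({"m": 24}, 48),                      # A. madidiense
            ({"m": 12, "sm": 6, "a": 4}, 40),     # Atta sexdens
            ({"m": 4, "sm": 4}, 16),              # M. goeldii
            ({"t": 3, "a": 2}, 5),
        ],
    )
    def test_examples(self, formula, expected):
        assert km.fundamental_number(formula) == expected

    @given(
        st.fixed_dictionaries(
            {},
            optional={
                k: st.integers(min_value=0, max_value=40)
                for k in ("m", "sm", "st", "t", "a")
            },
        ),
        st.fixed_dictionaries(
            {},
            optional={
                k: st.integers(min_value=0, max_value=40)
                for k in ("m", "sm", "st", "t", "a")
            },
        ),
    )
    def test_additive(self, f1, f2):
        merged = {
            k: f1.get(k, 0) + f2.get(k, 0) for k in set(f1) | set(f2)
        }
        assert km.fundamental_number(merged) == km.fundamental_number(
            f1
        ) + km.fundamental_number(f2)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            km.fundamental_number({"m": 2, "x": 1})


class TestSummarizeKaryotype:
    def test_table_profiles(self, karyotables):
        df = karyotables["myrmicocrypta_sp"]
        spread = spread_from_table(df)
        summary = km.summarize_karyotype(km.aggregate_spreads([spread]))
        assert summary.diploid_number == 28
        assert summary.formula == {"m": 24, "sm": 4}
        assert summary.fundamental_number == 56

    def test_trivial_two_chromosomes(self):
        spread = km.MetaphaseSpread(
            "s", (km.ArmMeasurement(2.5, 2.5), km.ArmMeasurement(2.5, 2.5))
        )
        summary = km.summarize_karyotype(km.aggregate_spreads([spread]))
        assert summary.diploid_number == 2
        assert summary.formula == {"m": 2}
        assert summary.fundamental_number == 4
        assert summary.karyotype_length == pytest.approx(10.0)

    def test_fn_bounds_invariant(self, karyotables):
        for df in karyotables.values():
            spread = spread_from_table(df)
            summary = km.summarize_karyotype(km.aggregate_spreads([spread]))
            two_n = summary.diploid_number
            assert two_n <= summary.fundamental_number <= 2 * two_n
            uniarmed = summary.formula.get("t", 0) + summary.formula.get("a", 0)
            assert (summary.fundamental_number == 2 * two_n) == (uniarmed == 0)

    def test_kl_equals_sum_of_mean_tl(self, karyotables):
        df = karyotables["cyphomyrmex_transversus"]
        spread = spread_from_table(df)
        profiles = km.aggregate_spreads([spread])
        summary = km.summarize_karyotype(profiles)
        assert summary.karyotype_length == pytest.approx(
            sum(p.mean_TL for p in profiles)
        )


class TestHeteromorphism:
    @staticmethod
    def _spreads(pair_specs, n_spreads=6):
        spreads = []
        for j in range(n_spreads):
            measurements = []
            for (l1, s1), (l2, s2) in pair_specs:
                measurements.append(km.ArmMeasurement(l1, s1))
                measurements.append(km.ArmMeasurement(l2, s2))
            spreads.append(km.MetaphaseSpread(f"s{j}", tuple(measurements)))
        return spreads

    def test_same_class_small_delta_not_flagged(self):
        # homologues with r 2.3 vs 2.4, equal TL: same class, no flag
        spreads = self._spreads([(((2.3 / 3.3) * 6, (1 / 3.3) * 6), ((2.4 / 3.4) * 6, (1 / 3.4) * 6))])
        assert not km.detect_heteromorphism(spreads, 1).flagged

    def test_class_mismatch_flagged(self):
        # one homologue metacentric (r=1.2), the other submetacentric (r=2.2)
        spreads = self._spreads([((3.27, 2.73), (4.12, 1.88)), ((2.0, 1.8), (2.0, 1.8))])
        evidence = km.detect_heteromorphism(spreads, 1)
        assert evidence.flagged and evidence.class_mismatch_fraction == 1.0
        assert not km.detect_heteromorphism(spreads, 2).flagged

    def test_size_difference_flagged(self):
        spreads = self._spreads([((4.0, 3.5), (2.6, 2.3))])
        evidence = km.detect_heteromorphism(spreads, 1)
        assert evidence.flagged and evidence.mean_tl_ratio > 1.25

    def test_identical_homologues_unflagged_everywhere(self):
        spreads = self._spreads([((4.0, 3.0), (4.0, 3.0)), ((2.0, 1.0), (2.0, 1.0))])
        for pair in (1, 2):
            assert not km.detect_heteromorphism(spreads, pair).flagged

    def test_invalid_pair_index(self):
        spreads = self._spreads([((4.0, 3.0), (4.0, 3.0))])
        with pytest.raises(ValueError):
            km.detect_heteromorphism(spreads, 2)


class TestMorphologyRecovery:
    def test_boundary_distant_karyotypes_recover_classes(self):
        """With 2% arm noise and 10% condensation noise over 10 spreads,
        karyotypes whose true ratios sit >= 0.05 from every class
        boundary recover the true class in >= 99/100 replicates."""
        truth = TrueKaryotype(
            pairs=((10.0, 1.25), (8.0, 2.1), (6.0, 3.5), (4.0, 1.5))
        )
        true_classes = sorted(
            km.classify_levan(r) for _, r in truth.pairs
        )
        successes = 0
        for seed in range(100):
            spreads = simulate_spreads(
                truth, 10, condensation_sd=0.10, arm_noise_sd=0.02, seed=seed
            )
            profiles = km.aggregate_spreads(spreads)
            got = sorted(p.morphology for p in profiles if p.homologue == 0)
            successes += got == true_classes
        assert successes >= 99
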