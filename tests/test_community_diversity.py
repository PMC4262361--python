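import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import skbio.diversity.alpha as skbio_alpha

from seepcomm.core_data_io import CloneLibrary, Ribotype, SulfateReducerRegistry, ValidationError
from seepcomm.community_diversity import (
    DiversitySummary, chao1, counts_from_percentages, default_sr_registry,
    goods_coverage, shannon, sr_fraction, summarize_library,
)
from seepcomm.synthetic_data import gen_library


class TestCountsFromPercentages:
    @pytest.mark.parametrize("percents,n,expected", [
        ([53, 22, 25], 36, [19, 8, 9]),
        ([100], 10, [10]),
        ([50, 50], 9, [5, 4]),  # equal remainders: first-listed wins
        ([33.3, 33.3, 33.4], 3, [1, 1, 1]),
    ])
    def test_largest_remainder_examples(self, percents, n, expected):
        assert counts_from_percentages(percents, n) == expected

    def test_bad_sum_reports_total(self):
        with pytest.raises(ValidationError, match="90"):
            counts_from_percentages([45, 45], 10)

    @given(st.lists(st.integers(1, 50), min_size=2, max_size=8),
           st.integers(10, 200))
    @settings(max_examples=50, deadline=None)
    def test_sum_exact_and_percent_round_trip(self, weights, n):
        percents = [100.0 * w / sum(weights) for w in weights]
        counts = counts_from_percentages(percents, n)
        assert sum(counts) == n
        # Hamilton apportionment stays within one clone of every exact quota
        for c, p in zip(counts, percents):
            assert abs(100.0 * c / n - p) < 100.0 / n + 1e-9


class TestEstimators:
    def test_shannon_worked_examples(self):
        assert round(shannon([19, 8, 9]), 2) == 1.02
        assert shannon([36]) == 0.0
        assert shannon([1, 1, 1, 1]) == pytest.approx(np.log(4))

    @pytest.mark.parametrize("counts,variant,expected", [
        ([19, 8, 9], "classic", 3.0),
        ([19, 8, 9], "bias_corrected", 3.0),
        ([1, 1, 2, 5], "classic", 6.0),   # 4 + 2²/(2·1)
        ([1, 2, 3], "classic", 3.5),      # 3 + 1/(2·1)
        ([35], "classic", 1.0),
    ])
    def test_chao1_worked_examples(self, counts, variant, expected):
        assert chao1(counts, variant) == pytest.approx(expected)

    def test_goods_coverage_worked_examples(self):
        assert goods_coverage([19, 8, 9]) == 100.0
        assert goods_coverage([1, 1, 2, 5]) == pytest.approx(100 * (1 - 2 / 9))
        assert goods_coverage([1, 1, 1]) == 0.0

    def test_empty_and_zero_counts_rejected(self):
        for fn in (shannon, chao1, goods_coverage):
            with pytest.raises(ValidationError):
                fn([])
            with pytest.raises(ValidationError):
                fn([3, 0, 2])

    @given(st.lists(st.integers(1, 60), min_size=1, max_size=15))
    @settings(max_examples=60, deadline=None)
    def test_against_scikit_bio(self, counts):
        """Independent oracle: skbio's alpha-diversity implementations."""
        assert shannon(counts) == pytest.approx(
            skbio_alpha.shannon(counts, base=np.e), abs=1e-12)
        assert chao1(counts, "bias_corrected") == pytest.approx(
            skbio_alpha.chao1(counts, bias_corrected=True))
        assert goods_coverage(counts) == pytest.approx(
            100.0 * skbio_alpha.goods_coverage(counts))

    @given(st.lists(st.integers(1, 30), min_size=2, max_size=12))
    @settings(max_examples=60, deadline=None)
    def test_shannon_permutation_invariant_and_bounded(self, counts):
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(counts))
        assert shannon(perm) == pytest.approx(shannon(counts))
        assert shannon(counts) <= np.log(len(counts)) + 1e-12
        uniform = [5] * len(counts)
        assert shannon(uniform) == pytest.approx(np.log(len(counts)))

    @given(st.lists(st.integers(1, 10), min_size=2, max_size=12))
    @settings(max_examples=60, deadline=None)
    def test_chao1_variant_ordering(self, counts):
        c = np.asarray(counts)
        f1, f2 = int((c == 1).sum()), int((c == 2).sum())
        if f1 == 0:
            assert chao1(counts, "classic") == chao1(counts, "bias_corrected") == len(counts)
        if f2 == 0 and f1 >= 2:
            assert chao1(counts, "bias_corrected") <= chao1(counts, "classic")


def test_chao1_recovers_multinomial_richness_within_10pct():
    """Mean Chao1 over 500 seeded draws tracks the true richness S at n >= 50 S."""
    S = 10
    probs = np.full(S, 1.0 / S)
    profile = [(f"R{i}", None, p) for i, p in enumerate(probs)]
    rng = np.random.default_rng(7)
    estimates = [
        chao1(gen_library(profile, 50 * S, rng).counts, "classic")
        for _ in range(500)
    ]
    assert np.mean(estimates) == pytest.approx(S, rel=0.10)


class TestSummarizeLibrary:
    def test_bacterial_80C_fixture(self, bact80_library):
        d = summarize_library(bact80_library)
        assert d.s_obs == 3
        assert round(d.shannon_nats, 2) == 1.02
        assert d.chao1 == 3.0
        assert d.coverage_pct == 100.0
        assert (d.f1, d.f2) == (0, 0)

    def test_single_ribotype_archaeal_fixture(self, arch80_library):
        d = summarize_library(arch80_library)
        assert (d.s_obs, d.shannon_nats, d.chao1, d.coverage_pct) == (1, 0.0, 1.0, 100.0)

    def test_mixed_singleton_library(self):
        lib = CloneLibrary("bacteria", "test", 9,
                          tuple(Ribotype(f"R{i}", c) for i, c in enumerate([1, 1, 2, 5])))
        d = summarize_library(lib)
        assert d.s_obs == 4
        assert d.shannon_nats == pytest.approx(1.1490, abs=1e-4)
        assert d.chao1 == 6.0
        assert d.coverage_pct == pytest.approx(77.78, abs=0.01)

    def test_summary_rejects_internally_inconsistent_values(self):
        """A Shannon index above ln(S_obs) is impossible and must be refused.

        (A two-ribotype library cannot have H > ln 2 ≈ 0.693, so a printed
        pairing like H = 0.89 with S = 2 cannot be reproduced from any
        abundance vector.)
        """
        with pytest.raises(ValidationError, match="Shannon"):
            DiversitySummary(s_obs=2, shannon_nats=0.89, chao1=2.0,
                             chao1_bias_corrected=2.0, coverage_pct=98.0,
                             f1=1, f2=0)


class TestSrFraction:
    def test_no_reducers_in_80C_bacteria(self, bact80_library):
        frac, breakdown = sr_fraction(bact80_library, default_sr_registry())
        assert frac == 0.0 and breakdown == {}

    def test_pure_archaeoglobus_library(self, arch80_library):
        frac, breakdown = sr_fraction(arch80_library, default_sr_registry())
        assert frac == 1.0
        assert breakdown == {"Archaeoglobus": 1.0}

    def test_54pct_thermodesulfovibrio(self):
        lib = CloneLibrary("bacteria", "50C", 50, (
            Ribotype("R1", 27, "Thermodesulfovibrio"),
            Ribotype("R2", 23, "Thermotoga"),
        ))
        frac, breakdown = sr_fraction(lib, default_sr_registry())
        assert frac == pytest.approx(0.54)
        assert breakdown["Thermodesulfovibrio"] == pytest.approx(0.54)

    def test_unknown_genus_warns_and_counts_as_nonreducer(self):
        lib = CloneLibrary("bacteria", "x", 10, (
            Ribotype("R1", 6, "Desulfovibrio"), Ribotype("R2", 4, "Wolbachia"),
        ))
        with pytest.warns(UserWarning, match="Wolbachia"):
            frac, _ = sr_fraction(lib, default_sr_registry())
        assert frac == pytest.approx(0.6)

    def test_registry_extension_and_invariants(self):
        reg = SulfateReducerRegistry()
        reg.add("Desulfobacca", True, (30.0, 40.0))
        assert reg.is_reducer("Desulfobacca")
        with pytest.raises(ValidationError):
            reg.add("Bad", True, (40.0, 30.0))
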