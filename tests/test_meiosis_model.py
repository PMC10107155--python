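import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from achiasmate.genome import default_table
from achiasmate.meiosis_model import (
    LossParams,
    SegregationBias,
    SporeKaryotype,
    classify_tetrad,
    compute_bias,
    disomy_distribution,
    sample_viable_spores,
    segregate_mi,
    segregate_mii,
    simulate,
)

P_FULL_UNBIASED = (3 / 4) ** 16  # P(one MI daughter gets >=1 copy of all 16)


class TestComputeBias:
    def test_unbiased_collapses_to_half(self, table):
        bias = compute_bias(table, 0.5, 0.5)
        assert np.allclose(bias.x, 0.5)

    def test_extremes_and_midpoint(self, table):
        bias = compute_bias(table, 0.5, 1.0)
        assert bias.x[table.index("chr1")] == pytest.approx(0.5)  # shortest
        assert bias.x[table.index("chr4")] == pytest.approx(1.0)  # longest
        mid_len = (table.l_min + table.l_max) / 2
        x_mid = (mid_len - table.l_min) / (table.l_max - table.l_min) * 0.5 + 0.5
        assert x_mid == pytest.approx(0.75)

    @given(x_max=st.floats(0.5, 1.0))
    @settings(deadline=None, max_examples=25)
    def test_affine_in_length(self, x_max):
        """x is an affine function of length, bounded by [x_min, x_max]."""
        table = default_table()
        bias = compute_bias(table, 0.5, x_max)
        lengths = table.lengths_bp.astype(float)
        slope = (x_max - 0.5) / (table.l_max - table.l_min)
        assert np.allclose(bias.x, 0.5 + slope * (lengths - table.l_min))
        assert (bias.x >= 0.5 - 1e-12).all() and (bias.x <= x_max + 1e-12).all()

    def test_rejects_out_of_range(self, table):
        with pytest.raises(ValueError):
            compute_bias(table, 0.4, 0.9)
        with pytest.raises(ValueError):
            compute_bias(table, 0.5, 1.1)


class TestSegregateMI:
    def test_full_disjunction_always_one_each(self, table, rng):
        bias = compute_bias(table, x_min=0.5, x_max=1.0)
        i4 = table.index("chr4")  # x = 1.0 there
        for _ in range(200):
            d1, d2 = segregate_mi(bias, rng)
            assert d1[i4] in (1, 2) and d1[i4] + d2[i4] == 3

    def test_daughters_complementary(self, unbiased, rng):
        for _ in range(100):
            d1, d2 = segregate_mi(unbiased, rng)
            assert ((d1.astype(int) + d2.astype(int)) == 3).all()

    def test_unbiased_same_pole_rate(self, unbiased, rng):
        """At x=0.5 same-pole and opposite-pole are equally likely."""
        n = 4000
        draws = np.array([segregate_mi(unbiased, rng)[0] for _ in range(n)])
        frac_same = ((draws == 3) | (draws == 0)).mean()
        se = np.sqrt(0.25 / (n * 16))
        assert abs(frac_same - 0.5) < 3 * se

    def test_modes_swap_roles(self, table):
        dis = compute_bias(table, 0.5, 1.0, mode="disjunction")
        co = compute_bias(table, 0.5, 1.0, mode="co_segregation")
        assert np.allclose(dis.same_pole, 1.0 - dis.x)
        assert np.allclose(co.same_pole, co.x)


class TestSegregateMII:
    def test_no_loss_mirrors_daughter(self, rng):
        daughter = np.array([3, 1, 2, 0] * 4, dtype=np.uint8)
        s1, s2 = segregate_mii(daughter, LossParams(0, 0), rng)
        assert (s1.states == daughter).all() and (s2.states == daughter).all()

    def test_certain_disome_loss(self, rng):
        daughter = np.full(16, 3, dtype=np.uint8)
        s1, s2 = segregate_mii(daughter, LossParams(pa=0, pb=1.0), rng)
        assert (s1.states == 0).all() and (s2.states == 0).all()
        assert not s1.viable

    def test_disomy_outcome_frequencies(self, rng):
        """Per-spore disomy fate matches the per-copy Bernoulli expansion."""
        pb = 0.013
        expected = {
            3: (1 - pb) ** 2,          # ~0.97417 stays heterodisomy
            1: pb * (1 - pb),          # lost B copy
            2: pb * (1 - pb),          # lost A copy
            0: pb**2,                  # ~1.69e-4 lost both
        }
        daughter = np.full(16, 3, dtype=np.uint8)
        n = 6000
        states = np.concatenate(
            [segregate_mii(daughter, LossParams(0, pb), rng)[0].states
             for _ in range(n)]
        )
        for state, p in expected.items():
            se = np.sqrt(p * (1 - p) / states.size)
            assert abs((states == state).mean() - p) < 4 * se + 1e-6

    def test_no_chaining_of_pa_onto_pb_monosomies(self, rng):
        """With pa=1 and pb=0, disomies survive untouched: pa acts only on
        MII-entry monosomies, never on pb-created ones."""
        daughter = np.array([3] * 8 + [1] * 8, dtype=np.uint8)
        s1, _ = segregate_mii(daughter, LossParams(pa=1.0, pb=0.0), rng)
        assert (s1.states[:8] == 3).all()
        assert (s1.states[8:] == 0).all()


class TestClassifyTetrad:
    def _spore(self, states):
        return SporeKaryotype(np.asarray(states, dtype=np.uint8))

    def test_identical_pair_is_copies(self):
        a = self._spore([3, 1, 2, 1] * 4)
        dead = self._spore([0] + [1] * 15)
        assert classify_tetrad([a, a, dead, dead]) == "copies"

    def test_single_chromosome_difference_is_altered(self):
        a = [1] * 16
        b = list(a)
        b[10] = 3  # chromosome 11 present twice in one spore only
        dead = [0] + [1] * 15
        cat = classify_tetrad(
            [self._spore(a), self._spore(b), self._spore(dead), self._spore(dead)]
        )
        assert cat == "altered_copies"

    def test_one_viable_is_single(self):
        a = self._spore([1] * 16)
        dead = self._spore([0] * 16)
        assert classify_tetrad([a, dead, dead, dead]) == "single"

    def test_dead_tetrad_daughter_information(self):
        dead = self._spore([0] + [1] * 15)
        full_daughter = np.full(16, 1, dtype=np.uint8)
        empty_daughter = np.array([0] + [1] * 15, dtype=np.uint8)
        spores = [dead] * 4
        assert (
            classify_tetrad(spores, (full_daughter, empty_daughter)) == "mii_dead"
        )
        assert (
            classify_tetrad(spores, (empty_daughter, empty_daughter)) == "mi_dead"
        )

    def test_three_viable_is_multi(self):
        a = self._spore([1] * 16)
        dead = self._spore([0] * 16)
        assert classify_tetrad([a, a, a, dead]) == "multi"

    def test_no_loss_full_daughter_always_copies(self, unbiased, rng):
        loss = LossParams(0, 0)
        found = 0
        for _ in range(3000):
            d1, d2 = segregate_mi(unbiased, rng)
            if not ((d1 != 0).all() or (d2 != 0).all()):
                continue
            found += 1
            spores = [*segregate_mii(d1, loss, rng), *segregate_mii(d2, loss, rng)]
            assert classify_tetrad(spores, (d1, d2)) in ("copies", "multi")
        assert found > 0


class TestSimulate:
    def test_viable_fraction_matches_closed_form(self, unbiased):
        """Without losses a spore is viable iff its MI daughter carried a
        full set, so the viable fraction is (3/4)^16."""
        s = simulate(1_000_000, unbiased, LossParams(0, 0), seed=7)
        frac = s.n_viable_spores / (4 * s.n_tetrads)
        # conservative SE: spores within a tetrad are correlated, so treat
        # each tetrad as one observation
        se = np.sqrt(P_FULL_UNBIASED / s.n_tetrads)
        assert abs(frac - P_FULL_UNBIASED) < 3 * se

    def test_no_loss_viable_sets_are_copies(self, unbiased):
        s = simulate(300_000, unbiased, LossParams(0, 0), seed=8)
        assert s.category_counts["altered_copies"] == 0
        assert s.category_counts["single"] == 0
        assert s.category_counts["mii_dead"] == 0

    def test_category_counts_sum_to_n(self, unbiased, fitted_loss):
        s = simulate(100_000, unbiased, fitted_loss, seed=9, conditional=True)
        assert sum(s.category_counts.values()) == s.n_tetrads
        assert s.disomy_hist.sum() == s.n_viable_spores

    def test_reproducible_given_seed(self, unbiased, fitted_loss):
        a = simulate(50_000, unbiased, fitted_loss, seed=42, conditional=True)
        b = simulate(50_000, unbiased, fitted_loss, seed=42, conditional=True)
        assert a.category_counts == b.category_counts
        assert (a.disomy_hist == b.disomy_hist).all()

    def test_conditioning_probability_recorded(self, unbiased):
        s = simulate(1000, unbiased, LossParams(0, 0), seed=1, conditional=True)
        assert s.p_full_daughter == pytest.approx(P_FULL_UNBIASED)
        assert s.category_counts["mi_dead"] == 0

    def test_rejects_nonpositive_n(self, unbiased):
        with pytest.raises(ValueError):
            simulate(0, unbiased, LossParams(0, 0), seed=1)


class TestDisomyDistribution:
    def test_no_loss_matches_binomial_third(self, unbiased):
        """Conditional on a full daughter each chromosome is disomic with
        probability (1/4)/(3/4) = 1/3, independently."""
        from scipy.stats import binom

        hist = disomy_distribution(unbiased, LossParams(0, 0), 200_000, seed=13)
        n_spores = hist.sum()
        pmf = binom.pmf(np.arange(17), 16, 1 / 3)
        frac = hist / n_spores
        se = np.sqrt(pmf * (1 - pmf) / n_spores)
        assert (np.abs(frac - pmf) < 3 * se + 1e-4).all()

    def test_full_disjunction_protects_longest(self, table):
        """With x_max=1 (disjunction) the longest chromosome always
        disjoins, so it is never disomic before losses."""
        bias = compute_bias(table, 0.5, 1.0, mode="disjunction")
        s = simulate(50_000, bias, LossParams(0, 0), seed=14, conditional=True)
        assert s.per_chrom_disomy[table.index("chr4")] == 0


class TestInvariantsAcrossTetrads:
    def test_copy_conservation_and_heterodisomy(self, unbiased, rng):
        """Per chromosome the four spores carry 4 - (losses) <= 4 copies;
        no spore ever exceeds 2 copies and every disomy is heterodisomy
        (state 3: one copy from each parent)."""
        loss = LossParams(0.3, 0.3)
        for _ in range(300):
            d1, d2 = segregate_mi(unbiased, rng)
            spores = [*segregate_mii(d1, loss, rng), *segregate_mii(d2, loss, rng)]
            copies = np.array([s.copy_numbers for s in spores])
            assert copies.max() <= 2
            assert (copies.sum(axis=0) <= 4).all()
            for s in spores:
                assert set(np.unique(s.states)) <= {0, 1, 2, 3}


class TestSampleViableSpores:
    def test_all_viable_and_deterministic(self, unbiased, fitted_loss):
        a = sample_viable_spores(50, unbiased, fitted_loss, seed=21)
        b = sample_viable_spores(50, unbiased, fitted_loss, seed=21)
        assert a.shape == (50, 16)
        assert (a != 0).all()
        assert (a == b).all()
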