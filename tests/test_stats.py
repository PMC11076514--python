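"""Statistical battery: oracles, identities, and null behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cylsfm import (
    block_effect,
    cohens_d,
    duration_histogram,
    exclusion_contingency,
    icc_3k,
    kruskal_wallis,
    ks_two_sample,
    metabolite_correlations,
    posthoc_pairwise,
    spearman,
)
from cylsfm.stats import bonferroni


def kw_rank_formula(*groups):
    """Independent tie-corrected Kruskal-Wallis evaluation from the rank
    definition, used as the oracle for the scipy-backed implementation."""
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n = pooled.size
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie


class TestKruskalWallis:
    def test_identical_distributions_near_zero(self):
        res = kruskal_wallis([1, 2, 3], [1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_rank_formula_oracle(self):
        groups = ([1, 2, 3], [4, 5, 6], [7, 8, 9])
        res = kruskal_wallis(*groups)
        assert res.statistic == pytest.approx(kw_rank_formula(*groups))
        assert res.df == 2

    def test_matches_oracle_with_ties(self):
        groups = ([1, 1, 2, 5], [2, 2, 3, 5], [5, 6, 6, 9])
        assert kruskal_wallis(*groups).statistic == pytest.approx(kw_rank_formula(*groups))

    def test_two_groups_equal_ranksum_z_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=20), rng.normal(0.8, 1, size=25)
        h = kruskal_wallis(a, b).statistic
        # tie-corrected rank-sum z: standardized rank sum of group a
        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)
        n, na = pooled.size, a.size
        _, counts = np.unique(pooled, return_counts=True)
        tie = 1 - np.sum(counts**3 - counts) / (n**3 - n)
        mu = na * (n + 1) / 2
        var = na * (n - na) * (n + 1) / 12 * tie
        z = (ranks[:na].sum() - mu) / np.sqrt(var)
        assert h == pytest.approx(z**2)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0], [2, 3, 4])


class TestPosthoc:
    def test_identical_samples(self):
        res = posthoc_pairwise([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.df == 1

    def test_equals_two_group_kw(self):
        a, b = list(range(1, 11)), list(range(11, 21))
        res = posthoc_pairwise(a, b)
        assert res.statistic == pytest.approx(kruskal_wallis(a, b).statistic)
        assert res.p_bonferroni == pytest.approx(min(1.0, 3 * res.p))

    def test_monotone_invariance(self):
        rng = np.random.default_rng(2)
        a, b = rng.gamma(2, 2, 30), rng.gamma(3, 2, 25)
        r1 = posthoc_pairwise(a, b).statistic
        r2 = posthoc_pairwise(np.log(a), np.log(b)).statistic
        assert r1 == pytest.approx(r2)


class TestKS:
    def test_identical_samples_zero_d(self):
        x = [1.0, 2.0, 5.5, 7.0]
        assert ks_two_sample(x, x).statistic == pytest.approx(0.0)

    def test_disjoint_samples_full_d(self):
        assert ks_two_sample([1, 2, 3], [10, 11, 12]).statistic == pytest.approx(1.0)

    def test_matches_ecdf_scan_oracle(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=50), rng.normal(0.4, 1.3, size=50)
        grid = np.concatenate([a, b])
        ecdf_a = np.searchsorted(np.sort(a), grid, side="right") / a.size
        ecdf_b = np.searchsorted(np.sort(b), grid, side="right") / b.size
        d_oracle = np.max(np.abs(ecdf_a - ecdf_b))
        assert ks_two_sample(a, b).statistic == pytest.approx(d_oracle)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0, 2.0])


class TestSpearman:
    def test_monotone_transform_perfect_rho(self):
        x = np.array([0.3, 1.2, 2.0, 5.5, 9.0])
        assert spearman(x, np.exp(x)).statistic == pytest.approx(1.0)
        assert spearman(x, -(x**3)).statistic == pytest.approx(-1.0)

    def test_ties_equal_pearson_on_average_ranks(self):
        x = [1, 2, 2, 3, 5, 5, 5, 8]
        y = [4, 4, 6, 2, 9, 9, 1, 7]
        rho = spearman(x, y).statistic
        r = sps.pearsonr(sps.rankdata(x), sps.rankdata(y)).statistic
        assert rho == pytest.approx(r)

    def test_constant_input_flagged(self):
        res = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(res.statistic)
        assert "constant" in res.note


class TestICC:
    def test_duplicated_sessions_perfect_reliability(self, rng):
        x = rng.normal(size=30)
        res = icc_3k(np.column_stack([x, x]))
        assert res.statistic == pytest.approx(1.0)

    def test_independent_noise_near_zero(self, rng):
        m = rng.normal(size=(1000, 2))
        assert abs(icc_3k(m).statistic) < 0.1

    def test_matches_anova_decomposition_oracle(self, rng):
        m = rng.normal(size=(25, 3)) + rng.normal(size=(25, 1))
        n, k = m.shape
        grand = m.mean()
        bms = k * np.sum((m.mean(axis=1) - grand) ** 2) / (n - 1)
        wms_cols = n * np.sum((m.mean(axis=0) - grand) ** 2) / (k - 1)
        sst = np.sum((m - grand) ** 2)
        ems = (sst - (n - 1) * bms - (k - 1) * wms_cols) / ((n - 1) * (k - 1))
        expected = (bms - ems) / bms
        assert icc_3k(m).statistic == pytest.approx(expected)

    def test_monotone_in_noise(self, rng):
        trait = rng.normal(size=(200, 1))
        iccs = []
        for sd in (0.1, 0.5, 1.0, 2.0):
            m = trait + rng.normal(0, sd, size=(200, 2))
            iccs.append(icc_3k(m).statistic)
        assert all(a > b for a, b in zip(iccs, iccs[1:]))

    def test_incomplete_rows_dropped(self, rng):
        m = rng.normal(size=(20, 2))
        m[3, 1] = np.nan
        res = icc_3k(m)
        assert "dropped 1" in res.note


class TestCohensD:
    def test_identical_groups(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_unit_shift(self, rng):
        a = rng.normal(0, 1, 50_000)
        b = rng.normal(1, 1, 50_000)
        assert cohens_d(a, b) == pytest.approx(-1.0, abs=0.03)

    def test_hand_arithmetic(self):
        # means 2 and 4, pooled SD 1 -> |d| = 2
        assert abs(cohens_d([1, 2, 3], [3, 4, 5])) == pytest.approx(2.0)

    def test_zero_spread_flagged(self):
        assert np.isnan(cohens_d([1, 1], [1, 1]))


class TestContingency:
    def test_proportional_table_zero(self):
        assert exclusion_contingency([[10, 20, 30], [10, 20, 30]]).statistic == pytest.approx(0.0)
        assert exclusion_contingency([[10, 10, 10], [10, 10, 10]]).statistic == pytest.approx(0.0)

    def test_matches_direct_formula(self):
        # counts shaped like a screening exclusion narrative
        table = np.array([[37, 37, 48], [6, 7, 17]], dtype=float)
        exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        oracle = np.sum((table - exp) ** 2 / exp)
        res = exclusion_contingency(table)
        assert res.statistic == pytest.approx(oracle)
        assert res.df == 2

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            exclusion_contingency([[0, 5, 5], [0, 5, 5]])


class TestBlockEffect:
    def test_no_block_effect_zero_f(self, rng):
        # cyclic Latin square: every block (column) has the same mean, so
        # the block sum of squares, and hence F, is exactly zero
        base = np.arange(5.0)
        latin = np.stack([np.roll(base, -i) for i in range(5)])
        m = np.tile(latin, (6, 1)) + rng.normal(size=(30, 1))
        assert block_effect(m).statistic == pytest.approx(0.0, abs=1e-20)

    def test_detects_linear_decline(self, rng):
        m = rng.normal(size=(100, 5)) + np.linspace(0, -0.5, 5)
        res = block_effect(m)
        assert res.p < 0.001
        assert res.df == 4

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(6)
        rejections = 0
        n_sims = 400
        for _ in range(n_sims):
            m = rng.normal(size=(15, 5))
            rejections += block_effect(m).p < 0.05
        rate = rejections / n_sims
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_sims)


class TestHistogram:
    def test_single_bin(self):
        h = duration_histogram({"g": [1.0, 2.0, 3.0]}, [0, 5])
        assert h.proportions["g"] == pytest.approx([1.0])

    def test_arithmetic(self):
        h = duration_histogram({"g": [1, 1, 3]}, [0, 2, 4])
        assert h.proportions["g"] == pytest.approx([2 / 3, 1 / 3])

    def test_out_of_range_clipped_and_mass_conserved(self):
        h = duration_histogram({"g": [1.0, 99.0]}, [0, 2, 4])
        assert h.proportions["g"].sum() == pytest.approx(1.0)


class TestMetaboliteCorrelations:
    def test_null_metabolites_uncorrelated(self, rng):
        n = 2000
        rates = rng.normal(size=n)
        conc = pd.DataFrame({m: rng.normal(size=n) for m in ("GABA", "glutamate", "glutamine")})
        rep = metabolite_correlations(rates, conc)
        for m in ("GABA", "glutamate", "glutamine"):
            assert abs(rep[f"{m}_pooled"].statistic) < 0.05

    def test_constant_metabolite_flagged(self, rng):
        n = 50
        conc = pd.DataFrame({"GABA": np.ones(n)})
        rep = metabolite_correlations(rng.normal(size=n), conc, metabolites=("GABA",))
        assert np.isnan(rep["GABA_pooled"].statistic)

    def test_bonferroni_family(self, rng):
        n = 60
        conc = pd.DataFrame({m: rng.normal(size=n) for m in ("GABA", "glutamate", "glutamine")})
        rep = metabolite_correlations(rng.normal(size=n), conc)
        for m in ("GABA", "glutamate", "glutamine"):
            e = rep[f"{m}_pooled"]
            assert e.p_bonferroni == pytest.approx(min(1.0, 3 * e.p))


def test_bonferroni_properties():
    assert bonferroni(0.01, 6) == pytest.approx(0.06)
    assert bonferroni(0.5, 6) == 1.0
    assert bonferroni(0.2, 1) == pytest.approx(0.2)
    with pytest.raises(ValueError):
        bonferroni(0.1, 0)
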