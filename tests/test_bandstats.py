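"""Statistical toolkit: rank tests vs brute-force oracles, agreement,
mixtures and mixed-model machinery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from shellbands.bandstats import (
    aic_model_average,
    band_gap_correlations,
    bh_adjust,
    bland_altman,
    dunn_bh,
    emmeans_tukey,
    gmm_1d,
    kruskal_wallis,
    ks_centered,
    lrt_fixed,
    mann_whitney,
    wilcoxon_signed_rank,
)


# -- independent oracles ----------------------------------------------------

def mw_exact_oracle(x, y):
    """Exact two-sided Mann-Whitney p by enumerating rank assignments."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    n, m = len(x), len(y)

    def u_stat(xs, ys):
        u = 0.0
        for xi in xs:
            for yj in ys:
                if xi < yj:
                    u += 1.0
                elif xi == yj:
                    u += 0.5
        return u

    u_obs = u_stat(x, y)
    mu = n * m / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(n + m), n):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(n + m) if i not in combo]
        u = u_stat(xs, ys)
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


def ks_oracle(x, y):
    """ECDF-supremum two-sample KS statistic by direct scan."""
    xs, ys = np.sort(x), np.sort(y)
    grid = np.concatenate([xs, ys])
    fx = np.searchsorted(xs, grid, side="right") / len(xs)
    fy = np.searchsorted(ys, grid, side="right") / len(ys)
    return np.max(np.abs(fx - fy))


def kw_oracle(groups):
    """Kruskal-Wallis H from the rank formula with tie correction."""
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1 - np.sum(counts**3 - counts) / (n_total**3 - n_total)
    return h / correction


class TestMannWhitney:
    def test_disjoint_small_example(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.extra["U"] == pytest.approx(4.0)  # all pairs x < y
        assert res.value == pytest.approx(0.0)  # rank-sum W convention
        assert res.p == pytest.approx(2.0 / 6.0)
        assert res.note == "exact"

    def test_identical_samples_symmetric(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney(x, list(x))
        assert res.value == pytest.approx(len(x) ** 2 / 2.0)

    def test_exact_p_matches_enumeration_oracle(self, rng):
        for _ in range(12):
            n, m = rng.integers(2, 8, size=2)
            x = rng.normal(size=n)
            y = rng.normal(loc=rng.normal(), size=m)
            res = mann_whitney(x, y)
            assert res.p == pytest.approx(mw_exact_oracle(x, y), abs=1e-10)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestKruskalDunn:
    def test_constant_groups(self):
        res = kruskal_wallis([5.0, 5.0], [5.0, 5.0], [5.0, 5.0])
        assert res.value == 0.0 and res.p == 1.0

    def test_h_matches_rank_formula(self, rng):
        groups = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
        res = kruskal_wallis(*groups)
        assert res.value == pytest.approx(kw_oracle(groups), abs=1e-12)
        assert res.df == 2
        # with ties
        tied = [rng.integers(0, 4, size=6).astype(float) for _ in range(3)]
        res2 = kruskal_wallis(*tied)
        assert res2.value == pytest.approx(kw_oracle(tied), abs=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0, 2.0])

    def test_dunn_z_formula_and_bh_monotone(self, rng):
        groups = [rng.normal(loc=mu, size=8) for mu in (0.0, 0.5, 2.0)]
        pairs = dunn_bh(*groups)
        # adjusted p order consistent with raw p order
        raws = [t.p for _, _, t in pairs]
        adjs = [t.p_adjusted for _, _, t in pairs]
        assert all(a >= r for r, a in zip(raws, adjs))
        order = np.argsort(raws)
        assert np.all(np.diff(np.array(adjs)[order]) >= -1e-12)
        # direct formula for the first pair, no-ties case
        pooled = np.concatenate(groups)
        ranks = stats.rankdata(pooled)
        r1, r2 = ranks[:8].mean(), ranks[8:16].mean()
        n_total = len(pooled)
        se = math.sqrt((n_total * (n_total + 1) / 12.0) * (2.0 / 8.0))
        assert pairs[0][2].value == pytest.approx((r1 - r2) / se, abs=1e-12)


class TestBhAdjust:
    def test_step_up_by_hand(self):
        adj = bh_adjust([0.005, 0.01, 0.03])
        assert np.allclose(adj, [0.015, 0.015, 0.03])

    def test_single_and_equal_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(bh_adjust([0.04, 0.04, 0.04]), 0.04)

    def test_idempotent_bounded_order_preserving(self, rng):
        p = rng.uniform(size=20)
        adj = bh_adjust(p)
        assert np.all(adj <= 1.0) and np.all(adj >= p - 1e-12)
        assert np.allclose(bh_adjust(adj), bh_adjust(bh_adjust(adj)))
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestKsCentered:
    def test_pure_shift_removed(self):
        # dyadic values keep the centering exact in floating point
        x = np.arange(40) / 8.0
        res = ks_centered(x, x + 5.0)
        assert res.value == pytest.approx(0.0, abs=1e-12)

    def test_spread_difference_detected(self, rng):
        x = rng.normal(size=60)
        res = ks_centered(x, 2.0 * x)
        assert res.value > 0.1

    def test_matches_ecdf_oracle_after_centering(self, rng):
        for _ in range(10):
            x = rng.normal(size=int(rng.integers(5, 20)))
            y = rng.normal(scale=2.0, size=int(rng.integers(5, 20)))
            res = ks_centered(x, y)
            assert res.value == pytest.approx(
                ks_oracle(x - x.mean(), y - y.mean()), abs=1e-12
            )

    def test_degenerate_flagged(self):
        res = ks_centered([3.0, 3.0, 3.0], [7.0, 7.0])
        assert res.value == 0.0 and "degenerate" in res.note


class TestWilcoxonSignedRank:
    def test_all_positive_small(self):
        res = wilcoxon_signed_rank([0.5, 1.0, 2.0])
        assert res.value == 6.0

    def test_sign_flip_symmetry(self, rng):
        d = rng.normal(size=9)
        v = wilcoxon_signed_rank(d).value
        v_flip = wilcoxon_signed_rank(-d).value
        n = np.count_nonzero(d)
        assert v + v_flip == pytest.approx(n * (n + 1) / 2)

    @pytest.mark.parametrize("alternative", ["two-sided", "greater"])
    def test_exact_p_matches_scipy_enumeration(self, rng, alternative):
        for _ in range(8):
            d = rng.normal(loc=0.3, size=int(rng.integers(4, 11)))
            res = wilcoxon_signed_rank(d, alternative=alternative)
            ref = stats.wilcoxon(d, alternative=alternative, method="exact")
            assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zeros_dropped_and_degenerate_flagged(self):
        res = wilcoxon_signed_rank([0.0, 0.0])
        assert "degenerate" in res.note and res.p == 1.0

    def test_large_sample_normal_approximation(self, rng):
        d = rng.normal(loc=0.3, size=60)
        res = wilcoxon_signed_rank(d)
        ref = stats.wilcoxon(d, correction=True, method="approx")
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)


class TestCorrelations:
    def make_table(self, rng, n=40):
        cols = {f"b{i}_w": rng.normal(5, 1, n) for i in range(1, 6)}
        cols.update({f"g{j}_w": rng.normal(10, 2, n) for j in range(1, 7)})
        return pd.DataFrame(cols)

    def test_unit_diagonal_and_symmetry(self, rng):
        r, p = band_gap_correlations(self.make_table(rng))
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r, r.T)
        assert r.shape == (11, 11)

    def test_perfect_tradeoff(self, rng):
        table = self.make_table(rng)
        table["g1_w"] = 20.0 - table["b1_w"]
        r, _ = band_gap_correlations(table)
        assert r.loc["b1_w", "g1_w"] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        table = self.make_table(rng, n=25)
        r, _ = band_gap_correlations(table)
        ref = np.corrcoef(table.to_numpy().T)
        assert np.allclose(r.to_numpy(), ref, atol=1e-12)

    def test_sparse_pairs_flagged_missing(self, rng):
        table = self.make_table(rng, n=10)
        table.loc[2:, "b2_w"] = np.nan  # only 2 complete pairs remain
        r, _ = band_gap_correlations(table)
        assert np.isnan(r.loc["b2_w", "g1_w"])


class TestBlandAltman:
    def test_identical_pairs(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.bias == 0.0
        assert res.loa_lower == 0.0 and res.loa_upper == 0.0

    def test_hand_computed_example(self):
        a = np.array([1.0, 0.0, 5.0, 5.0])
        b = a - np.array([1.0, -1.0, 0.0, 0.0])
        res = bland_altman(a, b)
        assert res.bias == pytest.approx(0.0)
        assert res.sd == pytest.approx(0.816496580927726, abs=1e-12)
        assert res.loa_upper == pytest.approx(1.6003333, abs=1e-6)
        assert res.loa_lower == pytest.approx(-1.6003333, abs=1e-6)

    def test_swap_negates_bias_and_mirrors_loa(self, rng):
        a, b = rng.normal(size=50), rng.normal(size=50)
        r1, r2 = bland_altman(a, b), bland_altman(b, a)
        assert r2.bias == pytest.approx(-r1.bias)
        assert r2.loa_lower == pytest.approx(-r1.loa_upper)
        assert r2.loa_upper == pytest.approx(-r1.loa_lower)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


class TestGmm1d:
    def test_k1_equals_closed_form_mle(self, rng):
        x = rng.normal(3.0, 2.0, 200)
        res = gmm_1d(x, k_max=1, seed=0)
        assert res.selected_k == 1
        assert res.means[0] == pytest.approx(x.mean(), abs=1e-9)
        assert res.sds[0] == pytest.approx(x.std(), abs=1e-6)
        # closed-form maximum log-likelihood of a single Gaussian
        n = len(x)
        ll = -0.5 * n * (1 + math.log(2 * math.pi) + 2 * math.log(x.std()))
        assert res.bic_table["logL"].max() == pytest.approx(ll, abs=1e-6)

    def test_well_separated_components_selected(self, rng):
        x = np.concatenate([rng.normal(0, 1, 100), rng.normal(8, 1, 100)])
        res = gmm_1d(x, k_max=3, seed=0)
        assert res.selected_k == 2
        assert res.means == pytest.approx([0, 8], abs=0.5)

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(size=80)
        r1 = gmm_1d(x, seed=7)
        r2 = gmm_1d(x, seed=7)
        pd.testing.assert_frame_equal(r1.bic_table, r2.bic_table)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            gmm_1d(np.arange(5.0))


def _simulated_mixed_table(rng, n_groups=10, n_per=40, shape_beta=0.0):
    rows = []
    for g in range(n_groups):
        u = rng.normal(0, 1.0)
        shape = rng.normal(0.8, 0.05, n_per)
        height = rng.normal(16, 1.5, n_per)
        weight = rng.normal(2, 0.3, n_per)
        y = 27.0 + shape_beta * shape + u + rng.normal(0, 1.0, n_per)
        for i in range(n_per):
            rows.append((f"pop{g}", shape[i], height[i], weight[i], y[i]))
    return pd.DataFrame(rows, columns=["population", "shape", "height_mm", "weight_g", "y"])


class TestAicModelAverage:
    def test_true_effect_outweighs_null_terms(self, rng):
        table = _simulated_mixed_table(rng, shape_beta=8.0)
        rows = aic_model_average(table, "y")
        by_term = {r.term: r for r in rows}
        w_shape = by_term["shape"].weight
        assert w_shape > by_term.get("height_mm", by_term["Intercept"]).weight - 1.0
        assert all(0.0 <= r.weight <= 1.0 + 1e-12 for r in rows)
        assert w_shape > 0.9  # strong true effect dominates the model set
        ci = (by_term["shape"].ci_lower, by_term["shape"].ci_upper)
        assert ci[0] < 8.0 < ci[1] or abs(by_term["shape"].coefficient - 8.0) < 2.0

    def test_null_data_averaging_is_well_formed(self, rng):
        table = _simulated_mixed_table(rng, shape_beta=0.0)
        rows = aic_model_average(table, "y")
        for r in rows:
            assert r.ci_lower <= r.coefficient <= r.ci_upper
            assert 0.0 <= r.weight <= 1.0 + 1e-12


class TestLrtAndEmmeans:
    def test_strong_fixed_effect_detected(self, rng):
        table = _simulated_mixed_table(rng, shape_beta=8.0)
        res = lrt_fixed(table, "y", ["shape", "height_mm"], drop="shape")
        assert res.statistic == "chi_sq" and res.df == 1
        assert res.p < 1e-6
        assert res.extra["delta_aic"] > 2.0

    def test_null_fixed_effect_modest(self, rng):
        table = _simulated_mixed_table(rng, shape_beta=0.0)
        res = lrt_fixed(table, "y", ["shape"], drop="shape")
        assert res.p > 0.01

    def test_identical_groups_give_null_contrasts(self, rng):
        n = 30
        table = pd.DataFrame(
            {
                "region": np.repeat(["gap1", "band1", "gap2"], n),
                "rate": np.tile(rng.normal(0.12, 0.01, n), 3),
            }
        )
        out = emmeans_tukey(table, "rate", "region")
        assert np.allclose(out["estimate"], 0.0, atol=1e-12)
        assert np.all(out["p_tukey"] > 0.99)

    def test_two_level_tukey_equals_t_test(self, rng):
        table = pd.DataFrame(
            {
                "g": np.repeat(["a", "b"], 20),
                "y": np.concatenate([rng.normal(0, 1, 20), rng.normal(0.8, 1, 20)]),
            }
        )
        out = emmeans_tukey(table, "y", "g")
        t_ref = stats.ttest_ind(
            table.y[table.g == "a"], table.y[table.g == "b"]
        )
        assert out.loc[0, "p_tukey"] == pytest.approx(t_ref.pvalue, rel=1e-4)
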