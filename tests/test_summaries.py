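import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dmscore.summaries import (
    LOG_ETA_BOUNDS,
    _dirichlet_mle,
    cluster_mutants,
    cluster_variant_groups,
    estimate_eta,
    estimate_eta0,
    fit_alpha,
    jsd_matrix,
    naive_scores,
)
from tests.conftest import make_screen
from tests.test_model import synthetic_ns


class TestNaiveScores:
    def test_exact_line_has_exact_slope(self):
        ns = synthetic_ns([3.0], 0.0, T=3, R=1)
        ns.m[0, :, 0] = [0.0, 1.0, 2.0, 3.0]
        t = naive_scores(ns)
        assert t["estimate"].iloc[0] == pytest.approx(3.0, abs=1e-12)
        assert t["raw"].iloc[0] == pytest.approx(0.0, abs=1e-10)  # zero residual

    def test_flat_zero_trajectory_gives_p_one(self):
        ns = synthetic_ns([0.0, 0.0], 0.0, T=3, R=2)
        ns.m[:] = 0.0
        t = naive_scores(ns)
        assert (t["estimate"] == 0).all()
        assert (t["raw"] == 1.0).all()

    def test_matches_statsmodels_ols(self):
        import statsmodels.api as sm

        ns = synthetic_ns(np.linspace(-2, 2, 8), 0.4, T=3, R=2, seed=9)
        t = naive_scores(ns).set_index("variant_id")
        x = np.tile(np.arange(4) / 3, 2)
        for v in range(8):
            y = ns.m[v].T.ravel()
            fit = sm.OLS(y, sm.add_constant(x)).fit()
            row = t.loc[f"v{v}"]
            assert row["estimate"] == pytest.approx(fit.params[1], abs=1e-10)
            assert row["se"] == pytest.approx(fit.bse[1], abs=1e-10)
            assert row["raw"] == pytest.approx(fit.pvalues[1], abs=1e-10)


def dirmult_rvs(rng, alpha, n):
    return rng.multinomial(n, rng.dirichlet(alpha)).astype(float)


def dirmult_toy_tables():
    """Five small count tables with varying overdispersion."""
    rng = np.random.default_rng(12)
    tables = []
    for eta in (0.5, 2.0, 10.0, 40.0, 1.0):
        k = int(rng.integers(3, 8))
        p0 = rng.dirichlet(np.full(k, 5.0))
        c0 = np.round(p0 * 2000)
        c0[c0 == 0] = 1
        c1 = dirmult_rvs(rng, eta * k * p0, 2000)
        tables.append((c0.astype(float), c1))
    return tables


def grid_search_eta(c0, c1):
    k = c0.size
    props = (c0 + 0.5) / (c0 + 0.5).sum()
    grid = np.arange(LOG_ETA_BOUNDS[0], LOG_ETA_BOUNDS[1] + 1e-9, 0.01)
    ll = [
        stats.dirichlet_multinomial.logpmf(c1, (10.0**g) * k * props, int(c1.sum()))
        for g in grid
    ]
    return grid[int(np.argmax(ll))]


class TestDispersion:
    def test_mle_matches_grid_search_on_toy_tables(self):
        for c0, c1 in dirmult_toy_tables():
            counts = np.stack([c0, c1], axis=1)[:, :, None]
            sc = make_screen(counts, mutation_types=["synonymous"] * c0.size)
            est = estimate_eta(sc)
            assert est.log10_value == pytest.approx(grid_search_eta(c0, c1), abs=0.01)

    def test_identical_proportions_hit_upper_bound(self):
        c0 = np.array([100.0, 200.0, 300.0, 400.0])
        counts = np.stack([c0, 2 * c0], axis=1)[:, :, None]
        sc = make_screen(counts, mutation_types=["synonymous"] * 4)
        est = estimate_eta(sc)
        assert est.at_upper_bound

    def test_recovery_from_simulated_dispersion(self):
        rng = np.random.default_rng(3)
        n_syn, eta = 2000, 50.0
        p0 = rng.dirichlet(np.full(n_syn, 20.0))
        c0 = np.round(p0 * n_syn * 200)
        c0[c0 == 0] = 1
        props = (c0 + 0.5) / (c0 + 0.5).sum()
        c1 = dirmult_rvs(rng, eta * n_syn * props, int(c0.sum()))
        counts = np.stack([c0, c1], axis=1)[:, :, None]
        sc = make_screen(counts, mutation_types=["synonymous"] * n_syn)
        est = estimate_eta(sc)
        assert 35 <= est.value <= 70

    def test_uniform_library_hits_bound_and_imbalance_recovered(self):
        rng = np.random.default_rng(4)
        V, eta0 = 1000, 5.0
        uniform = np.full((V, 2, 1), 100.0)
        sc = make_screen(uniform)
        assert estimate_eta0(sc).at_upper_bound

        c0 = dirmult_rvs(rng, np.full(V, eta0), 100 * V)
        counts = np.stack([c0] * 2, axis=1)[:, :, None]
        est = estimate_eta0(make_screen(counts))
        assert 3.5 <= est.value <= 7

    def test_permutation_invariance(self):
        c0 = np.array([120.0, 30.0, 250.0, 400.0, 80.0])
        c1 = np.array([100.0, 60.0, 150.0, 500.0, 90.0])
        counts = np.stack([c0, c1], axis=1)[:, :, None]
        sc = make_screen(counts, mutation_types=["synonymous"] * 5)
        perm = [3, 1, 4, 0, 2]
        sc_perm = make_screen(counts[perm], mutation_types=["synonymous"] * 5)
        assert estimate_eta(sc).value == pytest.approx(estimate_eta(sc_perm).value,
                                                       rel=1e-6)


class TestMutantClustering:
    def test_jsd_properties(self):
        rng = np.random.default_rng(0)
        dens = rng.dirichlet(np.ones(30), size=6)
        D = jsd_matrix(dens)
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0.0, atol=1e-12)
        assert D.max() <= math.log(2) + 1e-9

    def test_identical_rows_have_zero_divergence_and_same_group(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 40)
        mat = pd.DataFrame(
            [base, base, base + 5, base - 5],
            index=["a", "a2", "b", "c"],
        )
        f1, props = cluster_mutants(mat, n_groups=3)
        assert f1["a"] == f1["a2"]
        assert props.sum() == pytest.approx(1.0)

    def test_disjoint_supports_reach_maximal_divergence(self):
        mat = pd.DataFrame([np.zeros(30), np.full(30, 10.0)])
        from dmscore.summaries import score_density

        lo, hi = -0.1 - 0.1, 10.1 + 0.1
        edges = np.arange(lo, hi, 0.1)
        d0 = score_density(mat.to_numpy()[0], edges)
        d1 = score_density(mat.to_numpy()[1], edges)
        D = jsd_matrix(np.stack([d0, d1]))
        assert D[0, 1] == pytest.approx(math.log(2), abs=1e-9)

    def test_recovers_planted_archetypes(self):
        rng = np.random.default_rng(2)
        centers = [-4.0, -1.5, 0.0, 3.0]
        rows, names = [], []
        for i in range(20):
            c = centers[i % 4]
            rows.append(rng.normal(c, 0.2, 60))
            names.append(f"mut{i}")
        mat = pd.DataFrame(rows, index=names)
        f1, props = cluster_mutants(mat, n_groups=4)
        planted = {name: i % 4 for i, name in enumerate(names)}
        # same planted archetype -> same recovered group (up to relabeling)
        mapping = {}
        for name, g in f1.items():
            mapping.setdefault(planted[name], set()).add(g)
        assert all(len(v) == 1 for v in mapping.values())
        assert sorted(np.round(props, 2)) == [0.25] * 4

    def test_more_groups_than_mutants_rejected(self):
        mat = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 10)))
        with pytest.raises(ValueError):
            cluster_mutants(mat, n_groups=4)


class TestVariantGroups:
    @staticmethod
    def score_table(values, syn_mask=None):
        n = len(values)
        syn = np.zeros(n, bool) if syn_mask is None else syn_mask
        return pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(n)],
                "position": np.arange(n) % 50 + 1,
                "mutant": [f"m{i % 19}" for i in range(n)],
                "mutation_type": np.where(syn, "synonymous", "missense"),
                "estimate": values,
            }
        )

    def test_bimodal_mixture_recovery(self):
        rng = np.random.default_rng(5)
        vals = np.concatenate(
            [rng.normal(0, 0.2, 3000), rng.normal(-3, 0.5, 2000)]
        )
        labels, groups, cutoffs = cluster_variant_groups(
            self.score_table(vals), n_components=2, selection_sign="negative"
        )
        # equal-responsibility boundary of the true mixture:
        # 0.6 N(0, 0.2^2) vs 0.4 N(-3, 0.5^2) crosses at x = -0.90
        assert cutoffs[0] == pytest.approx(-0.90, abs=0.15)
        by_label = {g.label: g for g in groups}
        assert by_label["neutral"].mean == pytest.approx(0.0, abs=0.1)
        assert by_label["lof"].mean == pytest.approx(-3.0, abs=0.1)

    def test_unimodal_single_neutral_group(self):
        rng = np.random.default_rng(6)
        labels, groups, cutoffs = cluster_variant_groups(
            self.score_table(rng.normal(0, 1, 500)), n_components=1
        )
        assert [g.label for g in groups] == ["neutral"]
        assert cutoffs == []

    def test_synonymous_labeled_control(self):
        rng = np.random.default_rng(7)
        vals = np.concatenate([rng.normal(0, 0.2, 300), rng.normal(-3, 0.3, 200)])
        syn = np.zeros(500, bool)
        syn[:50] = True
        labels, groups, cutoffs = cluster_variant_groups(
            self.score_table(vals, syn), n_components=2, selection_sign="negative"
        )
        assert (labels[:50] == "control").all()

    def test_score_exactly_at_cutoff_joins_lower_group(self):
        from dmscore.summaries import assign_by_cutoffs

        cut = -0.9
        idx = assign_by_cutoffs(np.array([cut - 1e-9, cut, cut + 1e-9]), [cut])
        assert list(idx) == [0, 0, 1]


class TestAlpha:
    def test_identical_compositions_match_direction(self):
        comp = np.array([0.5, 0.3, 0.2])
        P = np.tile(comp, (20, 1))
        alpha = _dirichlet_mle(P + 1e-6)
        np.testing.assert_allclose(alpha / alpha.sum(), comp, atol=0.01)
        assert alpha.sum() > 1e3  # zero-variance limit: huge concentration

    def test_recovery_within_fifteen_percent(self):
        rng = np.random.default_rng(8)
        true = np.array([2.0, 1.0, 1.0, 0.5])
        P = rng.dirichlet(true, size=500)
        alpha = _dirichlet_mle(P)
        np.testing.assert_allclose(alpha, true, rtol=0.15)

    def test_counts_to_composition_plumbing(self):
        positions = np.repeat(np.arange(10), 6)
        gm = np.tile([0, 0, 0, 1, 1, 1], 10)
        gv = np.tile(["neutral", "lof", "neutral", "lof", "neutral", "lof"], 10)
        alpha = fit_alpha(positions, gm, gv, n_gm=2, gv_order=["lof", "neutral"])
        assert alpha.shape == (4,)
        assert (alpha > 0).all()

    def test_too_few_positions_rejected(self):
        with pytest.raises(ValueError):
            fit_alpha(np.array([1, 1, 2]), np.zeros(3, int),
                      np.array(["lof", "lof", "neutral"]))
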