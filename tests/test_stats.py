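import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from ffgassess.core import ValidationError
from ffgassess.stats import (
    DistanceMatrix,
    bray_curtis,
    euclidean,
    mann_whitney,
    mantel,
    mantel_screen,
    permanova,
    spawn_seeds,
)


class TestBrayCurtis:
    def test_identical_rows_distance_zero(self):
        d = bray_curtis(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert d.values[0, 1] == 0.0

    def test_disjoint_rows_distance_one(self):
        d = bray_curtis(np.array([[1.0, 0.0], [0.0, 3.0]]))
        assert d.values[0, 1] == 1.0

    def test_hand_case(self):
        d = bray_curtis(np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 1.0]]))
        assert d.values[0, 1] == pytest.approx(0.5)

    def test_all_zero_pair_is_zero_by_convention(self):
        d = bray_curtis(np.zeros((2, 3)))
        assert d.values[0, 1] == 0.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            bray_curtis(np.array([[1.0, -1.0], [0.0, 1.0]]))

    def test_entries_in_unit_interval(self):
        rng = np.random.default_rng(3)
        x = rng.gamma(1.0, 5.0, size=(10, 6)) * rng.integers(0, 2, (10, 6))
        d = bray_curtis(x)
        assert ((d.values >= 0) & (d.values <= 1)).all()
        assert np.allclose(d.values, d.values.T)


def _groups_factor(groups):
    return pd.DataFrame({"group": groups})


class TestPermanova:
    def test_euclidean_univariate_matches_classical_anova(self):
        # closed-form limit: one-way PERMANOVA on Euclidean distances of
        # 1-D data is classical ANOVA
        rng = np.random.default_rng(5)
        y = np.concatenate([rng.normal(0, 1, 6), rng.normal(1.5, 1, 7),
                            rng.normal(-1, 1, 5)])
        groups = ["a"] * 6 + ["b"] * 7 + ["c"] * 5
        dm = euclidean(y[:, None])
        res = permanova(dm, _groups_factor(groups), terms=("group",),
                        interaction=False, n_perm=9, seed=0)
        f_classical = scipy.stats.f_oneway(y[:6], y[6:13], y[13:]).statistic
        assert res["group"]["pseudo_F"] == pytest.approx(f_classical, rel=1e-9)

    def test_matches_skbio_one_way(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(11)
        x = rng.gamma(1, 10, size=(12, 5))
        groups = ["a"] * 6 + ["b"] * 6
        dm = bray_curtis(x)
        res = permanova(dm, _groups_factor(groups), terms=("group",),
                        interaction=False, n_perm=9, seed=0)
        sk = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(dm.values, dm.labels),
            grouping=groups, permutations=9,
        )
        assert res["group"]["pseudo_F"] == pytest.approx(sk["test statistic"], rel=1e-9)

    def test_exact_permutation_p_equals_enumeration(self):
        # 6 samples in 2 groups of 3: p over all 6! relabelings must
        # equal the 6!/(3!3!) = 20 distinct-assignment enumeration
        y = np.array([0.1, 0.3, 0.2, 1.9, 2.2, 2.0])
        dm = euclidean(y[:, None])
        groups = ["a", "a", "a", "b", "b", "b"]
        res = permanova(dm, _groups_factor(groups), terms=("group",),
                        interaction=False, permutations="exact")

        def f_of(assignment):
            g1 = y[list(assignment)]
            g2 = y[[i for i in range(6) if i not in assignment]]
            return scipy.stats.f_oneway(g1, g2).statistic

        f_obs = f_of((0, 1, 2))
        fs = [f_of(c) for c in itertools.combinations(range(6), 3)]
        p_enum = sum(f >= f_obs - 1e-12 for f in fs) / len(fs)
        assert res["group"]["p_value"] == pytest.approx(p_enum)

    def test_huge_shift_r_squared_near_one(self):
        rng = np.random.default_rng(2)
        x = np.vstack([rng.normal(0, 1, (5, 3)), rng.normal(1e4, 1, (5, 3))])
        dm = euclidean(x)
        res = permanova(dm, _groups_factor(["a"] * 5 + ["b"] * 5),
                        terms=("group",), interaction=False, n_perm=99, seed=1)
        assert res["group"]["r_squared"] > 0.999

    def test_partition_identities_two_factor(self):
        rng = np.random.default_rng(9)
        n = 24
        fac = pd.DataFrame({
            "section": np.repeat(["gorge", "plain"], 12),
            "month": list(np.tile(np.repeat(["March", "May", "July"], 4), 2)),
        })
        x = rng.gamma(1, 5, (n, 4))
        dm = bray_curtis(x)
        res = permanova(dm, fac, n_perm=49, seed=0)
        t = res.table
        assert t.loc["Total", "df"] == n - 1
        assert t.drop("Total")["df"].sum() == n - 1
        assert t.drop("Total")["sum_sq"].sum() == pytest.approx(
            t.loc["Total", "sum_sq"], rel=1e-9
        )
        assert t.drop("Total")["r_squared"].sum() == pytest.approx(1.0, abs=1e-9)
        ps = t["p_value"].dropna()
        assert ((ps >= 1 / 50) & (ps <= 1.0)).all()

    def test_invariant_to_sample_reordering(self):
        rng = np.random.default_rng(13)
        n = 16
        fac = pd.DataFrame({
            "section": np.repeat(["g", "p"], 8),
            "month": list(np.tile(np.repeat(["a", "b"], 4), 2)),
        })
        x = rng.gamma(1, 5, (n, 4))
        dm = bray_curtis(x)
        res1 = permanova(dm, fac, n_perm=0, seed=0)
        perm = rng.permutation(n)
        dm2 = DistanceMatrix([dm.labels[i] for i in perm],
                             dm.values[np.ix_(perm, perm)])
        res2 = permanova(dm2, fac.iloc[perm].reset_index(drop=True),
                         n_perm=0, seed=0)
        for col in ("df", "sum_sq", "pseudo_F"):
            assert np.allclose(
                res1.table[col].astype(float),
                res2.table[col].astype(float),
                equal_nan=True,
            )

    def test_constant_factor_rejected(self):
        dm = euclidean(np.arange(6.0)[:, None])
        with pytest.raises(ValidationError, match="constant"):
            permanova(dm, _groups_factor(["a"] * 6), terms=("group",),
                      interaction=False, n_perm=9)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(17)
        x = rng.gamma(1, 5, (12, 3))
        fac = _groups_factor(["a"] * 6 + ["b"] * 6)
        r1 = permanova(bray_curtis(x), fac, terms=("group",),
                       interaction=False, n_perm=99, seed=42)
        r2 = permanova(bray_curtis(x), fac, terms=("group",),
                       interaction=False, n_perm=99, seed=42)
        assert r1["group"]["p_value"] == r2["group"]["p_value"]


class TestMantel:
    def test_scaled_matrix_perfect_correlation(self):
        rng = np.random.default_rng(23)
        d1 = euclidean(rng.normal(size=(8, 2)))
        d2 = DistanceMatrix(d1.labels, 2.0 * d1.values)
        res = mantel(d1, d2, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == 1 / 100

    def test_matches_skbio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(29)
        a = euclidean(rng.normal(size=(10, 3)))
        noisy = a.values + rng.uniform(0, 0.4, a.values.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        b = DistanceMatrix(a.labels, noisy)
        res = mantel(a, b, n_perm=999, seed=1)
        r_sk, p_sk, _ = skbio_stats.mantel(
            skbio_stats.DistanceMatrix(a.values, a.labels),
            skbio_stats.DistanceMatrix(b.values, b.labels),
            method="pearson", permutations=999, alternative="greater",
        )
        assert res.r == pytest.approx(r_sk, rel=1e-9)
        assert abs(res.p_value - p_sk) < 0.05

    def test_zero_variance_flagged(self):
        d1 = DistanceMatrix(["0", "1", "2", "3"], np.ones((4, 4)) - np.eye(4))
        d2 = euclidean(np.arange(4.0)[:, None])
        res = mantel(d1, d2, n_perm=9, seed=0)
        assert math.isnan(res.r) and math.isnan(res.p_value)

    def test_null_pvalues_roughly_uniform(self):
        # independent matrices: permutation p should be near-uniform;
        # checked loosely via mean and KS on 60 replicates
        rng = np.random.default_rng(31)
        ps = []
        for i in range(60):
            a = euclidean(rng.normal(size=(12, 2)))
            b = euclidean(rng.normal(size=(12, 2)))
            ps.append(mantel(a, b, n_perm=99, seed=i).p_value)
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01

    def test_spearman_option_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(37)
        d1 = euclidean(rng.normal(size=(9, 2)))
        d2 = DistanceMatrix(d1.labels, d1.values**3)
        res = mantel(d1, d2, n_perm=49, seed=0, method="spearman")
        assert res.r == pytest.approx(1.0)


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.p == 1.0 and res.z == 0.0

    def test_small_sample_exact_enumeration(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.p_exact == pytest.approx(1 / 3)
        assert res.p_normal is not None

    def test_swap_flips_z_keeps_p(self):
        x, y = [1.0, 5.0, 2.0], [4.0, 8.0, 9.0, 7.0]
        a = mann_whitney(x, y)
        b = mann_whitney(y, x)
        assert a.z == pytest.approx(-b.z)
        assert a.p == pytest.approx(b.p)

    def test_sign_convention_gorge_below_plain(self):
        res = mann_whitney([1, 2, 3, 4], [10, 11, 12, 13])
        assert res.z < 0

    def test_exact_agrees_with_brute_force_small_layouts(self):
        # all layouts with n_x + n_y <= 8 on a fixed value pool with ties
        rng = np.random.default_rng(41)
        pool = rng.integers(0, 5, size=8).astype(float)
        for nx in range(1, 8):
            ny = 8 - nx
            x, y = pool[:nx], pool[nx:]
            res = mann_whitney(x, y, method="exact")
            mu = nx * ny / 2
            dev = abs(res.u - mu)
            hits = total = 0
            for comb in itertools.combinations(range(8), nx):
                xs = pool[list(comb)]
                ys = pool[[i for i in range(8) if i not in comb]]
                u = sum(
                    (a > b) + 0.5 * (a == b) for a in xs for b in ys
                )
                hits += abs(u - mu) >= dev - 1e-12
                total += 1
            assert res.p == pytest.approx(hits / total)

    def test_normal_approx_matches_scipy_with_ties(self):
        rng = np.random.default_rng(43)
        x = rng.integers(0, 6, 15).astype(float)
        y = rng.integers(1, 7, 12).astype(float)
        res = mann_whitney(x, y, method="normal")
        sp = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                      method="asymptotic", use_continuity=True)
        assert res.u == pytest.approx(sp.statistic)
        assert res.p_normal == pytest.approx(sp.pvalue, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])


class TestSeedFanout:
    def test_spawn_deterministic_and_distinct(self):
        a = spawn_seeds(7, 5)
        b = spawn_seeds(7, 5)
        assert a == b
        assert len(set(a)) == 5
        assert all(0 <= s < 2**31 for s in a)


@pytest.fixture(scope="module")
def screen():
    from ffgassess.core import build_matrix
    from ffgassess.simulate import default_scenario, generate

    ds = generate(default_scenario(), seed=101)
    m = build_matrix(ds.records)
    env = ds.environment.reindex(m.density.index)
    grid = mantel_screen(m, ds.attributes, env, n_perm=99, seed=5)
    return ds, grid


class TestMantelScreen:
    def test_grid_shape_five_ffgs_twelve_factors_four_months(self, screen):
        _, grid = screen
        assert len(grid) == 5 * 12 * 4
        assert grid.groupby(["month"]).size().eq(60).all()

    def test_constant_factor_gives_na(self):
        from ffgassess.core import build_matrix
        from ffgassess.simulate import default_scenario, generate

        ds = generate(default_scenario(), seed=103)
        m = build_matrix(ds.records)
        env = ds.environment.reindex(m.density.index).copy()
        env["pH"] = 7.7
        grid = mantel_screen(m, ds.attributes, env, n_perm=19, seed=0)
        assert grid.loc[grid["factor"] == "pH", "p_value"].isna().all()

    def test_planted_do_cg_link_among_smallest_p(self, screen):
        _, grid = screen
        cell = grid.set_index(["month", "ffg", "factor"])
        hit = False
        for month in ("March", "May", "July", "October"):
            sub = grid[grid["month"] == month]
            p = cell.loc[(month, "CG", "DO"), "p_value"]
            if p <= sub["p_value"].min() + 1e-12:
                hit = True
        assert hit
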