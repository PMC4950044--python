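"""ANOSIM against enumeration oracles, CCA/RDA against scikit-bio, partitioning."""

import itertools

import numpy as np
import pandas as pd
import pytest
import skbio
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kstest, rankdata
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.ordination import ca as skbio_ca
from skbio.stats.ordination import cca as skbio_cca

from aoamacro.beta import DistanceMatrix, bray_curtis
from aoamacro.community import (
    anosim_oneway,
    anosim_twoway,
    cca,
    rda,
    variation_partitioning,
)
from aoamacro.tables import OtuTable


def brute_force_anosim(d: np.ndarray, labels) -> tuple:
    """Independent enumerator: R and exact p over all label assignments."""
    labels = np.asarray(labels)
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu, ju])
    m = ranks.size

    def r_stat(lab):
        within = lab[iu] == lab[ju]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2)

    r_obs = r_stat(labels)
    seen = set()
    count = total = 0
    for perm in itertools.permutations(range(n)):
        key = tuple(labels[list(perm)])
        if key in seen:
            continue
        seen.add(key)
        total += 1
        if r_stat(np.asarray(key)) >= r_obs - 1e-12:
            count += 1
    return r_obs, count / total


def _worked_example():
    # groups (1,1,2,2); d12=1, d34=2, d13=3, d14=4, d23=5, d24=6
    d = np.zeros((4, 4))
    d[0, 1] = 1; d[2, 3] = 2; d[0, 2] = 3; d[0, 3] = 4; d[1, 2] = 5; d[1, 3] = 6
    d = d + d.T
    return DistanceMatrix(list("abcd"), d), np.array([1, 1, 2, 2])


class TestAnosimOneWay:
    def test_worked_example_r_and_exact_p(self):
        dm, labels = _worked_example()
        res = anosim_oneway(dm, labels, n_perm=None)
        assert res.R == pytest.approx(1.0, abs=1e-12)
        assert res.p_value == pytest.approx(1 / 3, abs=1e-12)

    def test_perfect_separation_r_one(self, rng):
        pts = np.vstack([rng.normal(0, 0.1, (4, 2)), rng.normal(10, 0.1, (4, 2))])
        d = squareform(pdist(pts))
        res = anosim_oneway(
            DistanceMatrix([str(i) for i in range(8)], d), [0] * 4 + [1] * 4,
            n_perm=199, seed=1,
        )
        assert res.R == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_brute_force_on_small_designs(self, rng, trial):
        n = int(rng.integers(5, 9))
        labels = rng.integers(0, 2, n)
        while len(np.unique(labels)) < 2 or min(np.bincount(labels)) < 2:
            labels = rng.integers(0, 2, n)
        d = squareform(pdist(rng.random((n, 3))))
        dm = DistanceMatrix([str(i) for i in range(n)], d)
        res = anosim_oneway(dm, labels, n_perm=None)
        r_bf, p_bf = brute_force_anosim(d, labels)
        assert res.R == pytest.approx(r_bf, abs=1e-12)
        assert res.p_value == pytest.approx(p_bf, abs=1e-12)

    def test_r_matches_skbio(self, rng):
        pts = rng.random((12, 3))
        d = squareform(pdist(pts))
        labels = ["a"] * 6 + ["b"] * 6
        res = anosim_oneway(DistanceMatrix([str(i) for i in range(12)], d), labels,
                            n_perm=99, seed=0)
        theirs = skbio_anosim(skbio.DistanceMatrix(d), grouping=labels, permutations=99)
        assert res.R == pytest.approx(theirs["test statistic"], abs=1e-12)

    def test_rank_based_invariance_under_monotone_transform(self, rng):
        pts = rng.random((10, 3))
        d = squareform(pdist(pts))
        labels = [0] * 5 + [1] * 5
        ids = [str(i) for i in range(10)]
        r1 = anosim_oneway(DistanceMatrix(ids, d), labels, n_perm=99, seed=3)
        r2 = anosim_oneway(DistanceMatrix(ids, d**2), labels, n_perm=99, seed=3)
        assert r1.R == pytest.approx(r2.R, abs=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_null_mean_r_near_zero_and_p_uniform(self, rng):
        """Random labels: mean R ~ 0 and permutation p ~ Uniform(0,1]."""
        rs, ps = [], []
        for rep in range(200):
            d = squareform(pdist(rng.random((12, 3))))
            labels = rng.permutation([0] * 6 + [1] * 6)
            res = anosim_oneway(
                DistanceMatrix([str(i) for i in range(12)], d), labels,
                n_perm=199, seed=int(rng.integers(2**31)),
            )
            rs.append(res.R)
            ps.append(res.p_value)
        rs = np.array(rs)
        assert abs(rs.mean()) < 2 * rs.std(ddof=1) / np.sqrt(len(rs))
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_singleton_group_rejected(self):
        dm, _ = _worked_example()
        with pytest.raises(ValueError, match="need >= 2"):
            anosim_oneway(dm, [1, 2, 2, 2])

    def test_constant_matrix_r_zero_with_warning(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(list("abcd"), d)
        with pytest.warns(UserWarning, match="constant"):
            res = anosim_oneway(dm, [1, 1, 2, 2])
        assert res.R == 0.0


class TestAnosimTwoWay:
    def _three_strata(self):
        """Three copies of the worked example as strata of factor B."""
        n = 12
        d = np.zeros((n, n))
        rng = np.random.default_rng(0)
        block = _worked_example()[0].values
        for k in range(3):
            s = slice(4 * k, 4 * k + 4)
            d[s, s] = block
        # fill cross-stratum distances arbitrarily (never used within strata)
        mask = d == 0
        np.fill_diagonal(mask, False)
        d[mask] = rng.uniform(7, 9, mask.sum())
        d = np.triu(d, 1)
        d = d + d.T
        dm = DistanceMatrix([str(i) for i in range(n)], d)
        a = np.tile([1, 1, 2, 2], 3)
        b = np.repeat([0, 1, 2], 4)
        return dm, a, b

    def test_perfect_within_stratum_separation(self):
        dm, a, b = self._three_strata()
        res_a, _ = anosim_twoway(dm, a, b, n_perm=99, seed=0)
        assert res_a.R == pytest.approx(1.0, abs=1e-12)
        assert res_a.per_stratum_R == pytest.approx([1.0, 1.0, 1.0])

    def test_exhaustive_product_p_is_one_27th(self):
        dm, a, b = self._three_strata()
        res_a, _ = anosim_twoway(dm, a, b, n_perm=None)
        assert res_a.p_value == pytest.approx(1 / 27, abs=1e-12)

    def test_constant_factor_within_strata_inestimable(self):
        dm, _, b = self._three_strata()
        a_const = np.repeat([1, 2, 3], 4)  # equals b: single level per stratum
        with pytest.raises(ValueError, match="inestimable"):
            anosim_twoway(dm, a_const, b, n_perm=99, seed=0)

    def test_survey_provinces_and_layers_separate(self, small_survey):
        _, _, _, fp, meta = small_survey
        from aoamacro.tables import align_samples

        sub, msub = align_samples(fp, meta)
        d = bray_curtis(sub)
        res_p, res_l = anosim_twoway(
            d, msub["province"].to_numpy(), msub["layer"].to_numpy(),
            n_perm=199, seed=1, names=("province", "layer"),
        )
        assert res_p.R > 0 and res_p.p_value < 0.05
        assert res_l.R > 0 and res_l.p_value < 0.05


class TestCca:
    def test_block_table_fully_constrained(self):
        y = OtuTable(list("abcd"), ["x", "y"],
                     [[10, 0], [10, 0], [0, 10], [0, 10]], "counts")
        res = cca(y, np.array([[1.0], [1.0], [0.0], [0.0]]))
        assert res.extras["total_inertia"] == pytest.approx(1.0, abs=1e-12)
        assert res.eigenvalues[0] == pytest.approx(1.0, abs=1e-10)
        assert res.prop_explained[0] == pytest.approx(1.0, abs=1e-10)

    def test_saturated_constraints_equal_ca(self, rng):
        y = rng.integers(1, 20, size=(6, 8)).astype(float)
        x = np.eye(6)
        res = cca(OtuTable([f"s{i}" for i in range(6)],
                           [f"o{j}" for j in range(8)], y, "counts"), x)
        ca_res = skbio_ca(pd.DataFrame(y))
        theirs = ca_res.eigvals.to_numpy()
        theirs = theirs[theirs > 1e-12]
        np.testing.assert_allclose(res.eigenvalues[: len(theirs)], theirs, atol=1e-9)

    def test_intercept_only_constraint_zero_inertia(self):
        y = OtuTable(list("abc"), ["x", "y"], [[5, 1], [2, 2], [1, 5]], "counts")
        res = cca(y, np.ones((3, 1)))
        assert res.extras["constrained_inertia"] == pytest.approx(0.0, abs=1e-12)

    def test_total_inertia_is_chi_square_over_total(self, rng):
        y = rng.integers(1, 30, size=(7, 5)).astype(float)
        from scipy.stats import chi2_contingency

        chi2 = chi2_contingency(y, correction=False)[0]
        res = cca(OtuTable([f"s{i}" for i in range(7)],
                           [f"o{j}" for j in range(5)], y, "counts"),
                  rng.random((7, 2)))
        assert res.extras["total_inertia"] == pytest.approx(chi2 / y.sum(), rel=1e-9)

    def test_constrained_inertia_bounded_by_total(self, rng):
        y = rng.integers(1, 30, size=(8, 6)).astype(float)
        res = cca(OtuTable([f"s{i}" for i in range(8)],
                           [f"o{j}" for j in range(6)], y, "counts"),
                  rng.random((8, 2)))
        assert res.extras["constrained_inertia"] <= res.extras["total_inertia"] + 1e-9

    def test_matches_skbio_cca_eigenvalues(self, rng):
        y = rng.integers(1, 25, size=(10, 7)).astype(float)
        x = rng.random((10, 3))
        res = cca(OtuTable([f"s{i}" for i in range(10)],
                           [f"o{j}" for j in range(7)], y, "counts"), x)
        theirs = skbio_cca(pd.DataFrame(y), pd.DataFrame(x)).eigvals.to_numpy()
        k = min(len(res.eigenvalues), 3)
        np.testing.assert_allclose(res.eigenvalues[:k], theirs[:k], atol=1e-9)

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError, match="all-zero sample"):
            cca(OtuTable(list("ab"), ["x", "y"], [[0, 0], [1, 2]], "counts"),
                np.ones((2, 1)))

    def test_collinear_columns_warned_and_dropped(self, rng):
        y = rng.integers(1, 9, size=(6, 4)).astype(float)
        x = rng.random((6, 1))
        x2 = np.hstack([x, 2 * x])
        with pytest.warns(UserWarning, match="collinear"):
            res = cca(OtuTable([f"s{i}" for i in range(6)],
                               [f"o{j}" for j in range(4)], y, "counts"), x2)
        assert res.extras["dropped_constraints"] == [1]


class TestRda:
    def test_exact_linear_r2_one(self, rng):
        x = rng.random((20, 2))
        y = x @ rng.random((2, 5))
        res = rda(y, x)
        assert res.extras["r_squared"] == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_predictor_r2_zero(self):
        n = 16
        x = np.cos(2 * np.pi * np.arange(n) / n)[:, None]
        y = np.sin(2 * np.pi * np.arange(n) / n)[:, None]
        res = rda(y, x)
        assert res.extras["r_squared"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_vegan_reference_values(self, rng):
        """Frozen oracle: vegan::rda on the same 15x6 table gives
        R2 = 0.101505, adjusted R2 = -0.04824412 and constrained
        eigenvalues (0.03697859, 0.006634062)."""
        y = rng.random((15, 6))
        x = rng.random((15, 2))
        res = rda(y, x)
        assert res.extras["r_squared"] == pytest.approx(0.101505, abs=1e-6)
        assert res.extras["adj_r_squared"] == pytest.approx(-0.04824412, abs=1e-6)
        np.testing.assert_allclose(
            res.eigenvalues[:2], [0.03697859, 0.006634062], atol=1e-7
        )

    def test_partial_with_empty_covariates_identical(self, rng):
        y = rng.random((12, 4))
        x = rng.random((12, 2))
        a = rda(y, x)
        b = rda(y, x, covariates=np.zeros((12, 0)))
        assert a.extras == b.extras
        np.testing.assert_array_equal(a.eigenvalues, b.eigenvalues)

    def test_partial_removes_covariate_signal(self, rng):
        z = rng.random((30, 1))
        y = z @ np.ones((1, 3)) + 0.01 * rng.random((30, 3))
        res = rda(y, z, covariates=z)
        assert res.extras["r_squared"] == pytest.approx(0.0, abs=1e-9)

    def test_null_adjusted_r2_centered_on_zero(self, rng):
        vals = []
        for _ in range(200):
            y = rng.random((30, 4))
            x = rng.random((30, 3))
            vals.append(rda(y, x).extras["adj_r_squared"])
        vals = np.array(vals)
        assert abs(vals.mean()) < 2 * vals.std(ddof=1) / np.sqrt(len(vals))

    def test_too_many_predictors_rejected(self, rng):
        with pytest.raises(ValueError, match="underdetermined"):
            rda(rng.random((5, 2)), rng.random((5, 6)))


class TestVariationPartitioning:
    def test_orthogonal_blocks_recover_designed_fractions(self):
        """Mutually orthogonal predictors recover their unique R^2 shares."""
        n = 64
        t = np.arange(n)
        env = np.cos(2 * np.pi * t / n)[:, None]
        space = np.sin(2 * np.pi * t / n)[:, None]
        time = np.cos(4 * np.pi * t / n)[:, None]
        y = 3.0 * env + 2.0 * space + 1.0 * time
        part = variation_partitioning(y, env, space, time)
        ss = {"env": 9.0, "space": 4.0, "time": 1.0}
        tot = sum(ss.values())
        # y is exactly explained by the three blocks, so adj R^2(all) = 1
        assert part.total_explained == pytest.approx(1.0, abs=1e-9)
        for name, val in ss.items():
            # unique fraction = adjR^2(all) - adjR^2(other two); with exact
            # orthogonal sinusoids this is (val/tot) * (n-1)/(n-2-1)
            expected = (val / tot) * (n - 1) / (n - 3)
            assert part.fractions[name] == pytest.approx(expected, abs=1e-6)
        overlaps = [v for k, v in part.fractions.items() if "&" in k]
        # overlaps are small Ezekiel corrections, near zero by construction
        assert np.allclose(overlaps, 0.0, atol=0.02)
        assert max(np.abs(overlaps)) < min(part.fractions[k] for k in ss)

    def test_identical_env_space_blocks_share_overlap(self, rng):
        n = 40
        env = rng.random((n, 2))
        time = rng.random((n, 1))
        y = env @ np.ones((2, 3)) + 0.1 * rng.random((n, 3))
        part = variation_partitioning(y, env, env, time)
        assert part.fractions["env"] == pytest.approx(0.0, abs=1e-9)
        assert part.fractions["space"] == pytest.approx(0.0, abs=1e-9)
        assert part.fractions["env&space"] > 0.5

    def test_fractions_and_residual_sum_to_one(self, rng):
        y = rng.random((30, 5))
        part = variation_partitioning(
            y, rng.random((30, 2)), rng.random((30, 2)), rng.random((30, 1))
        )
        assert sum(part.fractions.values()) + part.residual == pytest.approx(1.0, abs=1e-9)
        assert part.total_explained == pytest.approx(
            sum(part.fractions.values()), abs=1e-9
        )

    def test_pure_noise_total_near_zero(self, rng):
        vals = []
        for _ in range(100):
            y = rng.random((30, 3))
            part = variation_partitioning(
                y, rng.random((30, 1)), rng.random((30, 1)), rng.random((30, 1))
            )
            vals.append(part.total_explained)
        vals = np.array(vals)
        assert abs(vals.mean()) < 2 * vals.std(ddof=1) / np.sqrt(len(vals))
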