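"""Permutation, KS, FDR, mixed-model and spin-test machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import funcgrad as fg
from funcgrad.inference import InferenceError, interaction_family


class TestPairedPermutation:
    def test_exhaustive_equal_positive_differences(self):
        """n=5 all-equal positive differences: two-sided p = 2/32."""
        res = fg.paired_permutation([1.0] * 5, [0.0] * 5, n_perm=1000, seed=0)
        assert res.exhaustive
        assert res.p_uncorrected == pytest.approx(0.0625)

    def test_antisymmetric_differences_give_p_one(self):
        on = np.array([1.0, -1.0, 2.0, -2.0, 0.5, -0.5])
        res = fg.paired_permutation(on, np.zeros(6), n_perm=1000, seed=0)
        assert res.t == pytest.approx(0.0)
        assert res.p_uncorrected == 1.0

    def test_all_zero_differences_warn(self):
        with pytest.warns(RuntimeWarning):
            res = fg.paired_permutation([1.0] * 5, [1.0] * 5, n_perm=100, seed=0)
        assert res.t == 0.0
        assert res.p_uncorrected == 1.0

    def test_null_calibration(self):
        """Rejection rate at alpha=0.05 stays near nominal under the null."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 1000
        for i in range(n_rep):
            d = rng.standard_normal(12)
            res = fg.paired_permutation(d, np.zeros(12), n_perm=200, seed=i)
            rejections += res.p_uncorrected <= 0.05
        assert 0.035 <= rejections / n_rep <= 0.065

    def test_reproducible_from_seed(self, rng):
        on, off = rng.standard_normal((2, 15))
        a = fg.paired_permutation(on, off, n_perm=500, seed=9)
        b = fg.paired_permutation(on, off, n_perm=500, seed=9)
        assert a == b


class TestMaxstatFamily:
    def test_single_metric_family_fwe_equals_uncorrected(self, rng):
        on, off = rng.standard_normal((2, 10)), rng.standard_normal((2, 10))
        res = fg.maxstat_family(on.T[:, :1], off.T[:, :1], ["m"], n_perm=300, seed=1)[0]
        assert res.p_fwe == res.p_uncorrected

    def test_fwe_dominates_uncorrected(self, rng):
        on = rng.standard_normal((12, 8))
        off = rng.standard_normal((12, 8))
        for r in fg.maxstat_family(on, off, n_perm=300, seed=4):
            assert r.p_fwe >= r.p_uncorrected

    def test_planted_effect_vs_null_metrics(self, rng):
        n = 14
        off = rng.standard_normal((n, 5))
        on = off + rng.standard_normal((n, 5)) * 0.2
        on[:, 2] += 5.0  # huge planted effect on one metric
        results = fg.maxstat_family(on, off, n_perm=400, seed=7)
        assert results[2].p_fwe == pytest.approx(1 / 401)
        for j in (0, 1, 3, 4):
            assert results[j].p_fwe > 0.5


class TestKSAndFDR:
    def test_ks_examples(self):
        assert fg.ks_compare([1, 2, 3], [1, 2, 3]).d_statistic == 0.0
        assert fg.ks_compare([1, 2, 3], [4, 5, 6]).d_statistic == 1.0

    def test_bh_stepup_hand_example(self):
        adj = fg.bh_fdr([0.01, 0.02, 0.04])
        assert np.allclose(adj, [0.03, 0.03, 0.04])

    def test_bh_degenerate_inputs(self):
        assert fg.bh_fdr([0.2]) == pytest.approx([0.2])
        assert np.allclose(fg.bh_fdr([0.5, 0.5, 0.5]), 0.5)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=20,
        )
    )
    def test_bh_is_monotone_dominating_and_capped(self, pvals):
        adj = fg.bh_fdr(pvals)
        p = np.asarray(pvals)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestInteractionModel:
    @staticmethod
    def _simulate(n, beta_state, beta_inter, rng, sigma_e=0.5, sigma_u=0.5):
        doses = np.clip(rng.normal(680.0, 400.0, n), 1.0, None)
        z = (doses - doses.mean()) / doses.std(ddof=1)
        u = rng.normal(0, sigma_u, n)
        rows = []
        for i in range(n):
            for state, s in (("OFF", 0.0), ("ON", 1.0)):
                y = 1.0 + beta_state * s + 0.2 * z[i] + beta_inter * s * z[i]
                y += u[i] + rng.normal(0, sigma_e)
                rows.append({"subject": f"s{i}", "state": state, "value": y})
        data = pd.DataFrame(rows)
        dose_tab = pd.DataFrame({"subject": [f"s{i}" for i in range(n)], "DDE": doses})
        return data, dose_tab

    def test_identical_doses_rejected(self, rng):
        data, doses = self._simulate(8, 0.5, 0.3, rng)
        doses["DDE"] = 500.0
        with pytest.raises(InferenceError, match="identical"):
            fg.fit_state_dose_interaction(data, doses)

    def test_recovers_planted_interaction(self, rng):
        beta = 0.5
        estimates = []
        for _ in range(60):
            data, doses = self._simulate(27, 0.4, beta, rng)
            res = fg.fit_state_dose_interaction(data, doses)
            estimates.append(res.estimates["state_x_dose_z"])
            assert res.df_den == 25
        assert np.mean(estimates) == pytest.approx(beta, rel=0.10)

    def test_null_interaction_calibrated(self, rng):
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            data, doses = self._simulate(27, 0.4, 0.0, rng)
            res = fg.fit_state_dose_interaction(data, doses)
            rejections += res.p_value <= 0.05
        assert 0.03 <= rejections / n_rep <= 0.08

    def test_family_fdr_filled(self, rng):
        tables = {}
        for m in range(3):
            data, doses = self._simulate(10, 0.2, 0.0, rng)
            tables[f"m{m}"] = data
        results = interaction_family(tables, doses)
        assert all(r.p_fdr is not None and r.p_fdr >= r.p_value for r in results)


class TestDeltaMap:
    @staticmethod
    def _labeled(scores3, extra=2):
        p = scores3.shape[0]
        k = 3 + extra
        scores = np.column_stack([scores3, np.zeros((p, extra))])
        lam = np.linspace(0.9, 0.5, k)
        g = fg.GradientSet(
            scores=scores,
            eigenvalues=lam,
            variance_explained=lam / lam.sum(),
            alpha=0.5,
            parcel_ids=tuple(range(p)),
            labels={0: "G1", 1: "G2", 2: "G3"},
        )
        return g

    def test_zero_and_constant_delta(self, rng):
        base = rng.standard_normal((10, 3))
        on = {"a": self._labeled(base + np.array([0, 2.0, 0])), "b": self._labeled(base)}
        off = {"a": self._labeled(base), "b": self._labeled(base)}
        d = fg.delta_map(on, off, gradient="G2")
        assert np.allclose(d, 1.0)  # mean of +2 and 0
        assert np.allclose(fg.delta_map(on, on, gradient="G2"), 0.0)

    def test_unpaired_subject_rejected(self, rng):
        base = rng.standard_normal((10, 3))
        with pytest.raises(InferenceError, match="unpaired"):
            fg.delta_map({"a": self._labeled(base)}, {"b": self._labeled(base)})


class TestSpin:
    def test_rotations_deterministic_and_within_hemisphere(self, small_scheme):
        a = fg.spin_rotations(small_scheme, 20, seed=3)
        b = fg.spin_rotations(small_scheme, 20, seed=3)
        assert np.array_equal(a, b)
        left = set(small_scheme.hemisphere_indices("L"))
        for perm in a:
            assert set(perm[list(left)]) <= left
            assert not np.array_equal(perm, np.arange(small_scheme.n_parcels))

    def test_smooth_map_autocorrelation_preserved(self, scheme400):
        smooth = fg.generate_autocorrelated_map(scheme400, 0.8, seed=0)
        xyz = scheme400.centroids()
        d = np.arccos(np.clip(xyz @ xyz.T, -1, 1))
        iu = np.triu_indices_from(d, 1)
        near = d[iu] < np.quantile(d[iu], 0.05)

        def neighbor_corr(m):
            prod = np.outer(m - m.mean(), m - m.mean())[iu]
            return prod[near].mean() / m.var()

        base = neighbor_corr(smooth)
        perms = fg.spin_rotations(scheme400, 20, seed=1)
        rotated = np.mean([neighbor_corr(smooth[p]) for p in perms])
        assert abs(rotated - base) <= 0.2 * abs(base)

    def test_self_correlation_minimal_p(self, scheme400):
        smooth = fg.generate_autocorrelated_map(scheme400, 0.8, seed=2)
        perms = fg.spin_rotations(scheme400, 99, seed=5)
        res = fg.spin_correlate(smooth, smooth, perms)
        assert res.rho == pytest.approx(1.0)
        assert res.p_spin == pytest.approx(1 / 100)

    def test_constant_map_rejected(self, small_scheme):
        perms = fg.spin_rotations(small_scheme, 10, seed=0)
        with pytest.raises(InferenceError):
            fg.spin_correlate(np.ones(28), np.arange(28.0), perms)


class TestTermRanking:
    def test_gradient_and_negation_rank_first(self, rng):
        g = rng.standard_normal(50)
        maps = pd.DataFrame(
            {
                "self": g,
                "anti": -g,
                **{f"noise{i}": rng.standard_normal(50) for i in range(8)},
            }
        )
        ranked = fg.rank_term_maps(g, maps, top_k=2)
        pos = ranked[ranked.direction == "positive"]
        neg = ranked[ranked.direction == "negative"]
        assert pos.iloc[0].term == "self" and pos.iloc[0].rho == pytest.approx(1.0)
        assert neg.iloc[0].term == "anti" and neg.iloc[0].rho == pytest.approx(-1.0)

    def test_matches_scipy_on_random_maps(self, rng):
        from scipy import stats

        g = rng.standard_normal(40)
        maps = pd.DataFrame({f"t{i}": rng.standard_normal(40) for i in range(10)})
        ranked = fg.rank_term_maps(g, maps, top_k=5)
        for row in ranked.itertuples():
            expected = stats.spearmanr(g, maps[row.term]).statistic
            assert row.rho == pytest.approx(expected)
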