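"""Synthetic cohort generator: schemes, target covariances, maps, determinism."""

import numpy as np
import pytest

import funcgrad as fg
from funcgrad.synthetic import (
    GenerationError,
    build_target_covariance,
    nearest_psd_correlation,
    spatial_anomaly,
)
from funcgrad.parcellation import YEO7_NETWORKS, SchemeError


class TestParcelScheme:
    def test_default_400_parcel_scheme(self, scheme400):
        assert scheme400.n_parcels == 400
        counts = scheme400.table["hemisphere"].value_counts()
        assert counts["L"] == counts["R"] == 200
        sizes = scheme400.table["network"].value_counts()
        assert tuple(sizes[n] for n in YEO7_NETWORKS) == fg.SCHAEFER400_SIZES

    def test_minimal_scheme_two_parcels_per_network(self):
        scheme = fg.generate_parcel_scheme(14, (2,) * 7, seed=0)
        assert all(len(scheme.indices(n)) == 2 for n in YEO7_NETWORKS)

    def test_size_mismatch_rejected(self):
        with pytest.raises(SchemeError):
            fg.generate_parcel_scheme(20, (2,) * 7, seed=0)
        with pytest.raises(SchemeError):
            fg.generate_parcel_scheme(15, (3, 2, 2, 2, 2, 2, 2), seed=0)

    def test_deterministic_given_seed(self):
        a = fg.generate_parcel_scheme(28, (4,) * 7, seed=3)
        b = fg.generate_parcel_scheme(28, (4,) * 7, seed=3)
        assert a.table.equals(b.table)

    def test_centroids_unit_norm_and_clustered(self, small_scheme):
        xyz = small_scheme.centroids()
        assert np.allclose(np.linalg.norm(xyz, axis=1), 1.0, atol=1e-9)
        # network patches are spatially coherent: mean within-network
        # great-circle distance below mean between-network distance
        d = np.arccos(np.clip(xyz @ xyz.T, -1, 1))
        labels = small_scheme.network_labels
        same = labels[:, None] == labels[None, :]
        np.fill_diagonal(same, False)
        off = ~np.eye(len(labels), dtype=bool)
        assert d[same].mean() < d[~same & off].mean()


class TestTargetCovariance:
    def test_zero_effect_makes_conditions_identical(self, small_spec):
        spec = fg.CohortSpec(**{**small_spec.__dict__, "effect_size": 0.0})
        on = build_target_covariance(spec, "ON")
        off = build_target_covariance(spec, "OFF")
        assert np.array_equal(on, off)

    def test_perfect_blocks_give_block_diagonal(self):
        spec = fg.CohortSpec(
            n_pairs=3, n_controls=0, n_timepoints=40, n_parcels=14,
            network_sizes=(2,) * 7, within_r=1.0, between_r=0.0,
            effect_size=0.0, subject_sd=0.0, spatial_strength=0.0,
        )
        cov = build_target_covariance(spec, "OFF")
        labels = np.repeat(np.arange(7), 2)
        same = labels[:, None] == labels[None, :]
        assert np.allclose(cov[same], 1.0)
        assert np.allclose(cov[~same], 0.0)

    def test_effect_pair_reduction_read_back(self, small_scheme):
        """ON-state between-block correlation drops by effect_size at mean dose."""
        spec = fg.CohortSpec(
            n_pairs=3, n_controls=0, n_timepoints=40, n_parcels=28,
            network_sizes=(4,) * 7, within_r=0.4, between_r=0.2,
            effect_size=0.1, subject_sd=0.0, spatial_strength=0.0,
        )
        on = build_target_covariance(spec, "ON", dose_z=0.0)
        vis = np.arange(0, 4)
        dan = np.arange(8, 12)
        block_mean = on[np.ix_(vis, dan)].mean()
        assert block_mean == pytest.approx(0.2 - 0.1, abs=1e-9)

    def test_spatial_component_preserves_block_means(self, small_scheme):
        spec = fg.CohortSpec(
            n_pairs=3, n_controls=0, n_timepoints=40, n_parcels=28,
            network_sizes=(4,) * 7, within_r=0.4, between_r=0.2,
            effect_size=0.1, subject_sd=0.0, spatial_strength=0.3,
        )
        spatial = spatial_anomaly(small_scheme, spec.spatial_scale)
        on = build_target_covariance(spec, "ON", 0.0, None, spatial)
        vis, dan = np.arange(0, 4), np.arange(8, 12)
        # PSD repair may move entries slightly; block mean stays close
        assert on[np.ix_(vis, dan)].mean() == pytest.approx(0.1, abs=0.02)

    def test_psd_repair_restores_unit_diagonal(self, rng):
        base = np.eye(5)
        base[0, 1] = base[1, 0] = 0.99
        base[0, 2] = base[2, 0] = 0.99
        base[1, 2] = base[2, 1] = -0.9  # inconsistent -> indefinite
        repaired = nearest_psd_correlation(base)
        assert np.linalg.eigvalsh(repaired).min() >= -1e-10
        assert np.allclose(np.diag(repaired), 1.0)

    def test_invalid_spec_rejected(self):
        with pytest.raises(GenerationError):
            fg.CohortSpec(n_parcels=10, network_sizes=(2,) * 7)
        with pytest.raises(GenerationError):
            fg.CohortSpec(within_r=0.2, between_r=0.3)


class TestGenerateCohort:
    def test_shape_and_pairing(self, small_cohort, small_spec):
        scans = small_cohort.scans
        assert len(scans) == small_spec.n_pairs * 2 + small_spec.n_controls
        by_subject = {}
        for s in scans:
            by_subject.setdefault(s.subject, []).append(s.condition)
        on_off = [c for c in by_subject.values() if sorted(c) == ["OFF", "ON"]]
        assert len(on_off) == small_spec.n_pairs
        assert all(s.n_timepoints == small_spec.n_timepoints for s in scans)
        assert (small_cohort.doses["DDE"] >= 0).all()
        assert len(small_cohort.doses) == small_spec.n_pairs

    def test_same_seed_bit_identical(self, small_spec):
        a = fg.generate_cohort(small_spec)
        b = fg.generate_cohort(small_spec)
        assert all(
            np.array_equal(x.data, y.data) for x, y in zip(a.scans, b.scans)
        )
        assert a.doses.equals(b.doses)

    def test_empirical_fc_converges_to_target(self):
        """Frobenius error of the sample FC shrinks with scan length."""
        base = dict(
            n_pairs=1, n_controls=0, n_parcels=28, network_sizes=(4,) * 7,
            effect_size=0.0, subject_sd=0.0,
        )
        errs = {}
        for T in (140, 5000):
            tot = 0.0
            for seed in range(20):
                spec = fg.CohortSpec(**base, n_timepoints=T, seed=seed)
                coh = fg.generate_cohort(spec)
                scan = coh.scans[0]
                target = build_target_covariance(
                    spec, "OFF", 0.0, None,
                    spatial_anomaly(coh.scheme, spec.spatial_scale),
                )
                emp = np.corrcoef(scan.data, rowvar=False)
                tot += np.linalg.norm(emp - target)
            errs[T] = tot / 20
        assert errs[5000] < errs[140]

    def test_null_effect_balanced_between_block_fc(self):
        """With effect_size 0, ON and OFF mean between-block r differ only by noise."""
        from scipy import stats as sps

        diffs = []
        for seed in range(8):
            spec = fg.CohortSpec(
                n_pairs=6, n_controls=0, n_timepoints=80, n_parcels=28,
                network_sizes=(4,) * 7, effect_size=0.0, seed=seed,
            )
            coh = fg.generate_cohort(spec)
            vis, dan = coh.scheme.indices("VIS"), coh.scheme.indices("DAN")
            for sub in {s.subject for s in coh.scans if s.condition == "ON"}:
                on = next(s for s in coh.scans if s.subject == sub and s.condition == "ON")
                off = next(s for s in coh.scans if s.subject == sub and s.condition == "OFF")
                r_on = np.corrcoef(on.data, rowvar=False)[np.ix_(vis, dan)].mean()
                r_off = np.corrcoef(off.data, rowvar=False)[np.ix_(vis, dan)].mean()
                diffs.append(r_on - r_off)
        t, p = sps.ttest_1samp(diffs, 0.0)
        assert p > 0.01


class TestAutocorrelatedMap:
    def test_zero_mean_unit_sd_and_deterministic(self, small_scheme):
        m1 = fg.generate_autocorrelated_map(small_scheme, 0.5, seed=1)
        m2 = fg.generate_autocorrelated_map(small_scheme, 0.5, seed=1)
        assert np.array_equal(m1, m2)
        assert m1.mean() == pytest.approx(0.0, abs=1e-12)
        assert m1.std() == pytest.approx(1.0, abs=1e-12)

    @staticmethod
    def _neighbor_distant_corr(scheme, smoothness, seeds):
        xyz = scheme.centroids()
        d = np.arccos(np.clip(xyz @ xyz.T, -1, 1))
        iu = np.triu_indices_from(d, 1)
        near = d[iu] < np.quantile(d[iu], 0.05)
        far = d[iu] > np.quantile(d[iu], 0.95)
        prods_near, prods_far = [], []
        for seed in seeds:
            m = fg.generate_autocorrelated_map(scheme, smoothness, seed=seed)
            outer = np.outer(m, m)[iu]
            prods_near.append(outer[near].mean())
            prods_far.append(outer[far].mean())
        return np.mean(prods_near), np.mean(prods_far)

    def test_smoothness_limits(self, scheme400):
        near_iid, _ = self._neighbor_distant_corr(scheme400, 1e-3, range(5))
        assert abs(near_iid) < 0.1
        near_smooth, far_smooth = self._neighbor_distant_corr(scheme400, 1.0, range(5))
        assert near_smooth > far_smooth
        assert near_smooth > 0.5
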