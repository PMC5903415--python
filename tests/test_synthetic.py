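"""Synthetic cohort generator: geometry, correlation structure, trends, I/O."""

import numpy as np
import pandas as pd
import pytest

import scnet as s
from scnet.dataset import read_dataset, write_dataset

from conftest import constant_block_model


class TestGenerateRegions:
    def test_rejects_odd_region_count(self):
        with pytest.raises(ValueError, match="even"):
            s.generate_regions(101, 4, seed=0)

    def test_rejects_too_many_modules(self):
        with pytest.raises(ValueError):
            s.generate_regions(10, 6, seed=0)

    def test_hemispheres_split_evenly_with_unit_sphere_coords(self):
        rs = s.generate_regions(308, 7, seed=1)
        assert (rs.hemisphere == "left").sum() == 154
        assert (rs.hemisphere == "right").sum() == 154
        assert np.allclose(np.linalg.norm(rs.sphere, axis=1), 1.0, atol=1e-9)
        assert len(np.unique(rs.module)) == 7

    def test_hemispheres_mirror_symmetric_in_sagittal_plane(self):
        rs = s.generate_regions(100, 4, seed=7)
        left = rs.sphere[rs.hemisphere == "left"]
        right = rs.sphere[rs.hemisphere == "right"]
        assert np.allclose(left, right * np.array([-1.0, 1.0, 1.0]))
        cl = rs.centroid[rs.hemisphere == "left"]
        cr = rs.centroid[rs.hemisphere == "right"]
        assert np.allclose(cl, cr * np.array([-1.0, 1.0, 1.0]))

    def test_single_module_degenerate_case(self):
        rs = s.generate_regions(4, 1, seed=0)
        assert np.all(rs.module == 1)
        assert np.allclose(np.linalg.norm(rs.sphere, axis=1), 1.0, atol=1e-9)

    def test_module_patches_spatially_contiguous(self):
        # within-patch great-circle distances should be smaller than
        # between-patch ones, computed by brute-force pairwise enumeration
        rs = s.generate_regions(100, 4, seed=7)
        left = rs.hemisphere == "left"
        v = rs.sphere[left]
        lab = rs.module[left]
        ang = np.arccos(np.clip(v @ v.T, -1.0, 1.0))
        iu = np.triu_indices(len(v), 1)
        same = lab[iu[0]] == lab[iu[1]]
        assert ang[iu][same].mean() < ang[iu][~same].mean()


class TestGenerateCohort:
    def test_independent_regions_have_null_sample_correlations(self, regions100):
        model = constant_block_model(0.0, 0.0)
        ds, _ = s.generate_cohort(
            s.CohortSpec(n_participants=300, seed=4), regions100, model,
            ct_slope_mean=0.0, ct_slope_sd=0.0)
        r = s.correlation_matrix(ds).weights
        iu = np.triu_indices(100, 1)
        # 95% of null |r| under 2/sqrt(n)
        assert np.mean(np.abs(r[iu]) < 2 / np.sqrt(300)) > 0.90

    def test_near_degenerate_within_correlation(self):
        from conftest import make_equal_block_regions

        rs = make_equal_block_regions(4, 2)
        model = constant_block_model(0.99, 0.0)
        ds, gt = s.generate_cohort(
            s.CohortSpec(n_participants=1000, seed=0), rs, model,
            ct_slope_mean=0.0, ct_slope_sd=0.0)
        r = s.correlation_matrix(ds).weights
        same = gt.module_labels[:, None] == gt.module_labels[None, :]
        np.fill_diagonal(same, False)
        assert r[same].min() > 0.9

    def test_sample_correlation_converges_to_model(self):
        # max-over-pairs deviation scales as ~1/sqrt(n); n is sized so the
        # 0.05 tolerance sits several sigma above the expected maximum
        from conftest import make_equal_block_regions

        rs = make_equal_block_regions(20, 2)
        model = constant_block_model(0.45, 0.2)
        ds, gt = s.generate_cohort(
            s.CohortSpec(n_participants=8000, seed=2), rs, model,
            ct_slope_mean=0.0, ct_slope_sd=0.0)
        r = s.correlation_matrix(ds).weights
        same = gt.module_labels[:, None] == gt.module_labels[None, :]
        np.fill_diagonal(same, False)
        expected = np.where(same, 0.45, 0.2)
        np.fill_diagonal(expected, 1.0)
        assert np.max(np.abs(r - expected)) < 0.05

    def test_windowed_mean_correlation_traces_convex_curve(self, regions100):
        # convex correlation model, no morphometric trends: argmin of the
        # windowed mean correlation should sit at the planted minimum;
        # quadratic argmin as independent oracle
        model = s.CovarianceModel(
            within_module_r=lambda a: 0.30 + 0.004 * (a - 19.5) ** 2,
            between_module_r=lambda a: 0.30 + 0.004 * (a - 19.5) ** 2,
            age_of_minimum=19.5)
        all_ages, all_meanr = [], []
        for seed in range(10):
            ds, _ = s.generate_cohort(
                s.CohortSpec(n_participants=300, seed=50 + seed), regions100,
                model, ct_slope_mean=0.0, ct_slope_sd=0.0)
            ws = s.make_windows(ds.ages)
            all_ages.extend(w.median_age for w in ws)
            all_meanr.extend(
                s.correlation_matrix(ds, w.indices).mean_offdiagonal()
                for w in ws)
        # pooled quadratic regression: one shared mean-correlation factor per
        # window makes single-seed argmins heavy-tailed, so the convexity and
        # minimum location are asserted on the pooled curve
        c2, c1, _ = np.polyfit(all_ages, all_meanr, 2)
        assert c2 > 0
        assert abs(-c1 / (2 * c2) - 19.5) < 0.5

    def test_regional_age_slopes_recovered_within_2_se(self, independent_cohort):
        ds, truth = independent_cohort
        ages = ds.ages
        X = ds.values.to_numpy()
        a = ages - ages.mean()
        slopes = (a @ (X - X.mean(axis=0))) / (a @ a)
        resid = X - X.mean(axis=0) - np.outer(a, slopes)
        se = np.sqrt((resid**2).sum(axis=0) / (len(ages) - 2) / (a @ a))
        frac = np.mean(np.abs(slopes - truth.ct_slopes) < 2 * se)
        assert frac >= 0.90

    def test_deterministic_in_seed(self, regions100):
        spec = s.CohortSpec(n_participants=50, seed=11)
        d1, _ = s.generate_cohort(spec, regions100)
        d2, _ = s.generate_cohort(spec, regions100)
        d3, _ = s.generate_cohort(s.CohortSpec(n_participants=50, seed=12),
                                  regions100)
        assert d1.values.equals(d2.values)
        assert not np.allclose(d1.values.to_numpy(), d3.values.to_numpy())

    def test_strata_counts_balanced(self, regions100):
        ds, _ = s.generate_cohort(s.CohortSpec(n_participants=297, seed=0),
                                  regions100)
        edges = np.linspace(14, 24, 6)
        counts = np.histogram(ds.ages, bins=edges)[0]
        assert counts.max() - counts.min() <= 2
        assert counts.sum() == 297


class TestDatasetIO:
    def test_roundtrip_identity(self, tmp_path, regions60):
        ds, truth = s.generate_cohort(
            s.CohortSpec(n_participants=20, seed=5), regions60,
            mt_depths=("70%", "wm1mm"))
        write_dataset(ds, tmp_path / "d", ground_truth=truth)
        back = read_dataset(tmp_path / "d")
        assert np.array_equal(back.values.to_numpy(), ds.values.to_numpy())
        assert np.array_equal(back.participants["age"].to_numpy(), ds.ages)
        assert set(back.mt) == {"70%", "wm1mm"}
        assert np.array_equal(back.mt["70%"].to_numpy(),
                              ds.mt["70%"].to_numpy())

    def test_ground_truth_roundtrip(self, tmp_path, regions60):
        ds, truth = s.generate_cohort(s.CohortSpec(n_participants=20, seed=5),
                                      regions60)
        write_dataset(ds, tmp_path / "d", ground_truth=truth)
        back = s.GroundTruth.from_json((tmp_path / "d" / "ground_truth.json").read_text())
        assert back.age_of_minimum == truth.age_of_minimum
        assert np.allclose(back.ct_slopes, truth.ct_slopes)

    def test_missing_age_names_participant(self, regions60):
        ds, _ = s.generate_cohort(s.CohortSpec(n_participants=20, seed=5),
                                  regions60)
        participants = ds.participants.copy()
        participants.loc["p0003", "age"] = np.nan
        with pytest.raises(ValueError, match="p0003"):
            s.CorticalDataset(values=ds.values, participants=participants,
                              regions=ds.regions)

    def test_region_count_mismatch_rejected(self, regions60):
        ds, _ = s.generate_cohort(s.CohortSpec(n_participants=20, seed=5),
                                  regions60)
        with pytest.raises(ValueError, match="mismatch"):
            s.CorticalDataset(values=ds.values,
                              participants=ds.participants,
                              regions=ds.regions.iloc[:-1])

    def test_malformed_directory_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="malformed"):
            read_dataset(tmp_path / "nowhere")


class TestSmoothCorticalMap:
    def test_bilateral_symmetry_and_smoothness(self, regions100):
        rng = np.random.default_rng(0)
        m = s.smooth_cortical_map(regions100, rng, noise=0.0)
        left = m[regions100.hemisphere == "left"]
        right = m[regions100.hemisphere == "right"]
        assert np.allclose(left, right)
        # neighbouring regions more similar than random pairs
        v = regions100.sphere
        ang = np.arccos(np.clip(v @ v.T, -1, 1))
        same_hemi = regions100.hemisphere[:, None] == regions100.hemisphere[None, :]
        iu = np.triu_indices(100, 1)
        near = (ang[iu] < 0.5) & same_hemi[iu]
        far = (ang[iu] > 2.0) & same_hemi[iu]
        dm = np.abs(m[iu[0]] - m[iu[1]])
        assert dm[near].mean() < dm[far].mean()
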