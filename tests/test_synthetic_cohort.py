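"""Phantom-cohort generator: geometry, planted effects, clinical marginals."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gisthabitat.synthetic_cohort import (
    CohortConfig,
    DegeneratePhantomError,
    PhantomSpec,
    build_cohort,
    clairvoyant_auc,
    design_auc,
    file_checksums,
    generate_cohort,
    generate_phantom,
    sample_clinical,
)


class TestGeneratePhantom:
    def test_sphere_volume_within_20pct(self):
        spec = PhantomSpec(
            diameter_mm=30, class_label="low", core_fraction=0.0,
            flatness_target=1.0, b_ratio=1.0, seed=0,
        )
        _, _, mask, _ = generate_phantom(spec)
        expected = 4.0 / 3.0 * np.pi * 15.0**3
        assert abs(mask.n_voxels - expected) / expected < 0.20

    def test_core_fraction_bookkeeping(self):
        spec = PhantomSpec(
            diameter_mm=34, class_label="high", core_fraction=0.3,
            skewness_target=-2.0, flatness_target=0.8, seed=3,
        )
        _, _, mask, truth = generate_phantom(spec)
        frac = (truth.labels == 3).sum() / mask.n_voxels
        assert 0.25 <= frac <= 0.35

    def test_seed_determinism(self):
        spec = PhantomSpec(
            diameter_mm=25, class_label="high", core_fraction=0.2,
            flatness_target=0.7, seed=11, euler_deg=(10, 20, 30),
        )
        a = generate_phantom(spec)
        b = generate_phantom(spec)
        np.testing.assert_array_equal(a[0].voxels, b[0].voxels)
        np.testing.assert_array_equal(a[1].voxels, b[1].voxels)
        np.testing.assert_array_equal(a[2].voxels, b[2].voxels)

    def test_coarse_spacing_degenerates(self):
        spec = PhantomSpec(
            diameter_mm=20, class_label="low", flatness_target=0.5,
            spacing_mm=(5.0, 5.0, 5.0), seed=0,
        )
        with pytest.raises(DegeneratePhantomError):
            generate_phantom(spec)

    def test_truth_labels_density_ordered(self, phantom_high):
        truth = phantom_high["truth"]
        unenh = phantom_high["unenhanced"].voxels
        means = [unenh[truth.labels == l].mean() for l in (1, 2, 3)]
        assert means[0] > means[1] > means[2]

    def test_venous_attenuates_core_skewness(self, phantom_high):
        """Enhancement partially homogenizes the core: the within-mask skew
        contrast of the venous phase is weaker than the unenhanced one."""
        mask = phantom_high["mask"].voxels.astype(bool)
        core = phantom_high["truth"].labels == 3
        sk_u = stats.skew(phantom_high["unenhanced"].voxels[core])
        sk_v = stats.skew(phantom_high["venous"].voxels[core])
        assert abs(sk_v) < abs(sk_u)
        assert mask.sum() > core.sum()

    def test_skewness_magnitude_monotone_in_core_fraction(self):
        """Planted-effect monotonicity over a 50-phantom batch per level."""
        mean_abs_skew = []
        for cf in (0.0, 0.15, 0.30):
            vals = []
            for seed in range(50):
                spec = PhantomSpec(
                    diameter_mm=24, class_label="high", core_fraction=cf,
                    skewness_target=-2.0, flatness_target=0.85, seed=seed,
                )
                unenh, _, mask, _ = generate_phantom(spec)
                vals.append(abs(stats.skew(unenh.voxels[mask.voxels.astype(bool)])))
            mean_abs_skew.append(np.mean(vals))
        assert mean_abs_skew[0] < mean_abs_skew[1] < mean_abs_skew[2]


class TestSampleClinical:
    def test_age_mean_matches_configured_marginal(self):
        rng = np.random.default_rng(0)
        ages = [sample_clinical("low", 1, rng).age for _ in range(10_000)]
        assert abs(np.mean(ages) - 62.39) < 0.5

    def test_sex_frequency_matches_configured_marginal(self):
        rng = np.random.default_rng(1)
        recs = [sample_clinical("high", 1, rng) for _ in range(10_000)]
        f_frac = np.mean([r.sex == "F" for r in recs])
        assert abs(f_frac - 24 / 44) < 0.02

    def test_size_clipped_to_inclusion_range(self):
        rng = np.random.default_rng(2)
        sizes = [sample_clinical("high", 2, rng).size_cm for _ in range(2000)]
        assert min(sizes) >= 2.0 and max(sizes) <= 5.0

    def test_integer_seed_reproducible(self):
        assert sample_clinical("low", 2, 42) == sample_clinical("low", 2, 42)


class TestCohort:
    def test_default_cohort_size(self):
        assert CohortConfig().n_total == 368
        assert len(build_cohort(seed=0)) == 368

    def test_configured_counts(self):
        cfg = CohortConfig(center1_low=10, center1_high=2, center2_low=5, center2_high=1)
        man = build_cohort(cfg, seed=0)
        frame = man.to_frame()
        assert len(frame) == 18
        assert (frame.label == "high").sum() == 3
        assert frame.case_id.is_unique

    def test_written_cohort_is_byte_deterministic(self, tmp_path):
        cfg = CohortConfig(center1_low=2, center1_high=1, center2_low=1, center2_high=1)
        man_a = generate_cohort(cfg, seed=9, out_dir=tmp_path / "a")
        man_b = generate_cohort(cfg, seed=9, out_dir=tmp_path / "b")
        drop = ["path_unenhanced", "path_venous", "path_mask"]  # differ by out_dir
        pd.testing.assert_frame_equal(
            man_a.to_frame().drop(columns=drop), man_b.to_frame().drop(columns=drop)
        )
        sums_a = file_checksums(tmp_path / "a")
        sums_b = file_checksums(tmp_path / "b")
        assert sums_a == sums_b and len(sums_a) == 5 * 3 + 1
        man_a.validate(check_files=True)

    def test_clairvoyant_separability_at_least_090(self):
        man = build_cohort(seed=4)
        assert clairvoyant_auc(man) >= 0.9

    def test_clairvoyant_matches_design_auc_within_005(self):
        man = build_cohort(seed=5)
        assert abs(clairvoyant_auc(man) - design_auc(50_000)) < 0.05
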