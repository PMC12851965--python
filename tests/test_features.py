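"""Feature extraction schema, first-order oracle agreement, and the
stability / redundancy filters."""

import numpy as np
import pandas as pd
import pytest

from gisthabitat.features import (
    EXPECTED_TOTAL,
    FeatureExtractor,
    firstorder_features,
    firstorder_oracle,
    icc_2_1,
    jitter_mask,
    redundancy_filter,
    stability_filter,
)
from gisthabitat.volume import ImageVolume, TumorMask


@pytest.fixture(scope="module")
def default_extractor():
    return FeatureExtractor()


class TestSchema:
    def test_default_bank_has_exactly_1045_named_features(self, default_extractor):
        names = default_extractor.feature_names
        assert len(names) == EXPECTED_TOTAL
        assert len(set(names)) == EXPECTED_TOTAL
        assert "wavelet-LHH_firstorder_Skewness" in names
        assert "original_shape_Flatness" in names

    def test_shape_features_only_from_original_image(self, default_extractor):
        shape_feats = [n for n in default_extractor.feature_names if "_shape_" in n]
        assert len(shape_feats) == 14
        assert all(n.startswith("original_") for n in shape_feats)

    def test_full_extraction_on_phantom(self, phantom_high, default_extractor):
        vec = default_extractor.extract(phantom_high["unenhanced"], phantom_high["mask"])
        assert len(vec) == EXPECTED_TOTAL
        assert all(np.isfinite(v) for v in vec.values())
        assert tuple(vec) == default_extractor.feature_names

    def test_undersized_region_yields_missing_record(self, phantom_high):
        ex = FeatureExtractor(families=("firstorder",), filters=())
        region = np.zeros(phantom_high["unenhanced"].shape, dtype=bool)
        region[30, 30, 30] = True  # 1 voxel << 27
        vec = ex.extract(phantom_high["unenhanced"], region)
        assert len(vec) == len(ex.feature_names)
        assert all(np.isnan(v) for v in vec.values())


class TestFeatureValues:
    def test_sphere_flatness_near_one(self):
        grid = np.indices((25, 25, 25))
        sphere = ((grid - 12) ** 2).sum(axis=0) <= 10**2
        img = ImageVolume(np.random.default_rng(0).normal(size=(25, 25, 25)))
        ex = FeatureExtractor(families=("shape",), filters=())
        vec = ex.extract(img, sphere)
        assert abs(vec["original_shape_Flatness"] - 1.0) < 0.05
        assert abs(vec["original_shape_Elongation"] - 1.0) < 0.05

    def test_symmetric_histogram_has_near_zero_skewness(self):
        vals = np.concatenate([np.linspace(-1, 1, 2000)])
        fo = firstorder_features(vals)
        assert abs(fo["Skewness"]) < 0.05

    def test_right_tail_gives_positive_skewness(self):
        fo = firstorder_oracle([0.0, 0.0, 0.0, 10.0])
        assert fo["Skewness"] > 0

    def test_oracle_simple_mean(self):
        assert firstorder_oracle([1, 2, 3, 4])["Mean"] == pytest.approx(2.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_extractor_agrees_with_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.gamma(2.0, 1.5, size=500)
        got = firstorder_features(vals, voxel_volume_mm3=1.0)
        want = firstorder_oracle(vals, voxel_volume_mm3=1.0)
        for name, w in want.items():
            g = got[name]
            assert g == pytest.approx(w, rel=1e-4, abs=1e-10), name


class TestStabilityFilter:
    def _tables(self, rng, n=40, p=6):
        base = rng.normal(size=(n, p))
        cols = [f"f{i}" for i in range(p)]
        return pd.DataFrame(base, columns=cols)

    def test_identical_tables_retain_everything(self, rng):
        t = self._tables(rng)
        assert stability_filter(t, t) == list(t.columns)

    def test_noise_replaced_feature_is_dropped(self, rng):
        t = self._tables(rng)
        pert = t + rng.normal(0, 0.01, size=t.shape)  # high agreement
        pert["f3"] = rng.normal(size=len(t))          # independent noise
        kept = stability_filter(t, pert)
        assert "f3" not in kept
        assert set(kept) >= {"f0", "f1", "f2", "f4", "f5"}

    def test_threshold_is_strict(self, rng):
        t = self._tables(rng, p=1)
        pert = t + rng.normal(0, 0.6, size=t.shape)
        icc = icc_2_1(t.to_numpy(), pert.to_numpy())[0]
        # at threshold exactly equal to the observed ICC, the feature must go
        assert stability_filter(t, pert, threshold=icc) == []
        assert stability_filter(t, pert, threshold=icc - 1e-9) == list(t.columns)

    def test_zero_variance_feature_warns_and_drops(self, rng):
        t = self._tables(rng, p=2)
        t["f0"] = 1.0
        pert = t.copy()
        with pytest.warns(UserWarning, match="zero variance"):
            kept = stability_filter(t, pert)
        assert kept == ["f1"]

    def test_icc_matches_pingouin(self, rng):
        """Dual-route check of the ICC(2,1) estimator."""
        pingouin = pytest.importorskip("pingouin")
        a = rng.normal(size=30)
        b = a + rng.normal(0, 0.5, size=30)
        ours = icc_2_1(a, b)
        df = pd.DataFrame(
            {
                "subject": np.tile(np.arange(30), 2),
                "rater": np.repeat(["A", "B"], 30),
                "score": np.concatenate([a, b]),
            }
        )
        res = pingouin.intraclass_corr(
            df, targets="subject", raters="rater", ratings="score"
        )
        # two-way random, absolute agreement, single measure
        sel = res.Type.isin(["ICC2", "ICC(A,1)"])
        icc2 = float(res.loc[sel, "ICC"].iloc[0])
        assert ours == pytest.approx(icc2, abs=1e-6)


def _redundancy_oracle(table: pd.DataFrame, thr=0.9):
    """Independent re-run of the stated removal rule (brute force)."""
    retained = [c for c in table.columns if table[c].nunique() > 1]
    while True:
        corr = table[retained].corr(method="spearman").abs()
        np.fill_diagonal(corr.values, 0.0)
        worst, pair = 0.0, None
        for i, a in enumerate(retained):
            for b in retained[i + 1:]:
                r = corr.loc[a, b]
                if r > worst + 1e-15 or (
                    abs(r - worst) <= 1e-15 and pair and (a, b) < pair
                ):
                    if r > thr:
                        worst, pair = r, tuple(sorted((a, b)))
        if pair is None:
            return retained
        a, b = pair
        ma, mb = corr.loc[a, retained].mean(), corr.loc[b, retained].mean()
        drop = a if ma > mb else b if mb > ma else max(a, b)
        retained = [c for c in retained if c != drop]


class TestRedundancyFilter:
    def test_duplicated_column_removes_exactly_one(self, rng):
        t = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        t["a_copy"] = t["a"]
        kept = redundancy_filter(t)
        assert ("a" in kept) != ("a_copy" in kept)
        assert {"b", "c"} <= set(kept)

    def test_pair_below_threshold_both_retained(self, rng):
        x = rng.normal(size=200)
        y = x + rng.normal(0, 0.75, size=200)  # Spearman ~0.8 < 0.9
        t = pd.DataFrame({"x": x, "y": y})
        rho = abs(t.corr(method="spearman").loc["x", "y"])
        assert rho < 0.9
        assert redundancy_filter(t) == ["x", "y"]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(25, 2))
        t = pd.DataFrame(
            {
                "a": base[:, 0],
                "b": base[:, 0] + rng.normal(0, 0.05, 25),
                "c": base[:, 1],
                "d": base[:, 1] + rng.normal(0, 0.05, 25),
                "e": rng.normal(size=25),
            }
        )
        assert set(redundancy_filter(t)) == set(_redundancy_oracle(t))

    @pytest.mark.parametrize("seed", range(5))
    def test_no_remaining_pair_above_threshold(self, seed):
        rng = np.random.default_rng(100 + seed)
        latent = rng.normal(size=(40, 3))
        cols = {
            f"g{i}": latent[:, i % 3] + rng.normal(0, 0.1 * (1 + i % 4), 40)
            for i in range(8)
        }
        t = pd.DataFrame(cols)
        kept = redundancy_filter(t)
        if len(kept) > 1:
            corr = t[kept].corr(method="spearman").abs()
            np.fill_diagonal(corr.values, 0.0)
            assert corr.to_numpy().max() <= 0.9

    def test_constant_feature_dropped_with_warning(self):
        t = pd.DataFrame({"a": np.arange(10.0), "k": np.ones(10)})
        with pytest.warns(UserWarning, match="constant"):
            kept = redundancy_filter(t)
        assert kept == ["a"]


class TestJitterMask:
    def test_jitter_preserves_grid_and_stays_close(self, phantom_high):
        mask = phantom_high["mask"].voxels
        jit = jitter_mask(mask, seed=3)
        assert jit.shape == mask.shape
        dice = 2 * (jit & mask).sum() / (jit.sum() + mask.sum())
        assert dice > 0.9          # a small perturbation, not a new region
        assert not np.array_equal(jit, mask)

    def test_jitter_is_seeded(self, phantom_high):
        mask = phantom_high["mask"].voxels
        np.testing.assert_array_equal(jitter_mask(mask, 5), jitter_mask(mask, 5))
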