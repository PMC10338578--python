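import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hemocoupling import PipelineConfig, ValidationError
from hemocoupling.stats import (label_clusters, median_split_contrast,
                                partial_corr, region_partial_corr,
                                residualize, residualized_scores,
                                voxelwise_covariate_map)

from .oracles import (flood_fill_clusters, hat_matrix_residuals,
                      partial_corr_precision)


def _cohort(n=8, seed=0, group="CIS"):
    g = np.random.default_rng(seed)
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "group": [group] * n,
        "fss": np.clip(np.round(g.normal(33, 12, n)), 9, 63),
        "hads_d": np.clip(np.round(g.normal(5, 3, n)), 0, 21),
        "tiv": g.normal(1340, 140, n),
    })


class TestResidualize:
    def test_orthogonal_nuisance_only_centers(self):
        df = pd.DataFrame({
            "group": ["CIS"] * 4,
            "t": [1.0, 2.0, 3.0, 4.0],
            "n": [1.0, -1.0, -1.0, 1.0],   # sample r = 0 with t
        })
        out = residualize(df, "t", "n", "CIS")
        np.testing.assert_allclose(out.to_numpy(),
                                   df["t"] - df["t"].mean(), atol=1e-12)

    def test_self_residual_is_zero(self):
        df = _cohort()
        df["copy"] = df["fss"]
        out = residualize(df, "fss", "copy", "CIS")
        np.testing.assert_allclose(out.dropna(), 0.0, atol=1e-10)

    def test_matches_hat_matrix_oracle(self):
        df = _cohort(n=6, seed=3)
        out = residualize(df, "fss", "hads_d", "CIS")
        ref = hat_matrix_residuals(df["fss"].to_numpy(),
                                   df["hads_d"].to_numpy())
        np.testing.assert_allclose(out.to_numpy(), ref, atol=1e-12)

    def test_idempotent(self):
        df = _cohort(n=12, seed=5)
        once = residualize(df, "fss", "hads_d", "CIS")
        df2 = df.assign(fss=once)
        twice = residualize(df2, "fss", "hads_d", "CIS")
        np.testing.assert_allclose(twice, once, atol=1e-12)

    def test_constant_nuisance_rejected(self):
        df = _cohort()
        df["hads_d"] = 7.0
        with pytest.raises(ValidationError, match="constant"):
            residualize(df, "fss", "hads_d", "CIS")

    def test_mutual_residuals_orthogonal(self):
        """Adjusted FSS is uncorrelated with raw depression, and vice versa."""
        df = _cohort(n=24, seed=9)
        rs = residualized_scores(df, "CIS")
        t = rs.table
        r1 = np.corrcoef(t["fss_resid"], df["hads_d"])[0, 1]
        r2 = np.corrcoef(t["hads_resid"], df["fss"])[0, 1]
        assert abs(r1) < 1e-10 and abs(r2) < 1e-10


class TestPartialCorr:
    def test_orthogonal_nuisance_reduces_to_simple_r(self, rng):
        n = 400
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        z = rng.standard_normal(n)
        # force exact sample orthogonality to the nuisance
        x = hat_matrix_residuals(x, z)
        y = hat_matrix_residuals(y, z)
        r, _, _ = partial_corr(x, y, z)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)

    def test_identical_variables_give_unit_r(self, rng):
        x = rng.standard_normal(30)
        z = rng.standard_normal(30)
        r, p, _ = partial_corr(x, x, z)
        assert r == pytest.approx(1.0)

    def test_matches_precision_matrix_oracle(self):
        for seed in range(20):
            g = np.random.default_rng(seed)
            x, y, z = g.standard_normal((3, 8))
            r, _, _ = partial_corr(x, y, z)
            assert r == pytest.approx(partial_corr_precision(x, y, z),
                                      abs=1e-12)

    def test_multiple_nuisances_against_oracle(self, rng):
        x, y = rng.standard_normal((2, 15))
        z = rng.standard_normal((15, 3))
        r, _, _ = partial_corr(x, y, z)
        # residualize on all three, correlate — definitional double check
        rx = hat_matrix_residuals(x, z)
        ry = hat_matrix_residuals(y, z)
        assert r == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)

    def test_minimum_sample_size(self, rng):
        x = rng.standard_normal(4)
        with pytest.raises(ValidationError):
            partial_corr(x, x, rng.standard_normal(4))


class TestClusterFiltering:
    def _stat_inputs(self, effect_mask, n=24, seed=0, shape=(10, 10, 8)):
        g = np.random.default_rng(seed)
        cov = g.standard_normal(n)
        tiv = g.standard_normal(n)
        maps = g.standard_normal((n, *shape))
        maps[:, effect_mask] += 3.0 * cov[:, None]
        return maps, cov, tiv

    def test_27_voxel_cube_survives_19_voxel_cluster_removed(self):
        shape = (12, 12, 10)
        cube = np.zeros(shape, bool)
        cube[1:4, 1:4, 1:4] = True                    # 27 voxels
        small = np.zeros(shape, bool)
        small[6:9, 6:9, 6:8] = True                   # 18 voxels
        small[9, 6, 6] = True                         # 19th, connected (18-conn)
        g = np.random.default_rng(0)
        n = 24
        cov = g.standard_normal(n)
        tiv = g.standard_normal(n)
        noise = g.standard_normal((n, *shape))
        # background exactly orthogonal to the covariate: only planted
        # voxels can cross the voxel-level threshold
        flat = noise.reshape(n, -1)
        design = np.column_stack([np.ones(n), cov, tiv])
        flat -= design @ np.linalg.lstsq(design, flat, rcond=None)[0]
        maps = flat.reshape(n, *shape)
        maps[:, cube | small] += 3.0 * cov[:, None]
        cfg = PipelineConfig(cluster_min=20)
        out = voxelwise_covariate_map(maps, cov, tiv, cfg)
        assert out.surviving[cube].all()
        assert not out.surviving[small].any()
        sizes = sorted(c["size"] for c in out.clusters)
        assert sizes == [27]

    def test_planted_block_detected_across_seeds(self):
        """A 30-voxel block carrying the covariate survives in >=80% of runs."""
        shape = (8, 8, 6)
        block = np.zeros(shape, bool)
        block[2:7, 2:5, 1:3] = True  # 30 voxels
        cfg = PipelineConfig()
        hits = 0
        for seed in range(25):
            g = np.random.default_rng(seed)
            cov = g.standard_normal(24)
            tiv = g.standard_normal(24)
            maps = g.standard_normal((24, *shape))
            maps[:, block] += 1.5 * cov[:, None]
            out = voxelwise_covariate_map(maps, cov, tiv, cfg)
            hits += int(out.surviving[block].sum() >= 20)
        assert hits / 25 >= 0.8

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_labeling_matches_flood_fill_oracle(self, connectivity):
        for seed in range(50):
            g = np.random.default_rng(seed)
            mask = g.random((7, 7, 5)) < 0.25
            labels, n = label_clusters(mask, connectivity)
            comps = flood_fill_clusters(mask, connectivity)
            assert n == len(comps)
            got = {frozenset(map(tuple, np.argwhere(labels == k)))
                   for k in range(1, n + 1)}
            assert got == {frozenset(c) for c in comps}

    def test_too_few_subjects_rejected(self, rng):
        maps = rng.standard_normal((4, 3, 3, 3))
        with pytest.raises(ValidationError):
            voxelwise_covariate_map(maps, rng.standard_normal(4),
                                    rng.standard_normal(4), PipelineConfig())


class TestRegionPartialCorr:
    def _table(self, n=10, seed=0):
        g = np.random.default_rng(seed)
        rows = []
        for rid in (1, 2):
            for i in range(n):
                rows.append({"subject_id": f"s{i}", "region": rid,
                             "m": g.standard_normal()})
        return pd.DataFrame(rows)

    def test_matches_precision_oracle_on_toy_table(self):
        g = np.random.default_rng(4)
        n = 8
        tab = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "region": [1] * n,
            "m": g.standard_normal(n),
        })
        cov = pd.Series(g.standard_normal(n), index=tab["subject_id"])
        tiv = pd.Series(g.standard_normal(n), index=tab["subject_id"])
        res = region_partial_corr(tab, ["m"], cov, tiv, PipelineConfig())
        ref = partial_corr_precision(tab["m"].to_numpy(), cov.to_numpy(),
                                     tiv.to_numpy())
        assert res[0].r == pytest.approx(ref, abs=1e-12)

    def test_constant_metric_flagged_undefined(self):
        tab = self._table()
        tab.loc[tab.region == 2, "m"] = 1.0
        ids = tab.loc[tab.region == 1, "subject_id"]
        g = np.random.default_rng(0)
        cov = pd.Series(g.standard_normal(len(ids)), index=ids.to_numpy())
        tiv = pd.Series(g.standard_normal(len(ids)), index=ids.to_numpy())
        res = region_partial_corr(tab, ["m"], cov, tiv, PipelineConfig())
        r2 = [x for x in res if x.region == 2][0]
        assert np.isnan(r2.r) and not r2.significant

    def test_extra_nuisances_change_df(self, rng):
        n = 12
        ids = [f"s{i}" for i in range(n)]
        tab = pd.DataFrame({"subject_id": ids, "region": [1] * n,
                            "m": rng.standard_normal(n)})
        cov = pd.Series(rng.standard_normal(n), index=ids)
        tiv = pd.Series(rng.standard_normal(n), index=ids)
        extra = pd.DataFrame({"gm": rng.standard_normal(n),
                              "lesion": rng.standard_normal(n)}, index=ids)
        res = region_partial_corr(tab, ["m"], cov, tiv, PipelineConfig(),
                                  extra_nuisances=extra)
        rx = hat_matrix_residuals(tab["m"].to_numpy(),
                                  np.column_stack([tiv, extra["gm"],
                                                   extra["lesion"]]))
        ry = hat_matrix_residuals(cov.to_numpy(),
                                  np.column_stack([tiv, extra["gm"],
                                                   extra["lesion"]]))
        assert res[0].r == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-10)


class TestMedianSplit:
    def test_split_at_median_32_gives_12_and_12(self):
        """24 scores, half strictly above the median of 32, split 12/12."""
        g = np.random.default_rng(1)
        low = g.integers(15, 32, 12)   # at or below 32
        high = g.integers(33, 60, 12)
        scores = np.concatenate([low, [32], high[:-1]])  # median lands at 32
        scores = np.concatenate([low, high])
        df = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(24)],
            "group": ["CIS"] * 24,
            "fss": scores,
            "hads_d": 5, "tiv": 1300.0,
        })
        metric = pd.Series(g.standard_normal(24),
                           index=df["subject_id"])
        res = median_split_contrast(df, "fss", metric, "CIS")
        assert res.n_low == 12 and res.n_high == 12

    def test_null_p_uniform(self):
        """With identical distributions the contrast p-value is uniform."""
        ps = []
        for seed in range(200):
            g = np.random.default_rng(seed)
            df = pd.DataFrame({
                "subject_id": [f"s{i}" for i in range(24)],
                "group": ["CIS"] * 24,
                "fss": g.permutation(np.arange(24) + 20.0),
                "hads_d": 5, "tiv": 1300.0,
            })
            metric = pd.Series(g.standard_normal(24), index=df["subject_id"])
            ps.append(median_split_contrast(df, "fss", metric,
                                            "CIS").high_vs_low["p"])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_three_sd_shift_detected(self):
        """A 3-SD group difference at n=12/12 is significant almost always."""
        hits = 0
        for seed in range(100):
            g = np.random.default_rng(seed)
            scores = np.concatenate([g.integers(10, 32, 12),
                                     g.integers(33, 63, 12)]).astype(float)
            vals = g.standard_normal(24)
            vals[scores > 32] += 3.0
            df = pd.DataFrame({
                "subject_id": [f"s{i}" for i in range(24)],
                "group": ["CIS"] * 24,
                "fss": scores, "hads_d": 5, "tiv": 1300.0,
            })
            metric = pd.Series(vals, index=df["subject_id"])
            res = median_split_contrast(df, "fss", metric, "CIS")
            hits += res.high_vs_low["p"] < 0.01
        assert hits >= 95

    def test_reference_group_comparisons(self, rng):
        df = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(10)],
            "group": ["CIS"] * 10,
            "fss": np.arange(10) + 20.0, "hads_d": 5, "tiv": 1300.0,
        })
        metric = pd.Series(rng.standard_normal(10), index=df["subject_id"])
        res = median_split_contrast(df, "fss", metric, "CIS",
                                    reference=rng.standard_normal(15))
        assert res.high_vs_reference is not None
        assert "p" in res.low_vs_reference

    def test_identical_scores_rejected(self, rng):
        df = pd.DataFrame({
            "subject_id": ["a", "b", "c", "d", "e", "f"],
            "group": ["CIS"] * 6, "fss": 30.0, "hads_d": 5, "tiv": 1300.0,
        })
        metric = pd.Series(rng.standard_normal(6), index=df["subject_id"])
        with pytest.raises(ValidationError, match="identical"):
            median_split_contrast(df, "fss", metric, "CIS")
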