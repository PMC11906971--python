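"""Mixed-model contrasts, FDR, PET comparison and the categorical tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import atroprop as ap
from atroprop.core_data import META_COLUMNS, default_region_ids


@pytest.fixture(scope="module")
def cohort():
    cfg = ap.SimulationConfig(
        R=10, n_per_group=40, visits=3, n_connectome_subjects=2,
        target_density=0.2, rng_seed=17,
    )
    return ap.simulate_cohort(cfg)


class TestBhFdr:
    def test_known_rejection_set(self):
        res = ap.bh_fdr([0.001, 0.01, 0.02, 0.04, 0.2], q=0.05)
        assert res.n_rejected == 4
        assert not res.reject[4]

    def test_all_ones_and_singleton(self):
        res = ap.bh_fdr([1.0, 1.0, 1.0], q=0.05)
        assert res.n_rejected == 0
        np.testing.assert_array_equal(res.adjusted_p, 1.0)
        single = ap.bh_fdr([0.04], q=0.05)
        assert single.reject[0] and single.adjusted_p[0] == pytest.approx(0.04)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ap.bh_fdr([0.5, 1.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_direct_step_up_enumeration(self, seed):
        """BH via the library equals a from-scratch step-up implementation."""
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 40))
        p = rng.random(m)
        q = float(rng.choice([0.01, 0.05, 0.1, 0.2]))
        res = ap.bh_fdr(p, q)
        order = np.argsort(p)
        ps = p[order]
        thresh = q * np.arange(1, m + 1) / m
        passing = np.flatnonzero(ps <= thresh)
        k = passing.max() + 1 if passing.size else 0
        expect_reject = np.zeros(m, bool)
        expect_reject[order[:k]] = True
        np.testing.assert_array_equal(res.reject, expect_reject)
        # adjusted p: min over j>=i of m*p_(j)/j, capped at 1
        adj_sorted = np.minimum.accumulate((m * ps / np.arange(1, m + 1))[::-1])[::-1]
        expect_adj = np.empty(m)
        expect_adj[order] = np.minimum(adj_sorted, 1.0)
        np.testing.assert_allclose(res.adjusted_p, expect_adj)

    def test_monotone_and_permutation_equivariant(self):
        rng = np.random.default_rng(5)
        p = rng.random(30)
        res = ap.bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(res.adjusted_p[order]) >= -1e-15).all()
        perm = rng.permutation(30)
        res_p = ap.bh_fdr(p[perm])
        np.testing.assert_allclose(res_p.adjusted_p, res.adjusted_p[perm])


class TestCategoricalTests:
    def test_sex_table_chi_square(self):
        """AD (76 men/80 women) vs HC (43/73) gives the published 3.67."""
        res = ap.chi_square_2x2(76, 80, 43, 73)
        assert res.statistic == pytest.approx(3.67, abs=0.005)
        assert res.df == 1
        assert 0.05 < res.p_value < 0.06

    def test_proportional_and_symmetric_tables_give_zero(self):
        assert ap.chi_square_2x2(10, 20, 30, 60).statistic == pytest.approx(0.0)
        assert ap.chi_square_2x2(5, 5, 5, 5).statistic == pytest.approx(0.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            ap.chi_square_2x2(0, 0, 5, 5)

    def _counts_dataset(self, counts_by_group):
        rows, vals = [], []
        for g, counts in counts_by_group.items():
            for i, c in enumerate(counts):
                for t in range(c):
                    rows.append((f"{g}{i}", g, 70.0 + t, "F", 16.0, 25.0, 0, 0, t))
                    vals.append([0.0])
        meta = pd.DataFrame(rows, columns=META_COLUMNS)
        return ap.LongitudinalDataset(meta, np.asarray(vals), ["region_0"])

    def test_identical_count_multisets_give_zero_h(self):
        ds = self._counts_dataset({"HC": [1, 2, 3], "FHAD": [1, 2, 3], "AD": [1, 2, 3]})
        assert ap.scan_count_test(ds).statistic == pytest.approx(0.0)

    def test_hand_computed_two_group_h(self):
        """{1,2,3} vs {4,5,6}: ranks 1..6, H = 12/(6*7)*(6*4+15^2/3... ) = 3.857."""
        ds = self._counts_dataset({"HC": [1, 2, 3], "AD": [4, 5, 6]})
        res = ap.scan_count_test(ds)
        # direct rank computation: R1=6, R2=15, H = 12/(n(n+1)) * sum R_g^2/n_g - 3(n+1)
        expected = 12 / (6 * 7) * (6**2 / 3 + 15**2 / 3) - 3 * 7
        assert res.statistic == pytest.approx(expected)
        assert res.df == 1

    def test_monotone_transform_invariance(self):
        a = self._counts_dataset({"HC": [1, 2, 4], "FHAD": [2, 3, 4], "AD": [1, 1, 2]})
        b = self._counts_dataset(
            {"HC": [1, 4, 16], "FHAD": [4, 9, 16], "AD": [1, 1, 4]}
        )
        assert ap.scan_count_test(a).statistic == pytest.approx(
            ap.scan_count_test(b).statistic
        )


class TestRegionLmm:
    def test_null_effect_within_two_se(self, cohort):
        cfg_null = ap.SimulationConfig(
            R=10, n_per_group=40, visits=3,
            slope_effect={"HC": 0.0, "FHAD": 0.0, "AD": 0.0},
            n_connectome_subjects=2, target_density=0.2, rng_seed=23,
        )
        sim = ap.simulate_cohort(cfg_null)
        res = ap.fit_region_lmm(sim.dataset, sim.dataset.region_ids[0])
        assert abs(res.beta["AD-HC"]) < 2 * res.se["AD-HC"] + 1e-12

    def test_subject_relabeling_invariance(self, cohort):
        ds = cohort.dataset
        relabeled_meta = ds.meta.copy()
        relabeled_meta["subject_id"] = "x_" + relabeled_meta["subject_id"]
        ds2 = ap.LongitudinalDataset(relabeled_meta, ds.values, list(ds.region_ids))
        a = ap.fit_region_lmm(ds, ds.region_ids[0])
        b = ap.fit_region_lmm(ds2, ds.region_ids[0])
        assert a.beta == pytest.approx(b.beta)

    def test_contrast_linear_identity(self, cohort):
        res = ap.fit_region_lmm(cohort.dataset, cohort.dataset.region_ids[1])
        assert res.beta["AD-FHAD"] == pytest.approx(
            res.beta["AD-HC"] - res.beta["FHAD-HC"], abs=1e-12
        )

    def test_recovers_configured_effect(self, cohort):
        """Estimate lies within 3 SE of the generating AD-HC slope effect."""
        ds = cohort.dataset
        truth = cohort.ground_truth.true_beta["AD"]
        hit = 0
        for j, rid in enumerate(ds.region_ids):
            res = ap.fit_region_lmm(ds, rid)
            if abs(res.beta["AD-HC"] - truth[j]) < 3 * res.se["AD-HC"]:
                hit += 1
        assert hit >= len(ds.region_ids) - 1

    def test_requires_enough_subjects(self, cohort):
        small = cohort.dataset.select(
            cohort.dataset.meta["subject_id"].isin(
                cohort.dataset.meta["subject_id"].unique()[:10]
            ).to_numpy()
        )
        with pytest.raises(ValueError, match="at least"):
            ap.fit_region_lmm(small, small.region_ids[0])


class TestProgressionMaps:
    def test_region_column_permutation_equivariance(self, cohort):
        ds = cohort.dataset
        perm = np.random.default_rng(0).permutation(ds.n_regions)
        ds_p = ap.LongitudinalDataset(
            ds.meta.copy(), ds.values[:, perm],
            [ds.region_ids[i] for i in perm],
        )
        a = ap.progression_maps(ds)
        b = ap.progression_maps(ds_p)
        merged = a.table.merge(b.table, on="region_id", suffixes=("_a", "_b"))
        np.testing.assert_allclose(
            merged["beta_AD-HC_a"], merged["beta_AD-HC_b"], rtol=1e-6
        )

    def test_degenerate_partition_equals_global_mean_lmm(self, cohort):
        ds = cohort.dataset
        part = ap.NetworkPartition({str(r): "all" for r in ds.region_ids})
        net = ap.network_progression(ds, part)
        idx = part.indices_by_label(ds.region_ids)["all"]
        global_ds = ap.LongitudinalDataset(
            ds.meta.copy(), ds.values[:, idx].mean(axis=1, keepdims=True), ["all"]
        )
        direct = ap.progression_maps(global_ds)
        assert net.table["beta_AD-HC"].iloc[0] == pytest.approx(
            direct.table["beta_AD-HC"].iloc[0], rel=1e-3
        )

    def test_network_label_equivariance(self, cohort):
        ds = cohort.dataset
        ids = [str(r) for r in ds.region_ids]
        half = len(ids) // 2
        p1 = ap.NetworkPartition(
            {r: ("A" if i < half else "B") for i, r in enumerate(ids)}
        )
        p2 = ap.NetworkPartition(
            {r: ("B" if i < half else "A") for i, r in enumerate(ids)}
        )
        a = ap.network_progression(ds, p1).table.set_index("region_id")
        b = ap.network_progression(ds, p2).table.set_index("region_id")
        # relabeling swaps which label carries each region set
        assert a.loc["A", "beta_AD-HC"] == pytest.approx(
            b.loc["B", "beta_AD-HC"], rel=1e-6
        )
        assert a.loc["B", "beta_AD-HC"] == pytest.approx(
            b.loc["A", "beta_AD-HC"], rel=1e-6
        )

    def test_pattern_network_has_largest_effect(self):
        """A partition isolating the high-pattern regions concentrates beta."""
        cfg = ap.SimulationConfig(
            R=40, n_per_group=40, visits=3, n_connectome_subjects=2, rng_seed=31,
        )
        sim = ap.simulate_cohort(cfg)
        pattern = sim.ground_truth.pattern.values
        ids = [str(r) for r in sim.dataset.region_ids]
        top = set(np.argsort(pattern)[-8:])
        part = ap.NetworkPartition(
            {r: ("hot" if i in top else "cold") for i, r in enumerate(ids)}
        )
        res = ap.network_progression(sim.dataset, part).table.set_index("region_id")
        assert res.loc["hot", "beta_AD-HC"] > res.loc["cold", "beta_AD-HC"]


class TestSexInteractionScan:
    def test_duplicated_sexes_give_null_interactions(self):
        """Mirroring every subject across sex removes any sex effect."""
        cfg = ap.SimulationConfig(
            R=10, n_per_group=30, visits=2, sex_effect=0.0,
            n_connectome_subjects=2, target_density=0.2, rng_seed=41,
        )
        sim = ap.simulate_cohort(cfg)
        ds = sim.dataset
        m2 = ds.meta.copy()
        m2["subject_id"] = m2["subject_id"] + "_m"
        m2["sex"] = np.where(ds.meta["sex"] == "F", "M", "F")
        both = ap.LongitudinalDataset(
            pd.concat([ds.meta, m2], ignore_index=True),
            np.vstack([ds.values, ds.values]),
            list(ds.region_ids),
        )
        table = ap.sex_interaction_scan(both)
        assert (table["p_group_sex_age"] > 0.2).all()


class TestPartialSpearman:
    def test_monotone_relation_gives_rho_one(self):
        rng = np.random.default_rng(0)
        w = rng.standard_normal((50, 2))
        score = np.exp(w[:, 0])  # monotone in the first network's W
        cov = rng.standard_normal((50, 3))
        res = ap.partial_spearman(score, w, cov)
        assert res["rho"].iloc[0] == pytest.approx(1.0, abs=1e-10)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        w = rng.standard_normal((60, 3))
        score = w[:, 1] + 0.5 * rng.standard_normal(60)
        cov = rng.standard_normal((60, 2))
        a = ap.partial_spearman(score, w, cov)
        b = ap.partial_spearman(np.exp(score), w**3, cov)
        np.testing.assert_allclose(a["rho"], b["rho"], atol=1e-10)

    def test_calibration_under_independence(self):
        """Independent score and W: ~5% rejections at alpha=0.05."""
        rng = np.random.default_rng(2)
        rej = 0
        n_rep = 300
        for _ in range(n_rep):
            score = rng.standard_normal(100)
            w = rng.standard_normal((100, 1))
            cov = rng.standard_normal((100, 3))
            res = ap.partial_spearman(score, w, cov)
            rej += res["p"].iloc[0] < 0.05
        assert 0.025 < rej / n_rep < 0.085

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "x": rng.standard_normal(80),
                "y": rng.standard_normal(80),
                "c1": rng.standard_normal(80),
            }
        )
        df["y"] += 0.5 * df["x"]
        ours = ap.partial_spearman(
            df["x"].to_numpy(), df[["y"]].to_numpy(), df[["c1"]].to_numpy()
        )
        ref = pingouin.partial_corr(
            df, x="x", y="y", covar=["c1"], method="spearman"
        )
        assert ours["rho"].iloc[0] == pytest.approx(ref["r"].iloc[0], abs=1e-6)

    def test_constant_score_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ap.partial_spearman(
                np.ones(30), np.random.default_rng(0).standard_normal((30, 1)),
                np.random.default_rng(1).standard_normal((30, 2)),
            )


@pytest.fixture(scope="module")
def pet_dataset():
    rng = np.random.default_rng(8)
    rows, vals = [], []
    R = 30
    boosted = np.zeros(R)
    boosted[:12] = 0.15  # 40% of regions carry a group difference
    for g, n in (("FHAD", 60), ("AD", 60)):
        for i in range(n):
            suvr = 1.0 + 0.1 * rng.standard_normal(R)
            if g == "AD":
                suvr = suvr + boosted
            rows.append((f"{g}{i}", g, rng.uniform(65, 80),
                         "F" if rng.random() < 0.5 else "M",
                         rng.uniform(12, 20), rng.uniform(20, 32),
                         int(rng.integers(3)), 0, 0))
            vals.append(suvr)
    meta = pd.DataFrame(rows, columns=META_COLUMNS)
    return ap.LongitudinalDataset(meta, np.vstack(vals), default_region_ids(R))


class TestComparePetGroups:
    def test_boosted_regions_enriched_in_rejections(self, pet_dataset):
        table = ap.compare_pet_groups(pet_dataset)
        sig = set(table.loc[table["significant"], "region_id"])
        truly = set(default_region_ids(30)[:12])
        assert sig, "no rejections at all"
        precision = len(sig & truly) / len(sig)
        assert precision >= 0.8

    def test_location_invariance(self, pet_dataset):
        shifted = ap.LongitudinalDataset(
            pet_dataset.meta.copy(), pet_dataset.values + 5.0,
            list(pet_dataset.region_ids),
        )
        a = ap.compare_pet_groups(pet_dataset)
        b = ap.compare_pet_groups(shifted)
        np.testing.assert_allclose(a["t"], b["t"], atol=1e-9)

    def test_null_calibration(self):
        rng = np.random.default_rng(9)
        rej_frac = []
        for rep in range(25):
            rows, vals = [], []
            for g, n in (("FHAD", 40), ("AD", 40)):
                for i in range(n):
                    rows.append((f"{g}{i}", g, rng.uniform(65, 80),
                                 "F" if rng.random() < 0.5 else "M",
                                 rng.uniform(12, 20), rng.uniform(20, 32),
                                 int(rng.integers(3)), 0, 0))
                    vals.append(1.0 + 0.1 * rng.standard_normal(20))
            meta = pd.DataFrame(rows, columns=META_COLUMNS)
            ds = ap.LongitudinalDataset(meta, np.vstack(vals), default_region_ids(20))
            table = ap.compare_pet_groups(ds)
            rej_frac.append(table["significant"].mean())
        assert np.mean(rej_frac) <= 0.07
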