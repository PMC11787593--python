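"""Edge classification, regional GMV analysis, FDR, associations,
and demographic statistics."""

import numpy as np
import pandas as pd
import pytest

from idscn.atlas import default_atlas
from idscn.scn import compute_idscn, z_stack
from idscn.simulate import SimulationConfig, simulate_cohort
from idscn.stats import (
    bh_fdr,
    chi_square_counts,
    classify_edges,
    clinical_partial_corr,
    demography_tests,
    effective_tests,
    gmv_group_test,
    gmv_idscn_association,
    mannwhitney_z,
    nodal_idscn,
    partial_corr,
    t_from_summary,
)


def brute_force_bh(p):
    """Textbook step-up: q_(i) = min_{k>=i} p_(k) * n / k, capped at 1."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * n / rank)
        q[idx] = running
    return q


class TestClassifyEdges:
    def _edges(self):
        # atlas positions: even = left (ipsilesional slot), odd = right
        return [
            {"region_i": 0, "region_j": 2, "sign": "positive"},   # ipsi
            {"region_i": 0, "region_j": 4, "sign": "negative"},   # ipsi
            {"region_i": 1, "region_j": 3, "sign": "positive"},   # contra
            {"region_i": 0, "region_j": 1, "sign": "positive"},   # inter
            {"region_i": 2, "region_j": 5, "sign": "negative"},   # inter
        ]

    def test_hand_tally(self):
        atlas = default_atlas(8)
        table, hemi, subnet, degree = classify_edges(self._edges(), atlas)
        counts = table.hemisphere_class.value_counts()
        assert counts["ipsilesional"] == 2
        assert counts["contralesional"] == 1
        assert counts["interhemispheric"] == 2
        assert hemi.to_numpy().sum() == 5
        assert subnet.to_numpy().sum() == 5
        assert degree.set_index("region").degree[0] == 3

    def test_requires_orientation(self):
        with pytest.raises(ValueError, match="orient"):
            classify_edges([], default_atlas(4), oriented=False)

    def test_empty_edge_list(self):
        table, hemi, subnet, degree = classify_edges([], default_atlas(4))
        assert table.empty and hemi.empty


class TestEffectiveTests:
    def test_identity_gives_R(self):
        assert effective_tests(np.eye(10)) == pytest.approx(10.0)

    def test_perfect_redundancy_gives_one(self):
        assert effective_tests(np.ones((10, 10))) == pytest.approx(1.0, abs=1e-9)

    def test_compound_symmetry_hand_value(self):
        # 3x3, rho 0.5: eigenvalues {2, 0.5, 0.5} -> 1 + 0.5 + 0.5 = 2.0
        corr = np.full((3, 3), 0.5)
        np.fill_diagonal(corr, 1.0)
        assert effective_tests(corr) == pytest.approx(2.0, abs=1e-12)

    def test_bounds_and_permutation_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.normal(size=(50, 8))
            corr = np.corrcoef(x, rowvar=False)
            m = effective_tests(corr)
            assert 1.0 <= m <= 8.0
            perm = rng.permutation(8)
            assert effective_tests(corr[np.ix_(perm, perm)]) == pytest.approx(m)


class TestGMVGroupTest:
    def test_identical_groups_give_zero_t(self, toy_atlas):
        from conftest import make_manual_cohort

        rng = np.random.default_rng(1)
        vals = rng.uniform(3, 6, size=(10, 4))
        cohort = make_manual_cohort(
            np.vstack([vals, vals]), toy_atlas,
            groups=["control"] * 10 + ["patient"] * 10,
            lesions=[None] * 10 + ["left"] * 10)
        stats_list, _ = gmv_group_test(cohort)
        assert all(abs(r.t) < 1e-12 for r in stats_list)

    def test_direction_label_matches_means(self):
        cfg = SimulationConfig(
            n_regions=10, sites=("A",), n_controls_per_site=(60,),
            n_patients_per_site=(60,), site_offsets=(0.0,),
            site_scales=(1.0,), atrophy_regions=(1,), atrophy_d=1.5, seed=2)
        cohort, _ = simulate_cohort(cfg)
        stats_list, meff = gmv_group_test(cohort)
        assert 1.0 <= meff <= 10.0
        from idscn.stats import oriented_patient_values

        pat = oriented_patient_values(cohort)
        ctl = cohort.values[cohort.mask(group="control")]
        for r in stats_list:
            expected = "atrophy" if pat[:, r.region].mean() < ctl[:, r.region].mean() \
                else "increase"
            assert r.direction == expected
        assert stats_list[0].direction == "atrophy"
        assert stats_list[0].significant_after_fwe

    def test_null_calibration_uncorrected(self):
        """Fraction of regions with uncorrected p<0.05 is near 0.05."""
        hits, total = 0, 0
        for rep in range(20):
            cfg = SimulationConfig(
                n_regions=10, sites=("A",), n_controls_per_site=(40,),
                n_patients_per_site=(40,), site_offsets=(0.0,),
                site_scales=(1.0,), seed=600 + rep)
            cohort, _ = simulate_cohort(cfg)
            stats_list, _ = gmv_group_test(cohort)
            hits += sum(r.p < 0.05 for r in stats_list)
            total += len(stats_list)
        assert hits / total < 0.12


class TestBHFDR:
    def test_worked_example(self):
        q, _ = bh_fdr([0.01, 0.02, 0.04, 0.5])
        assert np.allclose(q, [0.04, 0.04, 0.05333333, 0.5], atol=1e-6)

    def test_all_ones(self):
        q, rej = bh_fdr([1.0, 1.0, 1.0])
        assert np.all(q == 1.0) and not rej.any()

    def test_single_p(self):
        q, _ = bh_fdr([0.03])
        assert q[0] == pytest.approx(0.03)

    def test_empty(self):
        q, rej = bh_fdr([])
        assert q.size == 0 and rej.size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_matches_brute_force_on_random_lists(self):
        rng = np.random.default_rng(3)
        for n in (1, 2, 7, 50, 333):
            p = rng.uniform(size=n)
            q, _ = bh_fdr(p)
            assert np.allclose(q, brute_force_bh(p), atol=1e-12)


class TestPartialCorrScalar:
    def test_near_perfect_association(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        y = x + rng.normal(scale=1e-4, size=50)
        cov = rng.normal(size=(50, 2))
        r, p, _ = partial_corr(x, y, cov)
        assert r > 0.999 and p < 1e-20

    def test_pure_covariate_signal_removed(self):
        rng = np.random.default_rng(5)
        age = rng.uniform(40, 75, size=80)
        x = rng.normal(size=80)
        y = 3.0 * age  # entirely explained by the covariate
        with pytest.raises(ValueError, match="constant"):
            # residual of y is exactly zero -> degenerate
            partial_corr(x, (y - y.mean()) * 0, np.column_stack([age]))
        r, p, _ = partial_corr(x, y + rng.normal(scale=1e-6, size=80),
                               np.column_stack([age]))
        assert abs(r) < 0.3

    def test_twelve_patient_worked_set_matches_residual_oracle(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=12)
        y = 0.5 * x + rng.normal(size=12)
        age = rng.uniform(40, 75, 12)
        gender = rng.integers(0, 2, 12).astype(float)
        cov = np.column_stack([age, gender])
        r, p, df = partial_corr(x, y, cov)
        X = np.column_stack([np.ones(12), cov - cov.mean(axis=0)])
        rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
        ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        assert r == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-10)
        assert df == 8  # 12 - 2 covariates - 2

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        cov = rng.normal(size=(30, 2))
        r, p, _ = partial_corr(x, y, cov)
        df = pd.DataFrame(np.column_stack([x, y, cov]),
                          columns=["x", "y", "u", "v"])
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["u", "v"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)


class TestClinicalPartialCorr:
    def test_family_fdr_and_missing_handling(self):
        rng = np.random.default_rng(8)
        m = 40
        age = rng.uniform(40, 75, m)
        gender = rng.integers(0, 2, m).astype(float)
        nodal = rng.normal(size=m)
        clin = pd.DataFrame({
            "FMT": nodal + rng.normal(scale=0.1, size=m),
            "F_RT": rng.normal(size=m),
        })
        clin.loc[:5, "F_RT"] = np.nan
        out = clinical_partial_corr(
            {"node0": nodal, "node1": rng.normal(size=m)},
            clin, age, gender)
        assert set(out.score) == {"FMT", "F_RT"}
        strong = out[(out.score == "FMT") & (out.label == "node0")].iloc[0]
        assert strong.r > 0.9 and strong.significant_fdr
        assert (out[out.score == "F_RT"].n == m - 6).all()

    def test_constant_score_rejected(self):
        rng = np.random.default_rng(9)
        m = 20
        clin = pd.DataFrame({"FMT": np.ones(m)})
        with pytest.raises(ValueError, match="constant"):
            clinical_partial_corr({"a": rng.normal(size=m)}, clin,
                                  rng.uniform(40, 75, m),
                                  rng.integers(0, 2, m).astype(float))


class TestAssociation:
    @staticmethod
    def _cohort_with_signal(seed=0):
        k4 = ((1, 3), (1, 5), (1, 7), (3, 5), (3, 7), (5, 7))
        cfg = SimulationConfig(
            n_regions=20, sites=("A",), n_controls_per_site=(120,),
            n_patients_per_site=(60,), site_offsets=(0.0,),
            site_scales=(1.0,), perturbed_edges=k4, edge_delta=0.5,
            seed=seed)
        return simulate_cohort(cfg)

    def test_modes_run_and_fdr_dominates_p(self):
        from idscn.nbs import NBSConfig, nbs_run

        cohort, _ = self._cohort_with_signal(seed=123)
        results = compute_idscn(cohort)
        nbs_res = nbs_run(z_stack(results), NBSConfig(n_perm=200, seed=0))
        if not nbs_res.significant_edges:
            pytest.skip("no significant component in this draw")
        assoc = gmv_idscn_association(cohort, results, nbs_res)
        assert assoc, "regions incident to significant edges expected"
        for a in assoc:
            assert -1.0 <= a.rho <= 1.0
            assert a.q >= a.p - 1e-12
        spatial = gmv_idscn_association(
            cohort, results, nbs_res, mode="spatial_across_regions")
        assert len(spatial) == 1

    def test_doctored_perfect_association(self):
        """If the nodal network summary is an exact monotone function of the
        adjusted GMV, Spearman rho is 1 and survives FDR."""
        from idscn.nbs import NBSResult, EdgeStatMap, NBSConfig
        from idscn.scn import IDSCNResult
        from idscn.stats import adjusted_gmv_z

        cohort, _ = self._cohort_with_signal(seed=5)
        gmv_z = adjusted_gmv_z(cohort)
        patients = [s for s in cohort.subjects if s.group == "patient"]
        R = cohort.atlas.n_regions
        results = []
        for m, s in enumerate(patients):
            z = np.zeros((R, R))
            z[0, 1] = z[1, 0] = np.exp(gmv_z[m, 0])  # monotone in region 0
            results.append(IDSCNResult(s.subject_id, s.site, z.copy(), z,
                                       oriented="lesion-oriented",
                                       lesion_side="left"))
        fake_nbs = NBSResult(
            components=[], null_max_sizes=np.array([0]),
            edge_stats=EdgeStatMap(np.zeros((R, R)), np.ones((R, R)), 1),
            mean_z=np.zeros((R, R)),
            significant_edges=[{"region_i": 0, "region_j": 1, "t": 0.0,
                                "p": 1.0, "mean_z": 0.0, "sign": "positive",
                                "component_id": 0, "fwe_p": 0.01}],
            config=NBSConfig())
        # doctored: region 0 right-lesion patients were already mirrored in
        # adjusted_gmv_z, so the coupling is exact by construction
        assoc = gmv_idscn_association(cohort, results, fake_nbs)
        by_label = {a.label: a for a in assoc}
        a0 = by_label[cohort.atlas.names[0]]
        assert a0.rho == pytest.approx(1.0)
        assert a0.q < 0.05

    def test_null_association_controls_fdr(self):
        """Independent network summaries and GMV: about 5% pass uncorrected,
        about none pass FDR (pooled over replicates)."""
        from idscn.nbs import NBSResult, EdgeStatMap, NBSConfig
        from idscn.scn import IDSCNResult

        unc, fdr, total = 0, 0, 0
        rng = np.random.default_rng(11)
        for rep in range(10):
            cfg = SimulationConfig(
                n_regions=10, sites=("A",), n_controls_per_site=(40,),
                n_patients_per_site=(30,), site_offsets=(0.0,),
                site_scales=(1.0,), seed=700 + rep)
            cohort, _ = simulate_cohort(cfg)
            patients = [s for s in cohort.subjects if s.group == "patient"]
            R = 10
            results = []
            for s in patients:
                z = rng.normal(size=(R, R))
                z = (z + z.T) / 2
                np.fill_diagonal(z, 0)
                results.append(IDSCNResult(s.subject_id, s.site, z.copy(), z,
                                           "lesion-oriented", s.lesion_side))
            sig = [{"region_i": i, "region_j": j, "t": 0.0, "p": 1.0,
                    "mean_z": 0.0, "sign": "positive", "component_id": 0,
                    "fwe_p": 0.01}
                   for i, j in [(0, 1), (2, 3), (4, 5), (6, 7), (8, 9)]]
            fake = NBSResult([], np.array([0]),
                             EdgeStatMap(np.zeros((R, R)), np.ones((R, R)), 1),
                             np.zeros((R, R)), sig, NBSConfig())
            assoc = gmv_idscn_association(cohort, results, fake)
            unc += sum(a.p < 0.05 for a in assoc)
            fdr += sum(a.q < 0.05 for a in assoc)
            total += len(assoc)
        assert unc / total < 0.15
        assert fdr / total <= 0.02


class TestDemography:
    def test_printed_gender_table_statistic(self):
        chi2, _ = chi_square_counts([[81, 31], [74, 48]])
        assert round(chi2, 2) == 3.55

    def test_printed_age_summary_statistic(self):
        t, _ = t_from_summary(55.82, 7.79, 112, 55.28, 7.54, 122)
        assert round(t, 2) == 0.54

    def test_identical_groups_zero_statistics(self, toy_atlas):
        from conftest import make_manual_cohort

        rng = np.random.default_rng(12)
        vals = rng.uniform(3, 6, size=(12, 4))
        cohort = make_manual_cohort(
            np.vstack([vals, vals]), toy_atlas,
            groups=["control"] * 12 + ["patient"] * 12,
            lesions=[None] * 12 + ["left"] * 12)
        # duplicate covariates so groups are literally identical
        for i in range(12):
            a, b = cohort.subjects[i], cohort.subjects[i + 12]
            cohort.subjects[i + 12] = type(b)(
                b.subject_id, b.group, b.site, a.age, a.gender, a.tiv,
                b.lesion_side, b.clinical)
        out = demography_tests(cohort).set_index("variable")
        assert abs(out.loc["age"].statistic) < 1e-9
        assert out.loc["gender"].statistic == 0.0

    def test_mannwhitney_z_agrees_with_scipy_p(self):
        from scipy import stats as sps

        rng = np.random.default_rng(13)
        x = rng.exponential(size=40)
        y = rng.exponential(size=45) + 0.3
        z, p = mannwhitney_z(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_full_table_on_simulated_cohort(self, small_cohort):
        cohort, _ = small_cohort
        out = demography_tests(cohort)
        assert {"age", "tiv", "gender"}.issubset(set(out.variable))
        assert out.p.between(0, 1).all()


class TestNodalSummary:
    def test_mean_and_sum_reduction(self):
        from idscn.nbs import NBSResult, EdgeStatMap, NBSConfig
        from idscn.scn import IDSCNResult

        R = 4
        z = np.zeros((R, R))
        z[0, 1] = z[1, 0] = 2.0
        z[0, 2] = z[2, 0] = 4.0
        res = [IDSCNResult("p1", "A", z.copy(), z, "lesion-oriented", "left")]
        sig = [{"region_i": 0, "region_j": 1, "t": 0, "p": 0, "mean_z": 2.0,
                "sign": "positive", "component_id": 0, "fwe_p": 0.01},
               {"region_i": 0, "region_j": 2, "t": 0, "p": 0, "mean_z": 4.0,
                "sign": "positive", "component_id": 0, "fwe_p": 0.01}]
        fake = NBSResult([], np.array([0]),
                         EdgeStatMap(np.zeros((R, R)), np.ones((R, R)), 1),
                         np.zeros((R, R)), sig, NBSConfig())
        nodal, deg = nodal_idscn(res, fake)
        assert nodal[0, 0] == pytest.approx(3.0)   # mean of 2 and 4
        assert nodal[0, 1] == pytest.approx(2.0)
        assert np.isnan(nodal[0, 3])
        assert list(deg) == [2, 1, 1, 0]
        nodal_sum, _ = nodal_idscn(res, fake, reduce="sum")
        assert nodal_sum[0, 0] == pytest.approx(6.0)
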