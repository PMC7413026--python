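import numpy as np
import pandas as pd
import pytest

import maitsig as m
from maitsig.bulk import CorrelationReport

import _oracles


@pytest.fixture(scope="module")
def bulk_ds():
    return m.generate_bulk_cohort(m.SyntheticBulkConfig(seed=31, n_samples=600))


@pytest.fixture(scope="module")
def marker_panel():
    return list(m.MAIT_SIGNATURE_GENES) + list(m.PAN_T_GENES) + list(m.NK_GENES)


def report_from_tau(markers, tau, p=None, alpha_p=1e-4):
    """Build a CorrelationReport directly from a tau matrix (p small where
    tau nonzero unless given)."""
    tau = pd.DataFrame(tau, index=markers, columns=markers)
    if p is None:
        p = pd.DataFrame(
            np.where(np.abs(tau.to_numpy()) > 0, alpha_p, 1.0),
            index=markers,
            columns=markers,
        )
    return CorrelationReport(markers=list(markers), tau=tau, p=p)


class TestKendallMatrix:
    def test_small_fixture_matches_pair_enumeration(self):
        rng = np.random.default_rng(0)
        n = 12
        expr = pd.DataFrame(
            {
                "SLC4A10": rng.integers(0, 4, n).astype(float),  # ties on purpose
                "KLRB1": rng.integers(0, 4, n).astype(float),
                "CD3D": rng.normal(size=n),
            },
            index=[f"s{i}" for i in range(n)],
        )
        clin = pd.DataFrame(
            {"os_time": 100.0, "os_event": 1.0, "pfs_time": 90.0, "pfs_event": 0.0},
            index=expr.index,
        )
        cohort = m.BulkCohort(expr=expr, clinical=clin)
        rep = m.kendall_matrix(cohort, ["SLC4A10", "KLRB1", "CD3D"])
        for a in rep.markers:
            for b in rep.markers:
                expected = 1.0 if a == b else _oracles.kendall_tau_b_bruteforce(
                    expr[a].to_numpy(), expr[b].to_numpy()
                )
                assert rep.tau.loc[a, b] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(rep.tau, rep.tau.T)

    def test_constant_gene_flagged_zero(self, bulk_ds):
        cohort = bulk_ds.cohort
        expr = cohort.expr.copy()
        expr["FLAT"] = 1.0
        cohort2 = m.BulkCohort(expr=expr, clinical=cohort.clinical)
        rep = m.kendall_matrix(cohort2, ["SLC4A10", "FLAT"])
        assert rep.constant_genes == ["FLAT"]
        assert rep.tau.loc["SLC4A10", "FLAT"] == 0.0

    def test_missing_marker_dropped_with_warning(self, bulk_ds):
        with pytest.warns(UserWarning, match="absent"):
            rep = m.kendall_matrix(bulk_ds.cohort, ["SLC4A10", "KLRB1", "NOSUCH"])
        assert "NOSUCH" not in rep.markers

    def test_too_few_samples_rejected(self, bulk_ds):
        small = m.BulkCohort(
            expr=bulk_ds.cohort.expr.iloc[:5], clinical=bulk_ds.cohort.clinical.iloc[:5]
        )
        with pytest.raises(m.ConfigError, match="10 samples"):
            m.kendall_matrix(small, ["SLC4A10", "KLRB1"])


class TestTrimSignature:
    def test_all_positive_pairs_retained(self):
        markers = list(m.MAIT_SIGNATURE_GENES) + list(m.PAN_T_GENES)
        tau = np.full((len(markers), len(markers)), 0.5)
        np.fill_diagonal(tau, 1.0)
        trimmed = m.trim_signature(report_from_tau(markers, tau))
        assert trimmed.retained == list(m.MAIT_SIGNATURE_GENES)
        assert trimmed.eligible

    def test_anchor_uncorrelated_gene_removed(self):
        markers = list(m.MAIT_SIGNATURE_GENES) + list(m.PAN_T_GENES)
        tau = np.full((len(markers), len(markers)), 0.5)
        np.fill_diagonal(tau, 1.0)
        i = markers.index("KLRB1")
        j = markers.index("SLC4A10")
        tau[i, j] = tau[j, i] = -0.2
        trimmed = m.trim_signature(report_from_tau(markers, tau))
        assert "KLRB1" not in trimmed.retained
        assert "rule1_anchor" in trimmed.removed["KLRB1"]

    def test_four_gene_outcome_ineligible(self):
        markers = list(m.MAIT_SIGNATURE_GENES) + list(m.PAN_T_GENES)
        tau = np.zeros((len(markers), len(markers)))
        np.fill_diagonal(tau, 1.0)
        # only 4 signature genes + pan-T mutually correlated
        keep = ["SLC4A10", "KLRB1", "IL23R", "RORC"] + list(m.PAN_T_GENES)
        for a in keep:
            for b in keep:
                if a != b:
                    tau[markers.index(a), markers.index(b)] = 0.6
        trimmed = m.trim_signature(report_from_tau(markers, tau))
        assert sorted(trimmed.retained) == sorted(["SLC4A10", "KLRB1", "IL23R", "RORC"])
        assert not trimmed.eligible

    def test_fixed_point_idempotence(self, bulk_ds, marker_panel):
        rep = m.kendall_matrix(bulk_ds.cohort, marker_panel)
        once = m.trim_signature(rep)
        again = m.trim_signature(rep, signature=once.retained)
        assert again.retained == once.retained

    def test_missing_anchor_rejected(self):
        markers = ["KLRB1", "CD3D", "CD3E"]
        tau = np.eye(3)
        with pytest.raises(m.ConfigError, match="anchor"):
            m.trim_signature(report_from_tau(markers, tau))


class TestScoreBulk:
    def test_residuals_orthogonal_to_t_score(self, bulk_ds, marker_panel):
        rep = m.kendall_matrix(bulk_ds.cohort, marker_panel)
        trimmed = m.trim_signature(rep)
        scores = m.score_bulk(bulk_ds.cohort, trimmed)
        r = np.corrcoef(scores.residual_score, scores.t_score)[0, 1]
        assert abs(r) < 1e-10

    def test_hand_solved_simple_regression_five_samples(self):
        # one signature gene and one pan-T gene: scores are their z-scores
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        expr = pd.DataFrame({"SLC4A10": y, "CD3D": t},
                            index=[f"s{i}" for i in range(5)])
        clin = pd.DataFrame(
            {"os_time": 10.0, "os_event": 0.0, "pfs_time": 10.0, "pfs_event": 0.0},
            index=expr.index,
        )
        cohort = m.BulkCohort(expr=expr, clinical=clin)
        scores = m.score_bulk(cohort, ["SLC4A10"])
        zy = (y - y.mean()) / y.std(ddof=1)
        zt = (t - t.mean()) / t.std(ddof=1)
        beta = np.sum((zt - zt.mean()) * (zy - zy.mean())) / np.sum(
            (zt - zt.mean()) ** 2
        )
        expected = zy - (zy.mean() - beta * zt.mean() + beta * zt)
        np.testing.assert_allclose(scores.residual_score, expected, atol=1e-12)

    def test_identical_scores_give_zero_residuals(self):
        v = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        expr = pd.DataFrame({"SLC4A10": v, "CD3D": v, "CD3E": v, "CD3G": v},
                            index=[f"s{i}" for i in range(5)])
        clin = pd.DataFrame(
            {"os_time": 10.0, "os_event": 0.0, "pfs_time": 10.0, "pfs_event": 0.0},
            index=expr.index,
        )
        cohort = m.BulkCohort(expr=expr, clinical=clin)
        scores = m.score_bulk(cohort, ["SLC4A10"])
        np.testing.assert_allclose(scores.residual_score, 0.0, atol=1e-12)

    def test_constant_t_score_warns_and_skips(self):
        expr = pd.DataFrame(
            {"SLC4A10": [1.0, 2.0, 3.0], "CD3D": [5.0, 5.0, 5.0]},
            index=["a", "b", "c"],
        )
        clin = pd.DataFrame(
            {"os_time": 10.0, "os_event": 0.0, "pfs_time": 10.0, "pfs_event": 0.0},
            index=expr.index,
        )
        cohort = m.BulkCohort(expr=expr, clinical=clin)
        with pytest.warns(UserWarning, match="constant"):
            scores = m.score_bulk(cohort, ["SLC4A10"])
        assert not scores.residualized
        np.testing.assert_allclose(scores.residual_score, scores.mait_score)


class TestSurvival:
    def test_group_sizes_partition_cohort(self, bulk_ds):
        res = m.survival_test(bulk_ds.z_mait, bulk_ds.cohort, "OS")
        assert sum(res.group_sizes.values()) == len(bulk_ds.cohort.sample_ids)
        assert res.ci_low <= res.hazard_ratio <= res.ci_high

    def test_identical_curves_logrank_zero(self):
        rng = np.random.default_rng(9)
        n = 90
        times = np.tile(rng.exponential(100, n // 3), 3)
        expr = pd.DataFrame({"SLC4A10": np.arange(n, dtype=float)},
                            index=[f"s{i}" for i in range(n)])
        clin = pd.DataFrame(
            {"os_time": times, "os_event": 1.0, "pfs_time": times, "pfs_event": 1.0},
            index=expr.index,
        )
        cohort = m.BulkCohort(expr=expr, clinical=clin)
        # score ordering assigns identical survival patterns to each tertile
        scores = np.repeat([0.0, 1.0, 2.0], n // 3)
        res = m.survival_test(scores, cohort, "OS")
        assert res.logrank_p > 0.99

    def test_planted_hazard_recovered_continuous(self, bulk_ds):
        res = m.survival_test(bulk_ds.z_mait, bulk_ds.cohort, "OS", mode="continuous")
        assert np.log(res.hazard_ratio) == pytest.approx(0.5, abs=0.2)

    def test_endpoint_validation_and_minimum_n(self, bulk_ds):
        with pytest.raises(m.ConfigError, match="OS or PFS"):
            m.survival_test(bulk_ds.z_mait, bulk_ds.cohort, "DSS")
        tiny = m.BulkCohort(
            expr=bulk_ds.cohort.expr.iloc[:20],
            clinical=bulk_ds.cohort.clinical.iloc[:20],
        )
        with pytest.raises(m.ConfigError, match="30 samples"):
            m.survival_test(bulk_ds.z_mait[:20], tiny, "OS")

    def test_tertile_boundary_goes_to_lower_stratum(self):
        scores = np.array([0.0] * 40 + [1.0] * 30 + [2.0] * 30)
        groups = m.tertile_groups(scores)
        # the 33rd percentile equals 0.0 here; ties go low
        assert (groups[:40] == "low").all()


class TestMr1Association:
    def test_affine_relation_r_one(self, bulk_ds):
        scores = bulk_ds.cohort.expr["MR1"].to_numpy() * 2.0 + 1.0
        out = m.mr1_association(bulk_ds.cohort, scores)
        assert out["r"] == pytest.approx(1.0)

    def test_six_sample_textbook_formula(self):
        mr1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        score = np.array([2.0, 1.0, 4.0, 3.0, 7.0, 5.0])
        expr = pd.DataFrame({"MR1": mr1, "SLC4A10": score},
                            index=[f"s{i}" for i in range(6)])
        clin = pd.DataFrame(
            {"os_time": 10.0, "os_event": 0.0, "pfs_time": 10.0, "pfs_event": 0.0},
            index=expr.index,
        )
        cohort = m.BulkCohort(expr=expr, clinical=clin)
        out = m.mr1_association(cohort, score)
        num = np.sum((mr1 - mr1.mean()) * (score - score.mean()))
        den = np.sqrt(np.sum((mr1 - mr1.mean()) ** 2) * np.sum((score - score.mean()) ** 2))
        assert out["r"] == pytest.approx(num / den, abs=1e-12)

    def test_planted_coupling_recovered(self, bulk_ds, marker_panel):
        rep = m.kendall_matrix(bulk_ds.cohort, marker_panel)
        trimmed = m.trim_signature(rep)
        scores = m.score_bulk(bulk_ds.cohort, trimmed)
        out = m.mr1_association(bulk_ds.cohort, scores.residual_score)
        assert out["r"] > 0.2 and out["p"] < 0.01

    def test_missing_mr1_rejected(self, bulk_ds):
        expr = bulk_ds.cohort.expr.drop(columns=["MR1"])
        cohort = m.BulkCohort(expr=expr, clinical=bulk_ds.cohort.clinical)
        with pytest.raises(m.StructuralError, match="MR1"):
            m.mr1_association(cohort, bulk_ds.z_mait)
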