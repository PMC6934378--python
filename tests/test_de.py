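"""Moderated-t differential expression, BH behavior and the concordance gate."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import scipy.stats as st

from scrobust.de import (bh_adjust, cluster_defining_genes,
                         cross_cohort_detection_test,
                         cross_dataset_characterization, de_test,
                         detection_rates, signature_overlap_test,
                         subpopulation_signature)
from scrobust.io_qc import CountMatrix

from conftest import dense_normalized


def _null(seed, n=60, g=80):
    rng = np.random.default_rng(seed)
    return dense_normalized(rng.gamma(2, 0.5, (n, g))), rng


class TestDeTest:
    def test_null_calibration(self):
        hits = total = 0
        for seed in range(20):
            norm, _ = _null(seed, n=80, g=100)
            t = de_test(norm, np.arange(40), np.arange(40, 80))
            hits += int((t["q"] < 0.1).sum())
            total += len(t)
        assert hits / total <= 0.02

    def test_planted_gene_ranks_first(self):
        norm, rng = _null(1, n=60, g=50)
        X = norm.to_dense()
        X[:30, 7] += 2.0
        t = de_test(dense_normalized(X), np.arange(30), np.arange(30, 60))
        assert t["q"].idxmin() == "G7"
        assert t.loc["G7", "fc"] > 1.25

    def test_zero_prior_on_equal_variances_matches_welch(self):
        # with equal group sizes and identical sample variances the pooled t
        # (prior df 0) coincides exactly with Welch's t
        rng = np.random.default_rng(2)
        base = rng.normal(size=(20, 40))
        X = np.vstack([base, base + rng.normal(size=40)])  # same variances
        norm = dense_normalized(X)
        fg, bg = np.arange(20), np.arange(20, 40)
        mod = de_test(norm, fg, bg, method="moderated-t", prior_df=0.0)
        welch = de_test(norm, fg, bg, method="welch-t")
        np.testing.assert_allclose(mod["t"], welch["t"], atol=1e-6)
        np.testing.assert_allclose(mod["p"], welch["p"], atol=1e-6)

    def test_symmetry_inverts_fold_change(self):
        norm, _ = _null(3)
        fg, bg = np.arange(30), np.arange(30, 60)
        a = de_test(norm, fg, bg)
        b = de_test(norm, bg, fg)
        np.testing.assert_allclose(a["fc"] * b["fc"], 1.0, rtol=1e-9)
        np.testing.assert_allclose(a["p"], b["p"], atol=1e-12)

    def test_zero_variance_gene_p_one(self):
        norm, _ = _null(4, n=20, g=10)
        X = norm.to_dense()
        X[:, 0] = 1.5
        t = de_test(dense_normalized(X), np.arange(10), np.arange(10, 20))
        assert t.loc["G0", "p"] == 1.0

    def test_overlap_and_small_sets_error(self):
        norm, _ = _null(5, n=20, g=10)
        with pytest.raises(ValueError):
            de_test(norm, [0, 1, 2], [2, 3, 4])
        with pytest.raises(ValueError):
            de_test(norm, [0, 1], [3, 4, 5])


def test_bh_false_discovery_proportion():
    rng = np.random.default_rng(0)
    q_level, fdps = 0.1, []
    for _ in range(500):
        p = rng.uniform(size=1000)
        rejected = bh_adjust(p) < q_level
        fdps.append(1.0 if rejected.any() else 0.0)
    # all hypotheses are null, so every rejection is false: FDP = 1{R>0};
    # E[FDP] must stay at or below q
    assert np.mean(fdps) <= q_level + 3 * np.std(fdps) / np.sqrt(len(fdps))


def test_bh_monotone_vs_raw():
    rng = np.random.default_rng(1)
    p = rng.uniform(size=200)
    q = bh_adjust(p)
    assert (q >= p - 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


class TestDetectionRates:
    def _counts(self):
        X = np.zeros((10, 3), dtype=int)
        X[:, 1] = 1
        X[:5, 2] = 2
        return CountMatrix(
            sp.csr_matrix(X), pd.DataFrame(index=[f"c{i}" for i in range(10)]),
            pd.DataFrame({"mito": False}, index=["A", "B", "C"]),
        )

    def test_rates(self):
        rates = detection_rates(self._counts(), {"all": np.arange(10)})
        assert rates.loc["A", "all"] == 0.0
        assert rates.loc["B", "all"] == 1.0
        assert rates.loc["C", "all"] == 0.5

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            detection_rates(self._counts(), {"none": []})


class TestClusterDefiningGenes:
    def _table(self, fc, q):
        return pd.DataFrame({"fc": fc, "q": q}, index=["G0", "G1", "G2"])

    def test_strict_thresholds_and_both_replicates(self):
        t1 = {0: self._table([1.25, 2.0, 3.0], [0.01, 0.01, 0.01])}
        t2 = {0: self._table([2.00, 2.0, 1.1], [0.01, 0.09, 0.01])}
        out = cluster_defining_genes(t1, t2)
        # G0: FC exactly 1.25 in rep1 -> excluded (strict >)
        # G1: passes both -> kept; G2: fails rep2 FC -> excluded
        assert out[0] == ["G1"]

    def test_q_boundary_strict(self):
        t1 = {0: self._table([2, 2, 2], [0.10, 0.01, 0.01])}
        t2 = {0: self._table([2, 2, 2], [0.01, 0.10, 0.01])}
        assert cluster_defining_genes(t1, t2)[0] == ["G2"]

    def test_unmatched_cluster_empty(self):
        t1 = {0: self._table([2, 2, 2], [0.01] * 3)}
        out = cluster_defining_genes(t1, {}, matching={0: None})
        assert out[0] == []


class TestSubpopulationSignature:
    @staticmethod
    def _strong_replicates():
        # strong program (e-fold 4) with ~800-UMI libraries so detection is
        # informative rather than saturated
        from scrobust.io_qc import normalize
        from scrobust.synthetic import CohortConfig, generate_cohort

        cfg = CohortConfig(
            n_datasets=1, replicates_per_dataset=2, cells_per_dataset=800,
            n_genes=1000, n_programs=4, batch_sd=0.8,
            program_effect=float(np.log(4)),
            libsize_log_mean=float(np.log(800)), doublet_rate=0.0,
            mito_high_rate=0.0, seed=7,
        )
        reps = [(normalize(m), t) for m, t in generate_cohort(cfg)]
        labels = [
            np.where(t.cells.loc[n.obs.index, "program"].to_numpy() == "P0", 0, 1)
            for n, t in reps
        ]
        return reps, labels

    def test_planted_program_recovered(self):
        reps, labels = self._strong_replicates()
        genes = subpopulation_signature(
            reps[0][0], labels[0], reps[1][0], labels[1], target=[0])
        program_genes = set(
            reps[0][1].genes.index[reps[0][1].genes["program"] == "P0"])
        inter = len(set(genes) & program_genes)
        union = len(set(genes) | program_genes)
        assert inter / union >= 0.7

    def test_impossible_margin_empty(self):
        reps, labels = self._strong_replicates()
        genes = subpopulation_signature(
            reps[0][0], labels[0], reps[1][0], labels[1], target=[0],
            det_margin=1.0)
        assert genes == []

    def test_null_target_empty(self):
        norm, rng = _null(6, n=120, g=60)
        labels = rng.integers(0, 2, 120)
        genes = subpopulation_signature(norm, labels, norm, labels, target=[0])
        assert genes == []


class TestCrossDataset:
    def test_gene_elevated_only_in_A_is_called(self):
        rng = np.random.default_rng(0)
        gX = rng.gamma(2, 0.5, (90, 40))
        gY = rng.gamma(2, 0.5, (90, 40))
        labels = np.repeat([0, 1, 2], 30)
        gX[labels == 0, 5] += 2.0  # only cluster A of X
        t1, t2, t3, calls = cross_dataset_characterization(
            dense_normalized(gX), labels, 0, dense_normalized(gY), labels, 0)
        assert "G5" in calls

    def test_shared_program_not_called(self):
        rng = np.random.default_rng(1)
        gX = rng.gamma(2, 0.5, (90, 40))
        gY = rng.gamma(2, 0.5, (90, 40))
        labels = np.repeat([0, 1, 2], 30)
        gX[labels == 0, 5] += 2.0
        gY[labels == 0, 5] += 2.0  # same elevation in B: passes (1), fails (3)
        *_, calls = cross_dataset_characterization(
            dense_normalized(gX), labels, 0, dense_normalized(gY), labels, 0)
        assert "G5" not in calls


class TestOverlap:
    def test_disjoint_sets_p_one(self):
        k, p = signature_overlap_test([f"a{i}" for i in range(10)],
                                      [f"b{i}" for i in range(10)], 20)
        assert k == 0
        assert p == pytest.approx(1.0)

    def test_identical_sets_closed_form(self):
        s = [f"g{i}" for i in range(5)]
        k, p = signature_overlap_test(s, s, 100)
        assert k == 5
        from math import comb
        assert p == pytest.approx(1 / comb(100, 5), rel=1e-9)

    def test_null_uniformity(self):
        # varied set sizes over a large universe smooth the discrete tail
        # distribution enough for a KS comparison with uniform
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(50):
            na, nb = rng.integers(50, 150), rng.integers(50, 150)
            a = rng.choice(1000, na, replace=False)
            b = rng.choice(1000, nb, replace=False)
            _, p = signature_overlap_test([str(x) for x in a],
                                          [str(x) for x in b], 1000)
            ps.append(p)
        assert st.kstest(ps, "uniform").pvalue > 0.01

    def test_universe_too_small(self):
        with pytest.raises(ValueError):
            signature_overlap_test(list("abcdef"), list("ab"), 3)


class TestCrossCohort:
    def _cohort(self, rates_a, rates_b, seed=0, cells_per_lesion=40):
        rng = np.random.default_rng(seed)
        lesions, rows = [], []
        response = {}
        for li, rate in enumerate(rates_a):
            response[f"LA{li}"] = "responder"
            for _ in range(cells_per_lesion):
                lesions.append(f"LA{li}")
                rows.append(rng.binomial(1, rate, 3))
        for li, rate in enumerate(rates_b):
            response[f"LB{li}"] = "nonresponder"
            for _ in range(cells_per_lesion):
                lesions.append(f"LB{li}")
                rows.append(rng.binomial(1, rate, 3))
        X = np.array(rows)
        m = CountMatrix(
            sp.csr_matrix(X),
            pd.DataFrame(index=[f"c{i}" for i in range(len(rows))]),
            pd.DataFrame({"mito": False}, index=["S0", "S1", "S2"]),
        )
        return m, lesions, response

    def test_separated_groups_significant(self):
        m, lesions, resp = self._cohort([0.8] * 6, [0.2] * 6)
        out = cross_cohort_detection_test(m, lesions, resp, ["S0", "S1", "S2"])
        assert (out["q"] < 0.05).all()

    def test_null_rarely_significant(self):
        sig_any = 0
        for seed in range(20):
            m, lesions, resp = self._cohort([0.5] * 4, [0.5] * 4, seed=seed)
            out = cross_cohort_detection_test(m, lesions, resp, ["S0", "S1", "S2"])
            sig_any += int((out["q"] < 0.05).any())
        assert sig_any <= 1

    def test_single_lesion_group_errors(self):
        m, lesions, resp = self._cohort([0.5], [0.5, 0.5])
        with pytest.raises(ValueError):
            cross_cohort_detection_test(m, lesions, resp, ["S0"])
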