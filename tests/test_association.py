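import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathscore.association import (
    ClinicalTable,
    adjust_pvalues,
    binary_classification,
    gene_hits,
    kaplan_meier,
    kmeans_split,
    linear_correlation,
    logrank_test,
    read_clinical,
    run_analysis,
    survival_association,
)
from pathscore.metrics import PathwayScoreMatrix
from pathscore.pathway_model import Interaction

from conftest import make_network


def enumeration_ranksum_p(a, b):
    """Two-sided exact rank-sum p by brute enumeration of all labelings."""
    pooled = np.asarray(list(a) + list(b), dtype=float)
    n1 = len(a)
    ranks = pd.Series(pooled).rank().to_numpy()
    observed = ranks[:n1].sum()
    mean = n1 * (len(pooled) + 1) / 2.0
    stats = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        stats.append(ranks[list(combo)].sum())
    stats = np.asarray(stats)
    p = np.mean(np.abs(stats - mean) >= abs(observed - mean) - 1e-9)
    return float(p)


class TestRankSum:
    def test_separated_triples(self):
        res = binary_classification([1, 2, 3, 4, 5, 6], ["A"] * 3 + ["B"] * 3)
        assert res.p_raw == pytest.approx(0.1)
        assert res.extras["method"] == "exact"

    def test_identical_multisets_give_p_one(self):
        res = binary_classification([1, 2, 3, 1, 2, 3], ["A"] * 3 + ["B"] * 3)
        assert res.p_raw == pytest.approx(1.0)

    def test_fully_separated_eights(self):
        scores = list(range(1, 17))
        res = binary_classification(scores, ["A"] * 8 + ["B"] * 8)
        assert res.p_raw == pytest.approx(2 / math.comb(16, 8))

    def test_constant_scores_give_p_one(self):
        res = binary_classification([2.0] * 6, ["A"] * 3 + ["B"] * 3)
        assert res.p_raw == 1.0
        assert res.extras["constant"]

    def test_singleton_class_rejected(self):
        with pytest.raises(ValueError):
            binary_classification([1, 2, 3], ["A", "B", "B"])

    @pytest.mark.parametrize("n1,n2", [(2, 2), (2, 4), (3, 3), (3, 5), (4, 4), (2, 8), (5, 5)])
    def test_exact_p_equals_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 100 + n2)
        scores = rng.permutation(np.arange(n1 + n2, dtype=float) + 1)
        labels = ["A"] * n1 + ["B"] * n2
        res = binary_classification(scores, labels)
        assert res.p_raw == pytest.approx(
            enumeration_ranksum_p(scores[:n1], scores[n1:]), abs=1e-10
        )

    def test_direction_sign(self):
        res = binary_classification([1, 2, 3, 7, 8, 9], ["A"] * 3 + ["B"] * 3)
        assert res.extras["direction"] == -1.0


class TestCorrelation:
    def test_perfect_linear(self):
        res = linear_correlation([1, 2, 3], [2, 4, 6])
        assert res.statistic == pytest.approx(1.0)
        assert res.p_raw == 0.0

    def test_hand_formula_four_points(self):
        # rho = 0.8, t = 0.8*sqrt(2)/0.6, two-sided p = 0.2 with 2 df
        res = linear_correlation([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.statistic == pytest.approx(0.8)
        assert res.p_raw == pytest.approx(0.2)

    def test_perfect_anticorrelation(self):
        res = linear_correlation([1, 2, 3], [3, 2, 1])
        assert res.statistic == pytest.approx(-1.0)
        assert res.p_raw == 0.0

    def test_constant_input_flagged(self):
        res = linear_correlation([1, 1, 1, 1], [1, 2, 3, 4])
        assert res.p_raw == 1.0
        assert res.extras["constant"]


class TestKmeansSplit:
    def test_clear_two_clusters(self):
        low, high = kmeans_split([0.0, 0.1, 0.9, 1.0], min_group_size=2)
        assert low.tolist() == [True, True, False, False]

    def test_min_group_size_constraint(self):
        # unconstrained optimum {0,0,0}|{1} is infeasible; best feasible is (2,2)
        low, high = kmeans_split([0.0, 0.0, 0.0, 1.0], min_group_size=2)
        assert low.sum() == 2 and high.sum() == 2

    def test_matches_exhaustive_minimization(self):
        def exhaustive(x, m):
            xs = np.sort(x)
            best, best_ss = None, np.inf
            for i in range(m, len(xs) - m + 1):
                lo, hi = xs[:i], xs[i:]
                ss = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
                if ss < best_ss - 1e-12:
                    best, best_ss = i, ss
            return best, best_ss

        rng = np.random.default_rng(33)
        for rep in range(50):
            n = int(rng.integers(6, 30))
            x = rng.normal(size=n)
            low, high = kmeans_split(x, min_group_size=3)
            i_star, ss_star = exhaustive(x, 3)
            xs_low = np.sort(x[low])
            got_ss = ((x[low] - x[low].mean()) ** 2).sum() + (
                (x[high] - x[high].mean()) ** 2
            ).sum()
            assert low.sum() == i_star
            assert got_ss == pytest.approx(ss_star, abs=1e-9)
            assert xs_low.max() <= np.sort(x[high]).min() + 1e-12

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            kmeans_split([1.0] * 10, min_group_size=2)


class TestSurvival:
    def test_product_limit_hand_example(self):
        times, surv = kaplan_meier([1, 2, 3], [1, 1, 1])
        assert surv == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_all_censored_flat_curve(self):
        times, surv = kaplan_meier([1, 2, 3], [0, 0, 0])
        assert len(times) == 0

    def test_single_event_among_n(self):
        _, surv = kaplan_meier([5, 6, 7, 8], [1, 0, 0, 0])
        assert surv[0] == pytest.approx(3 / 4)

    def test_logrank_worked_example(self):
        # deaths at {1,2} vs {3,4}: O1-E1 = 7/6, V = 17/36, chi2 = 49/17
        chi2, p = logrank_test(([1, 2], [1, 1]), ([3, 4], [1, 1]))
        assert chi2 == pytest.approx(49 / 17, abs=5e-4)

    def test_logrank_symmetry(self):
        g1 = ([1, 3, 5, 7], [1, 1, 0, 1])
        g2 = ([2, 4, 6, 8], [1, 0, 1, 1])
        assert logrank_test(g1, g2) == pytest.approx(logrank_test(g2, g1))

    def test_identical_groups_give_zero(self):
        g = ([1, 2, 3, 4], [1, 1, 1, 1])
        chi2, p = logrank_test(g, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_no_events_flagged(self):
        chi2, p = logrank_test(([1, 2], [0, 0]), ([3, 4], [0, 0]))
        assert (chi2, p) == (0.0, 1.0)

    def test_survival_association_detects_planted_hazard(self):
        # pathway behaves bimodally; hazard doubled in the high-score mode
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(500 + rep)
            high = np.arange(100) < 50
            scores = np.where(
                high, rng.normal(0.7, 0.05, 100), rng.normal(0.3, 0.05, 100)
            )
            tim = rng.exponential(np.where(high, 0.5, 1.0))
            res = survival_association(scores, tim, np.ones(100, int))
            hits += res.p_raw < 0.05
        assert hits >= 18

    def test_constant_scores_propagate_error(self):
        with pytest.raises(ValueError):
            survival_association([1.0] * 20, np.arange(20), np.ones(20, int))


class TestGeneHits:
    def _net_with_genes(self, genes):
        net = make_network("pw", [Interaction("i1", ["A", "B"], [], ["C", "D"])])
        for mid, g in zip(["A", "B", "C", "D"], genes):
            net.molecules[mid].entrez_ids = [g]
        return net

    def test_hand_hypergeometric_single_sample(self):
        # N=10 genes, K=4 in pathway, sample alters 5, 4 of them in pathway
        genes = [str(i) for i in range(1, 11)]
        net = self._net_with_genes(genes[:4])
        col = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]  # alters genes 1-5
        alt = pd.DataFrame({"s1": col}, index=genes)
        res = gene_hits(alt, net)
        p_s = 6 / 252
        assert res.statistic == pytest.approx(-2 * math.log(p_s))
        # omnibus with 2 df: p = exp(-X/2)
        assert res.p_raw == pytest.approx(p_s)

    def test_matches_enumeration_oracle_small_universe(self):
        # brute force over all C(N, n) placements of the altered set
        rng = np.random.default_rng(77)
        for rep in range(20):
            n_universe = int(rng.integers(5, 13))
            genes = [str(i) for i in range(n_universe)]
            k_path = int(rng.integers(1, n_universe))
            net = self._net_with_genes(genes[:min(k_path, 4)] + genes[:1] * 0)
            pathway_genes = set(net.gene_set())
            n_alt = int(rng.integers(1, n_universe + 1))
            altered = set(rng.choice(n_universe, size=n_alt, replace=False).tolist())
            k_obs = len({i for i in altered if genes[i] in pathway_genes})
            total = hits = 0
            for combo in itertools.combinations(range(n_universe), n_alt):
                k = len({i for i in combo if genes[i] in pathway_genes})
                total += 1
                hits += k >= k_obs
            col = [1 if i in altered else 0 for i in range(n_universe)]
            alt = pd.DataFrame({"s1": col}, index=genes)
            res = gene_hits(alt, net)
            expected_p_s = hits / total
            assert math.exp(-res.statistic / 2) == pytest.approx(expected_p_s, abs=1e-10)

    def test_zero_alteration_samples_excluded(self):
        genes = [str(i) for i in range(10)]
        net = self._net_with_genes(genes[:4])
        alt = pd.DataFrame(
            {"s1": [1, 1, 1, 1, 1, 0, 0, 0, 0, 0], "s2": [0] * 10}, index=genes
        )
        res = gene_hits(alt, net)
        assert res.extras["n_samples"] == 1

    def test_omnibus_combination_closed_form(self):
        # p-values {6/252, 0.5}: X = -2(ln p1 + ln p2), chi2 survival with 4 df
        p1, p2 = 6 / 252, 0.5
        x = -2 * (math.log(p1) + math.log(p2))
        expected = math.exp(-x / 2) * (1 + x / 2)
        assert x == pytest.approx(8.862, abs=5e-3)
        assert expected == pytest.approx(0.065, abs=5e-3)

    def test_disjoint_pathway_not_testable(self):
        net = self._net_with_genes(["901", "902", "903", "904"])
        alt = pd.DataFrame({"s1": [1, 0]}, index=["1", "2"])
        res = gene_hits(alt, net)
        assert not res.extras["testable"]


class TestAdjustment:
    def test_bonferroni_examples(self):
        assert adjust_pvalues([0.001] * 50)[0] == pytest.approx(0.05)
        assert adjust_pvalues([0.5] + [0.01] * 9)[0] == 1.0
        assert adjust_pvalues([0.3])[0] == pytest.approx(0.3)

    def test_bh_monotone_and_bounded(self):
        rng = np.random.default_rng(0)
        p = rng.random(40)
        adj = adjust_pvalues(p, method="bh")
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_bonferroni_significance_subset(self, p):
        adj = adjust_pvalues(p)
        assert set(np.flatnonzero(np.asarray(adj) < 0.05)) <= set(
            np.flatnonzero(np.asarray(p) < 0.05)
        )


def _toy_scores(rng, n_pathways=20, n_samples=12):
    samples = [f"s{j}" for j in range(n_samples)]
    idx = [f"pw{i}" for i in range(n_pathways)]
    return PathwayScoreMatrix(
        activity=pd.DataFrame(rng.random((n_pathways, n_samples)), index=idx, columns=samples),
        consistency=pd.DataFrame(rng.random((n_pathways, n_samples)), index=idx, columns=samples),
    )


class TestRunAnalysis:
    def test_correlation_run_counts_and_ordering(self):
        rng = np.random.default_rng(0)
        scores = _toy_scores(rng)
        clin = ClinicalTable(
            kind="correlation",
            sample_ids=scores.sample_ids,
            values=rng.normal(size=12),
        )
        table = run_analysis(scores, clin, "correlation")
        assert len(table) == 40  # 20 pathways x 2 metrics
        assert table["p_raw"].is_monotonic_increasing
        assert np.all(table["p_adjusted"] >= table["p_raw"] - 1e-12)

    def test_class_restriction_filters_samples(self):
        rng = np.random.default_rng(1)
        scores = _toy_scores(rng, n_samples=16)
        labels = ["tumor"] * 10 + ["normal"] * 6
        clin = ClinicalTable(
            kind="correlation", sample_ids=scores.sample_ids,
            values=rng.normal(size=16), labels=labels,
        )
        table = run_analysis(scores, clin, "correlation", restrict_class="tumor")
        assert table.iloc[0]["extras"]["n"] == 10

    def test_unknown_test_kind(self):
        rng = np.random.default_rng(2)
        scores = _toy_scores(rng)
        clin = ClinicalTable(kind="correlation", sample_ids=scores.sample_ids,
                             values=rng.normal(size=12))
        with pytest.raises(ValueError, match="unknown test"):
            run_analysis(scores, clin, "anova")

    def test_empty_intersection(self):
        rng = np.random.default_rng(3)
        scores = _toy_scores(rng)
        clin = ClinicalTable(kind="correlation", sample_ids=["zz1", "zz2", "zz3"],
                             values=np.ones(3))
        with pytest.raises(ValueError, match="no samples"):
            run_analysis(scores, clin, "correlation")


class TestClinicalIO:
    def test_round_trip_formats(self, tmp_path):
        f = tmp_path / "class.tsv"
        f.write_text("s1\tA\ns2\tB\n")
        t = read_clinical(f, "class")
        assert t.labels == ["A", "B"]

        f2 = tmp_path / "cont.tsv"
        f2.write_text("sample\tvalue\ns1\t1.5\ns2\t-2.0\n")
        t2 = read_clinical(f2, "correlation")
        assert t2.values == pytest.approx([1.5, -2.0])

        f3 = tmp_path / "surv.tsv"
        f3.write_text("s1\t3.5\t1\ns2\t8\t0\n")
        t3 = read_clinical(f3, "survival")
        assert t3.times == pytest.approx([3.5, 8.0])
        assert t3.events.tolist() == [1, 0]

        f4 = tmp_path / "alt.tsv"
        f4.write_text("gene\ts1\ts2\n101\t1\t0\n102\t0\t1\n")
        t4 = read_clinical(f4, "genehits")
        assert t4.alterations.loc["101", "s1"] == 1
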