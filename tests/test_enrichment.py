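"""Enrichment statistics against independent brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from optiregen import enrichment as en
from optiregen import phantoms
from tests.conftest import decoy_sets


# ---------------------------------------------------------------------------
# Independent oracles (kept deliberately naive)
# ---------------------------------------------------------------------------

def oracle_size_factors(matrix: np.ndarray) -> np.ndarray:
    n_genes, n_samples = matrix.shape
    keep = [g for g in range(n_genes) if all(matrix[g] > 0)]
    factors = []
    for s in range(n_samples):
        ratios = []
        for g in keep:
            geomean = math.exp(sum(math.log(v) for v in matrix[g])
                               / n_samples)
            ratios.append(matrix[g, s] / geomean)
        factors.append(float(np.median(ratios)))
    # standardize to unit geometric mean
    gm = math.exp(sum(math.log(f) for f in factors) / n_samples)
    return np.array(factors) / gm


def oracle_running_sum_es(ordered_genes, scores_by_gene, gene_set, weight):
    """Walk the ranking one gene at a time and track the extremum."""
    hits = [g for g in ordered_genes if g in gene_set]
    nr = sum(abs(scores_by_gene[g]) ** weight for g in hits)
    n_miss = len(ordered_genes) - len(hits)
    running, best = 0.0, 0.0
    for g in ordered_genes:
        if g in gene_set:
            running += (abs(scores_by_gene[g]) ** weight) / nr
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


def oracle_bh(pvals):
    """Textbook step-up BH."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = min(prev, p[i] * m / rank_from_end)
        adj[i] = val
        prev = val
    return adj


def oracle_hypergeom_p(N, m, n, k):
    """P(overlap >= k) by enumerating every n-subset of the universe."""
    members = set(range(m))
    total = hits = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(members & set(draw)) >= k:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# median-ratio normalization
# ---------------------------------------------------------------------------

class TestMedianRatioNormalize:
    def test_identical_samples_give_unit_factors(self):
        m = pd.DataFrame({"s1": [10, 5, 100], "s2": [10, 5, 100]})
        sf, norm = en.median_ratio_normalize(m)
        np.testing.assert_allclose(sf, 1.0)
        pd.testing.assert_frame_equal(norm, m.astype(float))

    def test_worked_three_gene_matrix_matches_oracle(self):
        m = pd.DataFrame([[10, 20], [100, 200], [4, 8]],
                         columns=["s1", "s2"])
        sf, _ = en.median_ratio_normalize(m)
        np.testing.assert_allclose(sf, oracle_size_factors(m.to_numpy()))
        np.testing.assert_allclose(sf, [1 / math.sqrt(2), math.sqrt(2)])

    def test_scaled_sample_factor_ratio_recovered(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(50, size=200) + 1
        mat = np.tile(base[:, None].astype(float), (1, 4))
        mat[:, 2] *= 2
        sf, _ = en.median_ratio_normalize(pd.DataFrame(
            mat, columns=list("abcd")))
        others = np.delete(sf.to_numpy(), 2)
        assert sf.iloc[2] / others.mean() == pytest.approx(2.0, rel=1e-9)
        # noisy libraries recover the scale approximately
        noisy = (base[:, None] * rng.uniform(0.9, 1.1, (200, 4)))
        noisy[:, 2] *= 2
        sf2, _ = en.median_ratio_normalize(pd.DataFrame(
            noisy, columns=list("abcd")))
        assert sf2.iloc[2] / np.delete(sf2.to_numpy(), 2).mean() \
            == pytest.approx(2.0, rel=0.05)

    def test_random_matrices_match_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            m = rng.poisson(20, size=(30, 5))
            sf, _ = en.median_ratio_normalize(pd.DataFrame(m))
            np.testing.assert_allclose(sf, oracle_size_factors(m),
                                       rtol=1e-12)

    def test_idempotence(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.poisson(40, size=(100, 6)) + 1)
        _, norm = en.median_ratio_normalize(m)
        sf2, _ = en.median_ratio_normalize(norm)
        np.testing.assert_allclose(sf2, 1.0, atol=1e-9)

    def test_no_reference_gene_rejected(self):
        m = pd.DataFrame({"s1": [0, 5], "s2": [3, 0]})
        with pytest.raises(ValueError, match="no reference genes"):
            en.median_ratio_normalize(m)


# ---------------------------------------------------------------------------
# permutation DE test
# ---------------------------------------------------------------------------

class TestDeTest:
    def test_identical_groups_give_null_results(self):
        m = pd.DataFrame(np.tile([[4.0, 4.0, 4.0, 4.0]], (10, 1)),
                         columns=list("abcd"))
        res = en.de_test(m, ["g1", "g1", "g2", "g2"])
        assert np.allclose(res["log2fc"], 0.0)
        assert np.allclose(res["p"], 1.0)

    def test_worked_log2fc_with_pseudocount(self):
        m = pd.DataFrame([[1.0, 1.0, 4.0, 4.0]], columns=list("abcd"))
        res = en.de_test(m, ["g1", "g1", "g2", "g2"], pseudocount=1)
        assert res["log2fc"].iloc[0] == pytest.approx(math.log2(5 / 2))

    def test_gene_and_sample_order_invariance(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.poisson(30, size=(40, 8)).astype(float),
                         index=[f"g{i}" for i in range(40)],
                         columns=[f"s{i}" for i in range(8)])
        groups = ["x"] * 4 + ["y"] * 4
        res1 = en.de_test(m, groups, seed=0).set_index("gene")
        shuffled = m.sample(frac=1, random_state=5)
        res2 = en.de_test(shuffled, groups, seed=0).set_index("gene")
        pd.testing.assert_frame_equal(res1.sort_index(), res2.sort_index())
        # swapping samples within a group leaves statistics unchanged
        m3 = m[["s1", "s0", "s2", "s3", "s5", "s4", "s6", "s7"]]
        res3 = en.de_test(m3, groups, seed=0).set_index("gene")
        pd.testing.assert_frame_equal(res1, res3)

    def test_null_type_one_error_calibrated(self):
        spec = phantoms.CountPhantomSpec(n_genes=2000, seed=8,
                                         spiked_log2fc=0.0)
        counts, truth = phantoms.make_count_matrix(spec)
        groups = [truth["groups"][s] for s in counts.columns]
        _, norm = en.median_ratio_normalize(counts)
        res = en.de_test(norm, groups, seed=1)
        assert (res["p"] < 0.05).mean() == pytest.approx(0.05, abs=0.015)

    def test_single_group_rejected(self):
        m = pd.DataFrame(np.ones((5, 4)), columns=list("abcd"))
        with pytest.raises(ValueError, match="two groups"):
            en.de_test(m, ["g1"] * 4)

    def test_fdr_is_bh_of_p(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.poisson(30, size=(50, 8)).astype(float))
        res = en.de_test(m, ["x"] * 4 + ["y"] * 4, seed=0)
        np.testing.assert_allclose(res["fdr"], oracle_bh(res["p"]))
        assert (res["fdr"] >= res["p"] - 1e-12).all()


class TestDeFilter:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene", "log2fc", "p", "fdr"])

    def test_strict_boundaries(self):
        t = self._table([("a", 1.0, 0.01, 0.01),    # log2fc at threshold
                         ("b", 1.5, 0.05, 0.05),    # fdr at threshold
                         ("c", 1.5, 0.001, 0.01),
                         ("d", -1.2, 0.001, 0.01)])
        up, down = en.de_filter(t)
        assert up == ["c"]
        assert down == ["d"]

    def test_spiked_genes_pass_filter(self):
        # 6 replicates per group: the exhaustive permutation p floor
        # (1/923) is fine enough for BH FDR < 0.05 to be reachable
        spec = phantoms.CountPhantomSpec(n_genes=800, n_per_group=6,
                                         seed=21, spiked_log2fc=2.0)
        counts, truth = phantoms.make_count_matrix(spec)
        groups = [truth["groups"][s] for s in counts.columns]
        _, norm = en.median_ratio_normalize(counts)
        res = en.de_test(norm, groups, seed=2)
        up, _ = en.de_filter(res)
        spiked = set(truth["spiked_set"]["CHOLESTEROL_BIOSYNTHESIS"])
        assert len(spiked & set(up)) >= 0.8 * len(spiked)


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------

class TestEnrichmentScore:
    def test_top_block_set_reaches_plus_one_with_weight_zero(self):
        scores = pd.Series(np.arange(10, 0, -1, dtype=float),
                           index=[f"g{i}" for i in range(10)])
        es = en.enrichment_score(scores, {"g0", "g1", "g2"}, weight=0.0)
        assert es == pytest.approx(1.0)

    @pytest.mark.parametrize("weight", [0.0, 1.0, 2.0])
    def test_matches_brute_force_oracle_on_ten_gene_universe(self, weight):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(10)]
        scores = pd.Series(rng.normal(size=10), index=genes)
        gene_set = {"g2", "g5", "g7"}
        ordered = list(scores.sort_values(ascending=False).index)
        expected = oracle_running_sum_es(ordered, scores.to_dict(),
                                         gene_set, weight)
        es = en.enrichment_score(scores, gene_set, weight=weight)
        assert es == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_oracle_equivalence_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        genes = [f"g{i}" for i in range(n)]
        scores = pd.Series(rng.normal(size=n), index=genes)
        m = int(rng.integers(1, n - 1))
        gene_set = set(rng.choice(genes, size=m, replace=False))
        ordered = list(scores.sort_values(ascending=False).index)
        expected = oracle_running_sum_es(ordered, scores.to_dict(),
                                         gene_set, 1.0)
        assert en.enrichment_score(scores, gene_set) \
            == pytest.approx(expected, abs=1e-12)

    def test_degenerate_sets_rejected(self):
        scores = pd.Series([3.0, 2.0, 1.0], index=list("abc"))
        with pytest.raises(ValueError):
            en.enrichment_score(scores, set())
        with pytest.raises(ValueError):
            en.enrichment_score(scores, {"a", "b", "c"})


class TestGsea:
    def test_spiked_set_ranks_first_by_nes(self, count_phantom_spiked):
        counts, groups, truth = count_phantom_spiked
        _, norm = en.median_ratio_normalize(counts)
        logn = np.log2(norm + 1)
        spiked = truth["spiked_set"]["CHOLESTEROL_BIOSYNTHESIS"]
        sets = {"CHOLESTEROL_BIOSYNTHESIS": spiked}
        sets.update(decoy_sets(counts.index, spiked, 20, 25, seed=77))
        res = en.gsea(logn, groups, sets, n_perm=500, seed=5)
        assert res.iloc[0]["set"] == "CHOLESTEROL_BIOSYNTHESIS"
        assert abs(res.iloc[0]["es"]) <= 1.0 + 1e-12

    def test_size_filter_applied_after_universe_intersection(self):
        rng = np.random.default_rng(6)
        expr = pd.DataFrame(rng.normal(size=(30, 8)),
                            index=[f"g{i}" for i in range(30)],
                            columns=[f"s{i}" for i in range(8)])
        groups = ["a"] * 4 + ["b"] * 4
        sets = {"too_small": ["g0", "g1", "missing1", "missing2"],
                "ok": [f"g{i}" for i in range(5, 12)]}
        res = en.gsea(expr, groups, sets, min_size=5, n_perm=50, seed=0)
        assert list(res["set"]) == ["ok"]
        with pytest.raises(ValueError, match="no gene set survives"):
            en.gsea(expr, groups, {"tiny": ["g0"]}, n_perm=50, seed=0)

    def test_permutation_p_converges_across_seeds(self):
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(rng.normal(size=(60, 12)),
                            index=[f"g{i}" for i in range(60)],
                            columns=[f"s{i}" for i in range(12)])
        expr.iloc[:8, 6:] += 1.0  # enrich one block
        groups = ["a"] * 6 + ["b"] * 6
        sets = {"block": [f"g{i}" for i in range(8)]}
        ps = [en.gsea(expr, groups, sets, n_perm=400, seed=s)["p"].iloc[0]
              for s in (0, 1)]
        mc_se = math.sqrt(max(ps[0], 1e-3) * (1 - ps[0]) / 400)
        assert abs(ps[0] - ps[1]) <= 4 * mc_se + 1e-6

    def test_nes_sign_follows_es(self, count_phantom_spiked):
        counts, groups, truth = count_phantom_spiked
        _, norm = en.median_ratio_normalize(counts)
        logn = np.log2(norm + 1)
        spiked = truth["spiked_set"]["CHOLESTEROL_BIOSYNTHESIS"]
        sets = {"spike": spiked}
        sets.update(decoy_sets(counts.index, spiked, 5, 25, seed=78))
        res = en.gsea(logn, groups, sets, n_perm=200, seed=6)
        finite = res[np.isfinite(res["nes"])]
        assert (np.sign(finite["nes"]) == np.sign(finite["es"])).all()


# ---------------------------------------------------------------------------
# intersection, ORA, ddCt, BH
# ---------------------------------------------------------------------------

class TestCommonGenes:
    def _table(self, fc_by_gene, universe):
        return pd.DataFrame({"gene": universe,
                             "log2fc": [fc_by_gene.get(g, 0.0)
                                        for g in universe]})

    def test_identical_tables_reduce_to_own_filter(self):
        uni = [f"g{i}" for i in range(6)]
        fc = {"g0": 1.0, "g1": 0.3, "g2": -2.0}
        t = self._table(fc, uni)
        out = en.common_genes(t, t, t)
        # linear |FC| > 1.5 <=> |log2fc| > log2(1.5) ~ 0.585
        assert out == ["g0", "g2"]

    def test_boundary_is_strict(self):
        uni = ["g0", "g1"]
        t = self._table({"g0": math.log2(1.5), "g1": 1.0}, uni)
        assert en.common_genes(t, t, t) == ["g1"]
        assert en.common_genes(t, t, t, fc_abs=1.0, scale="log2") == []

    def test_disjoint_passing_sets_give_empty(self):
        uni = ["g0", "g1"]
        a = self._table({"g0": 2.0}, uni)
        b = self._table({"g1": 2.0}, uni)
        assert en.common_genes(a, b, a) == []

    def test_constructed_overlap_of_seven(self):
        uni = [f"g{i}" for i in range(30)]
        shared = {f"g{i}": 2.0 for i in range(7)}
        a = self._table({**shared, "g10": 3.0}, uni)
        b = self._table({**shared, "g11": -3.0}, uni)
        c = self._table({**shared, "g12": 2.5}, uni)
        assert len(en.common_genes(a, b, c)) == 7

    def test_universe_mismatch_rejected(self):
        a = self._table({}, ["g0", "g1"])
        b = self._table({}, ["g0", "g2"])
        with pytest.raises(ValueError, match="universes disagree"):
            en.common_genes(a, b, a)


class TestOra:
    def test_full_overlap_ratio(self):
        uni = [f"g{i}" for i in range(100)]
        sets = {"s": uni[:10]}
        res = en.ora(uni[:10], sets, uni)
        assert res["enrichment_ratio"].iloc[0] == pytest.approx(10.0)

    def test_overlap_at_expectation_gives_unit_ratio(self):
        uni = [f"g{i}" for i in range(100)]
        sets = {"s": uni[:10]}  # expectation of a 20-gene list: k = 2
        lst = uni[:2] + uni[50:68]
        res = en.ora(lst, sets, uni)
        assert res["enrichment_ratio"].iloc[0] == pytest.approx(1.0)

    def test_p_matches_exhaustive_enumeration(self):
        N, m, n, k = 20, 5, 5, 4
        uni = [f"g{i}" for i in range(N)]
        sets = {"s": uni[:m]}
        lst = uni[:k] + uni[10:10 + (n - k)]
        res = en.ora(lst, sets, uni)
        assert res["p"].iloc[0] == pytest.approx(
            oracle_hypergeom_p(N, m, n, k), abs=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            en.ora([], {"s": ["g0"]}, ["g0", "g1"])


class TestDdct:
    def _cq(self, rows):
        return pd.DataFrame(rows, columns=["sample", "group", "gene", "Cq"])

    def test_control_sample_at_unit_fold(self):
        cq = self._cq([("c1", "control", "srebf2", 25.0),
                       ("c1", "control", "gapdh", 18.0),
                       ("c2", "control", "srebf2", 25.0),
                       ("c2", "control", "gapdh", 18.0)])
        res = en.ddct(cq, "srebf2")
        np.testing.assert_allclose(res["fold_change"], 1.0)

    @pytest.mark.parametrize("shift,fold", [(-1.0, 2.0), (-3.0, 8.0)])
    def test_cycle_shift_identities(self, shift, fold):
        cq = self._cq([("c1", "control", "srebf2", 25.0),
                       ("c1", "control", "gapdh", 18.0),
                       ("t1", "injured", "srebf2", 25.0 + shift),
                       ("t1", "injured", "gapdh", 18.0)])
        res = en.ddct(cq, "srebf2")
        t = res[res["group"] == "injured"]
        assert t["fold_change"].iloc[0] == pytest.approx(fold)
        assert (res["fold_change"] > 0).all()

    def test_missing_reference_rejected(self):
        cq = self._cq([("c1", "control", "srebf2", 25.0)])
        with pytest.raises(ValueError, match="reference gene"):
            en.ddct(cq, "srebf2")

    def test_technical_replicates_averaged(self):
        cq = self._cq([("c1", "control", "srebf2", 25.0),
                       ("c1", "control", "srebf2", 27.0),
                       ("c1", "control", "gapdh", 18.0)])
        res = en.ddct(cq, "srebf2")
        assert res["dct"].iloc[0] == pytest.approx(8.0)


class TestBhAdjust:
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_step_up_oracle(self, pvals):
        np.testing.assert_allclose(en.bh_adjust(pvals), oracle_bh(pvals),
                                   atol=1e-12)
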