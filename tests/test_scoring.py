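"""Additive signature scores, KS enrichment, GSEA running sum."""

import itertools

import numpy as np
import pytest
from scipy import sparse, stats

import coactivate as ca
from conftest import make_matrix


def norm_matrix(norm_rows, genes):
    """Matrix with a prescribed norm layer (counts irrelevant for scoring)."""
    arr = np.asarray(norm_rows, dtype=float)
    m = make_matrix(np.ones_like(arr, dtype=int), genes=genes)
    m.norm = sparse.csr_matrix(arr)
    m.norm_config = ca.NormalizationConfig()
    return m


class TestScoreSignature:
    def test_additive_by_definition(self):
        m = norm_matrix([[1, 2, 5], [0, 0, 7]], genes=["Irf3", "Tbk1", "Actb"])
        sv = ca.score_signature(m, ca.GeneSignature("s", ("Irf3", "Tbk1")))
        np.testing.assert_allclose(sv.values, [3, 0])
        assert sv.coverage == 1.0

    def test_partial_coverage(self):
        m = norm_matrix([[2.0, 1.0]], genes=["Irf3", "Actb"])
        sv = ca.score_signature(m, ca.GeneSignature("s", ("Irf3", "NotAGene1")))
        assert sv.coverage == 0.5
        assert sv.values[0] == pytest.approx(2.0)

    def test_disjoint_signatures_are_linear(self, small_dataset, signatures):
        m, _ = small_dataset
        a, b = signatures["cGAS-STING"], signatures["Endothelial activation/proliferation"]
        union = ca.GeneSignature("u", a.genes + b.genes)
        sa = ca.score_signature(m, a).values
        sb = ca.score_signature(m, b).values
        su = ca.score_signature(m, union).values
        np.testing.assert_allclose(su, sa + sb, rtol=1e-10)

    def test_zero_overlap_rejected(self):
        m = norm_matrix([[1.0]], genes=["Actb"])
        with pytest.raises(ca.MissingSignatureError, match="ghost"):
            ca.score_signature(m, ca.GeneSignature("ghost", ("NotAGene1",)))

    def test_mean_mode_divides_by_genes_used(self):
        m = norm_matrix([[2, 4]], genes=["Irf3", "Tbk1"])
        sv = ca.score_signature(
            m, ca.GeneSignature("s", ("Irf3", "Tbk1")), scale="mean"
        )
        assert sv.values[0] == pytest.approx(3.0)

    def test_alias_resolution_matches_canonical_column(self):
        # Tmem173 in the signature must find the Sting1 column in the matrix
        m = norm_matrix([[5.0, 1.0]], genes=["Sting1", "Actb"])
        sv = ca.score_signature(m, ca.GeneSignature("s", ("Tmem173",)))
        assert sv.values[0] == pytest.approx(5.0)
        assert sv.coverage == 1.0


def ks_enumeration_oracle(a, b):
    """Exact permutation p for the two-sample KS statistic by enumerating
    all C(n+m, n) group assignments of the pooled (tie-free) sample."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.sort(np.concatenate([a, b]))
    n, m = a.size, b.size

    def d_stat(x, y):
        grid = pooled
        fx = np.searchsorted(np.sort(x), grid, side="right") / x.size
        fy = np.searchsorted(np.sort(y), grid, side="right") / y.size
        return np.max(np.abs(fx - fy))

    d_obs = d_stat(a, b)
    count = total = 0
    for idx in itertools.combinations(range(n + m), n):
        mask = np.zeros(n + m, dtype=bool)
        mask[list(idx)] = True
        if d_stat(pooled[mask], pooled[~mask]) >= d_obs - 1e-12:
            count += 1
        total += 1
    return d_obs, count / total


class TestKsEnrichment:
    def test_identical_samples(self):
        r = ca.ks_enrichment([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_fully_separated(self):
        r = ca.ks_enrichment([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert r.statistic == 1.0

    def test_small_sample_against_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n, m = rng.integers(3, 8, size=2)
            a = rng.normal(size=n)
            b = rng.normal(0.5, size=m)
            d_oracle, p_oracle = ks_enumeration_oracle(a, b)
            r = ca.ks_enrichment(a, b)
            assert r.statistic == pytest.approx(d_oracle, abs=1e-12)
            assert r.p_value == pytest.approx(p_oracle, abs=1e-8)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=20), rng.normal(1, size=25)
        r1 = ca.ks_enrichment(a, b)
        r2 = ca.ks_enrichment(np.exp(a), np.exp(b))
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ca.ValidationError):
            ca.ks_enrichment([], [1.0])


def gsea_bruteforce_oracle(ranked_hits, weights):
    """Naive loop re-implementation of the weighted running sum."""
    n = len(ranked_hits)
    n_hit = sum(ranked_hits)
    total_w = sum(w for w, h in zip(weights, ranked_hits) if h)
    if total_w == 0:
        weights = [1.0] * n
        total_w = float(n_hit)
    running, best = 0.0, 0.0
    for i in range(n):
        if ranked_hits[i]:
            running += weights[i] / total_w
        else:
            running -= 1.0 / (n - n_hit)
        if abs(running) > abs(best):
            best = running
    return best


def random_gsea_instance(rng, n_max=50, set_max=10):
    n = int(rng.integers(5, n_max + 1))
    genes = [f"g{i}" for i in range(n)]
    scores = rng.normal(size=n)
    k = int(rng.integers(1, min(set_max, n - 1) + 1))
    members = rng.choice(genes, size=k, replace=False)
    return genes, scores, ca.GeneSignature("set", tuple(members))


class TestGseaES:
    def test_single_gene_at_top_rank(self):
        genes = ["a", "b", "c", "d"]
        scores = [4.0, 3.0, 2.0, 1.0]
        r = ca.gsea_es(genes, scores, ca.GeneSignature("s", ("a",)), weight_p=0,
                       n_permutations=0)
        assert r.statistic == pytest.approx(1.0)

    def test_uniformly_spread_set_has_small_es(self):
        n = 400
        genes = [f"g{i}" for i in range(n)]
        scores = np.linspace(1, 0, n)
        members = tuple(genes[i] for i in range(0, n, 20))
        r = ca.gsea_es(genes, scores, ca.GeneSignature("s", members), weight_p=0,
                       n_permutations=0)
        assert abs(r.statistic) < 0.1

    @pytest.mark.parametrize("weight_p", [0, 1])
    def test_matches_bruteforce_oracle(self, weight_p):
        rng = np.random.default_rng(11)
        for _ in range(100):
            genes, scores, sig = random_gsea_instance(rng)
            r = ca.gsea_es(genes, scores, sig, weight_p=weight_p, n_permutations=0)
            order = np.argsort(-scores, kind="stable")
            hits = [genes[i] in set(sig.genes) for i in order]
            w = [abs(scores[i]) ** weight_p for i in order]
            assert r.statistic == pytest.approx(
                gsea_bruteforce_oracle(hits, w), abs=1e-12
            )

    def test_degenerate_set_covering_ranking_rejected(self):
        genes = ["a", "b"]
        with pytest.raises(ca.ValidationError):
            ca.gsea_es(genes, [1.0, 0.5], ca.GeneSignature("s", ("a", "b")),
                       n_permutations=0)

    def test_permutation_p_lower_bound_and_nes_sign(self):
        rng = np.random.default_rng(5)
        genes, scores, sig = random_gsea_instance(rng)
        r = ca.gsea_es(genes, scores, sig, n_permutations=200, seed=3)
        assert r.p_value >= 1 / 201
        if r.nes is not None and r.nes != 0:
            assert np.sign(r.nes) == np.sign(r.statistic)

    def test_null_p_values_super_uniform(self):
        """Empirical CDF of permutation p at 0.05 stays within binomial
        99% bounds of 0.05 under the null (random set placements)."""
        rng = np.random.default_rng(21)
        n_draws, alpha = 1000, 0.05
        hits = 0
        for i in range(n_draws):
            genes, scores, sig = random_gsea_instance(rng, n_max=40, set_max=8)
            r = ca.gsea_es(genes, scores, sig, n_permutations=199, seed=int(i))
            if r.p_value <= alpha:
                hits += 1
        se = np.sqrt(alpha * (1 - alpha) / n_draws)
        assert abs(hits / n_draws - alpha) <= 2.576 * se + 1e-9


class TestSummarizeByGroup:
    def _scores(self, values, groups):
        import pandas as pd

        sv = ca.ScoreVector(
            signature_name="s",
            values=np.asarray(values, float),
            cell_ids=pd.Index([f"c{i}" for i in range(len(values))]),
            n_genes_used=1,
            coverage=1.0,
        )
        return ca.summarize_by_group(sv, groups)

    def test_normalized_n_is_relative_to_largest_group(self):
        table = self._scores([1.0] * 150, ["P6"] * 100 + ["P12"] * 50)
        assert dict(zip(table["group"], table["normalized_n"])) == {
            "P6": 1.0, "P12": 0.5,
        }

    def test_single_group(self):
        table = self._scores([1.0, 2.0], ["a", "a"])
        assert table["normalized_n"].tolist() == [1.0]

    def test_constant_scores(self):
        table = self._scores([3.0] * 10, ["x"] * 5 + ["y"] * 5)
        assert (table["mean"] == 3.0).all() and (table["median"] == 3.0).all()
        assert table["total"].tolist() == [15.0, 15.0]
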