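"""Spearman co-activation, stratification, and high/low contrasts."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import coactivate as ca
from conftest import make_matrix


def spearman_enumeration_oracle(x, y):
    """Independent full-enumeration oracle: Pearson-on-ranks rho and the
    two-sided exact permutation p, via plain loops over permutations."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    count = total = 0
    for perm in itertools.permutations(range(len(y))):
        r = float(np.corrcoef(rx, ry[list(perm)])[0, 1])
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
        total += 1
    return rho, count / total


class TestSpearmanCoactivation:
    def test_monotone_identity(self):
        r = ca.spearman_coactivation([1, 2, 3], [10, 20, 30])
        assert r.rho == pytest.approx(1.0)

    def test_antitone(self):
        r = ca.spearman_coactivation([1, 2, 3], [3, 2, 1])
        assert r.rho == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ca.ValidationError, match="constant"):
            ca.spearman_coactivation([1, 1, 1], [1, 2, 3])

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(15):
            n = int(rng.integers(4, 8))
            x = rng.normal(size=n)
            y = rng.integers(0, 4, size=n).astype(float)  # ties included
            rho_o, p_o = spearman_enumeration_oracle(x, y)
            if not np.isfinite(rho_o):  # constant y draw
                continue
            r = ca.spearman_coactivation(x, y, p_method="exact")
            assert r.rho == pytest.approx(rho_o, abs=1e-12)
            assert r.p_value == pytest.approx(p_o, abs=1e-12)

    def test_permutation_p_close_to_exact(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=7), rng.normal(size=7)
        exact = ca.spearman_coactivation(x, y, p_method="exact")
        mc = ca.spearman_coactivation(
            x, y, p_method="permutation", seed=0, n_permutations=20_000
        )
        assert mc.p_value == pytest.approx(exact.p_value, abs=0.02)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(-50, 50, allow_nan=False),
                st.floats(-50, 50, allow_nan=False),
            ),
            min_size=4,
            max_size=9,
        )
    )
    def test_monotone_invariance_and_antisymmetry(self, data):
        # quantize so monotone transforms stay strictly monotone in floats
        x = np.round([d[0] for d in data], 3)
        y = np.round([d[1] for d in data], 3)
        if np.unique(x).size < 2 or np.unique(y).size < 2:
            return
        base = ca.spearman_coactivation(x, y, p_method="exact")
        warped = ca.spearman_coactivation(np.exp(x / 50), np.arctan(y), p_method="exact")
        assert warped.rho == pytest.approx(base.rho, abs=1e-9)
        assert warped.p_value == pytest.approx(base.p_value, abs=1e-12)
        flipped = ca.spearman_coactivation(x, -y, p_method="exact")
        assert flipped.rho == pytest.approx(-base.rho, abs=1e-9)

    def test_exact_null_p_super_uniform(self):
        """Under the null, exact permutation p-values are super-uniform:
        P(p <= a) <= a, checked by full enumeration at n = 5."""
        n = 5
        x = np.arange(n, dtype=float)
        for a in (0.05, 0.1, 0.25, 0.5):
            below = 0
            perms = list(itertools.permutations(range(n)))
            for perm in perms:
                r = ca.spearman_coactivation(
                    x, np.array(perm, float), p_method="exact"
                )
                if r.p_value <= a:
                    below += 1
            assert below / len(perms) <= a + 1e-12


class TestGeneGeneCorrelation:
    def test_identical_columns(self):
        m = make_matrix(
            [[1, 1, 3], [5, 5, 1], [2, 2, 0], [4, 4, 2]], genes=["Sting1", "Kdr", "Actb"]
        )
        m = ca.normalize(m)
        r = ca.gene_gene_correlation(m, "Sting1", "Kdr")
        assert r.rho == pytest.approx(1.0)
        assert r.signature_x == "gene:Sting1"

    def test_absent_gene_named_in_error(self, small_dataset):
        m, _ = small_dataset
        with pytest.raises(ca.ValidationError, match="Nonexistent1"):
            ca.gene_gene_correlation(m, "Sting1", "Nonexistent1")

    def test_null_gene_pair_ci_covers_zero(self, small_dataset):
        """Two background genes carry no latent: Fisher CI covers 0."""
        m, _ = small_dataset
        bg = [g for g in m.gene_symbols if g.startswith("Gene")][:2]
        r = ca.gene_gene_correlation(m, bg[0], bg[1], p_method="t")
        half = 1.96 / math.sqrt(r.n - 3)
        z = math.atanh(max(min(r.rho, 1 - 1e-9), -1 + 1e-9))
        assert math.tanh(z - half) <= 0.0 <= math.tanh(z + half)


def score_vector(values):
    return ca.ScoreVector(
        signature_name="s",
        values=np.asarray(values, float),
        cell_ids=pd.Index([f"c{i}" for i in range(len(values))]),
        n_genes_used=1,
        coverage=1.0,
    )


def rank_chunk_oracle(values, k):
    """Independent oracle: stable rank order then contiguous chunks."""
    order = sorted(range(len(values)), key=lambda i: (values[i], i))
    sizes = [len(values) // k + (1 if i < len(values) % k else 0) for i in range(k)]
    labels = [None] * len(values)
    names = ["low", "mid", "high"] if k == 3 else [f"q{i+1}" for i in range(k)]
    pos = 0
    for name, s in zip(names, sizes):
        for i in order[pos : pos + s]:
            labels[i] = name
        pos += s
    return labels


class TestStratifyByScore:
    def test_nine_distinct_scores(self):
        sv = score_vector([9, 1, 5, 3, 7, 2, 8, 4, 6])
        strata = ca.stratify_by_score(sv, k=3)
        sizes = strata.group_labels.value_counts()
        assert sizes["low"] == sizes["mid"] == sizes["high"] == 3
        assert set(strata.group_labels[sv.values <= 3]) == {"low"}

    def test_all_ties_sizes_balanced(self):
        sv = score_vector([2.0] * 10)
        strata = ca.stratify_by_score(sv, k=3)
        sizes = strata.group_labels.value_counts()
        assert max(sizes) - min(sizes) <= 1
        assert strata.group_labels.tolist() == rank_chunk_oracle(sv.values, 3)

    def test_matches_rank_chunk_oracle_random(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(3, 40))
            vals = rng.integers(0, 5, size=n).astype(float)
            sv = score_vector(vals)
            assert ca.stratify_by_score(sv, 3).group_labels.tolist() == (
                rank_chunk_oracle(vals, 3)
            )

    def test_rank_invariance_under_monotone_relabeling(self):
        vals = np.array([0.3, 1.2, -4.0, 2.2, 0.0, 5.1])
        a = ca.stratify_by_score(score_vector(vals), 3).group_labels
        b = ca.stratify_by_score(score_vector(np.exp(vals)), 3).group_labels
        assert (a == b).all()

    def test_k_below_two_rejected(self):
        with pytest.raises(ca.ValidationError):
            ca.stratify_by_score(score_vector([1, 2, 3]), k=1)


class TestContrastAcrossStrata:
    def test_constant_other_scores(self):
        strata = ca.stratify_by_score(score_vector(np.arange(9.0)), 3)
        contrast = ca.contrast_across_strata(strata, score_vector([5.0] * 9))
        assert (contrast.table["p_value"] == 1.0).all()
        assert contrast.trend_statistic == pytest.approx(contrast.trend_null_mean)

    def test_self_contrast_is_maximal_trend(self):
        vals = score_vector(np.arange(12.0))
        strata = ca.stratify_by_score(vals, 3)
        contrast = ca.contrast_across_strata(strata, vals)
        # every cross-stratum pair is increasing: JT at its maximum
        assert contrast.trend_statistic == pytest.approx(3 * (4 * 4))
        medians = {
            r["group_a"]: r["median_a"] for _, r in contrast.table.iterrows()
        }
        assert medians["low"] < medians["mid"]

    def test_coactivated_scores_trend_up(self, small_dataset, panel, signatures):
        m, _ = small_dataset  # generator rho = 0.6
        ec = ca.select_endothelial(m, ca.annotate_cells(m, panel))
        sx = ca.score_signature(ec, signatures["cGAS-STING"])
        sy = ca.score_signature(ec, signatures["Angiogenesis"])
        strata = ca.stratify_by_score(sx, 3)
        contrast = ca.contrast_across_strata(strata, sy)
        med = {
            name: np.median(sy.values[(strata.group_labels == name).to_numpy()])
            for name in strata.group_order
        }
        assert med["low"] < med["high"]
        assert contrast.trend_p < 0.05


class TestHighLowGeneContrast:
    def test_halves_split_covers_all_cells(self, small_dataset):
        m, _ = small_dataset
        hl = ca.high_low_gene_contrast(m, "Sting1", "Kdr", mode="halves")
        assert hl.stratifier == "gene:Sting1"
        assert hl.n_high + hl.n_low == m.n_cells

    def test_target_only_in_high_group(self):
        # Actb keeps library sizes comparable so the contrast reflects Kdr
        genes = ["Sting1", "Kdr", "Actb"]
        counts = np.array(
            [[9, 7, 100], [8, 5, 100], [1, 0, 100], [0, 0, 100], [1, 0, 100], [0, 0, 100]]
        )
        m = ca.normalize(make_matrix(counts, genes=genes))
        hl = ca.high_low_gene_contrast(m, "Sting1", "Kdr", mode="halves")
        assert hl.log2_fc > 0

    def test_constant_target_fc_zero(self):
        genes = ["Sting1", "Kdr"]
        counts = np.array([[9, 3], [5, 3], [1, 3], [0, 3]])
        m = ca.normalize(make_matrix(counts, genes=genes))
        hl = ca.high_low_gene_contrast(m, "Sting1", "Kdr", mode="halves")
        # normalization rescales per cell, so compare on counts layer
        hl_counts = ca.high_low_gene_contrast(
            m, "Sting1", "Kdr", mode="halves", layer="counts"
        )
        assert hl_counts.log2_fc == pytest.approx(0.0, abs=1e-9)

    def test_loaded_target_up_in_high_stratum(self, small_dataset, panel, signatures):
        """Kdr loads on the angiogenesis latent; at generator rho = 0.6 the
        innate-immune-high ECs should show elevated Kdr."""
        m, _ = small_dataset
        ec = ca.select_endothelial(m, ca.annotate_cells(m, panel))
        hl = ca.high_low_gene_contrast(
            m=ec, stratifier=signatures["cGAS-STING"], target_gene="Kdr",
            mode="tertile-extremes",
        )
        assert hl.log2_fc > 0
        assert hl.test_p < 0.05
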