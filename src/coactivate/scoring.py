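"""Signature scoring and enrichment statistics.

The per-cell signature score is the sum (optionally mean) of the chosen
expression layer over the signature's genes — the additive score used
throughout the co-activation analyses.  Enrichment is offered in two
flavours, mirroring the two readings of "KS enrichment" in this
literature:

* :func:`ks_enrichment` — the two-sample Kolmogorov–Smirnov test between
  score distributions of two cell groups (group comparisons such as
  stage-wise or stratum-wise contrasts);
* :func:`gsea_es` — the GSEA weighted running-sum enrichment score over a
  ranked gene list, with a gene-label permutation null giving a nominal
  p-value and a normalized enrichment score (NES).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    ExpressionMatrix,
    GeneSignature,
    MissingSignatureError,
    ValidationError,
)
from .harmonize import resolve_to_matrix

logger = logging.getLogger(__name__)


@dataclass
class ScoreVector:
    """Per-cell scores for one signature, with coverage metadata."""

    signature_name: str
    values: np.ndarray
    cell_ids: pd.Index
    n_genes_used: int
    coverage: float
    layer: str = "norm"
    scale: str = "sum"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("score values must be finite")
        if not (0 < self.coverage <= 1):
            raise ValidationError("coverage must be in (0, 1]")
        if len(self.values) != len(self.cell_ids):
            raise ValidationError("values and cell_ids misaligned")

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell": self.cell_ids,
                "signature": self.signature_name,
                "score": self.values,
                "coverage": self.coverage,
            }
        )


@dataclass
class EnrichmentResult:
    """An enrichment statistic with its p-value and provenance."""

    statistic: float
    p_value: float
    side: str = "two-sided"
    nes: float | None = None
    n_permutations: int = 0
    seed: int | None = None
    method: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise ValidationError("p_value outside [0, 1]")


def score_signature(
    m: ExpressionMatrix,
    sig: GeneSignature,
    layer: Literal["norm", "counts"] = "norm",
    scale: Literal["sum", "mean"] = "sum",
) -> ScoreVector:
    """Additive per-cell signature score over the genes found in the matrix.

    Signature symbols are harmonized to the matrix species before
    matching; genes absent from the matrix reduce ``coverage`` and are
    logged, but do not error unless the overlap is empty.
    """
    if scale not in ("sum", "mean"):
        raise ValidationError(f"unknown scale {scale!r}")
    matrix_species = (
        str(m.gene_meta["species"].iloc[0]) if "species" in m.gene_meta else "mouse"
    )
    mapping = resolve_to_matrix(sig.genes, sig.species, m.gene_symbols, matrix_species)
    if not mapping:
        raise MissingSignatureError(
            f"no gene of signature {sig.name!r} found in the matrix"
        )
    missing = [g for g in sig.genes if g not in mapping]
    if missing:
        logger.warning(
            "signature %s: %d/%d genes absent from matrix: %s",
            sig.name, len(missing), len(sig.genes), missing[:10],
        )
    cols = m.gene_meta.index.get_indexer(list(mapping.values()))
    sub = m.layer(layer)[:, cols]
    values = np.asarray(sub.sum(axis=1)).ravel().astype(float)
    n_used = len(cols)
    if scale == "mean":
        values = values / n_used
    return ScoreVector(
        signature_name=sig.name,
        values=values,
        cell_ids=m.cell_ids,
        n_genes_used=n_used,
        coverage=n_used / len(sig.genes),
        layer=layer,
        scale=scale,
    )


def _as_values(x) -> np.ndarray:
    if isinstance(x, ScoreVector):
        return x.values
    return np.asarray(x, dtype=float)


def ks_enrichment(
    scores_a,
    scores_b,
    side: Literal["two-sided", "greater", "less"] = "two-sided",
    exact_limit: int = 10_000,
) -> EnrichmentResult:
    """Two-sample Kolmogorov–Smirnov comparison of score distributions.

    The exact small-sample p-value is used when ``n_a * n_b`` does not
    exceed ``exact_limit`` and the pooled data are tie-free (with ties the
    continuous-case exact distribution is not the conditional permutation
    law, so the asymptotic Kolmogorov form is used instead).
    """
    a = _as_values(scores_a)
    b = _as_values(scores_b)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    exact = (a.size * b.size <= exact_limit) and not has_ties
    method = "exact" if exact else "asymp"
    res = stats.ks_2samp(a, b, alternative=side, method=method)
    return EnrichmentResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        side=side,
        method=f"ks-{method}",
    )


def _running_sum_es(hit_mask: np.ndarray, weights: np.ndarray) -> float:
    """Signed maximal deviation of the GSEA running sum.

    ``weights`` are the (already |score|^p) ranking weights aligned with
    the ranked list; hits increment by weight normalized to 1 in total,
    misses decrement by 1/(N - N_h).
    """
    n = hit_mask.size
    n_hit = int(hit_mask.sum())
    hit_w = weights * hit_mask
    total = hit_w.sum()
    if total == 0:
        # all hit weights zero (e.g. zero ranking scores with p=1): fall
        # back to unweighted hits so the statistic stays defined
        hit_w = hit_mask.astype(float)
        total = hit_w.sum()
    step = hit_w / total - (~hit_mask.astype(bool)).astype(float) / (n - n_hit)
    running = np.cumsum(step)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def gsea_es(
    ranking_genes: Sequence[str],
    ranking_scores: Sequence[float],
    gene_set: GeneSignature,
    weight_p: int = 0,
    n_permutations: int = 1000,
    seed: int | None = 0,
) -> EnrichmentResult:
    """GSEA enrichment score with a gene-label permutation null.

    The ranked list is ordered by descending ranking score (ties broken by
    stable input order).  ``weight_p=0`` gives the classic unweighted
    KS-style running sum; ``weight_p=1`` weights hit increments by
    |ranking score|.  The nominal p-value and NES are computed against
    permutations of gene labels (random hit positions), restricted to
    null scores of the observed sign, with the add-one estimator.
    """
    genes = list(ranking_genes)
    scores = np.asarray(ranking_scores, dtype=float)
    if len(genes) != scores.size:
        raise ValidationError("ranking genes and scores misaligned")
    if weight_p not in (0, 1):
        raise ValidationError("weight_p must be 0 or 1")
    order = np.argsort(-scores, kind="stable")
    ranked = [genes[i] for i in order]
    ranked_scores = scores[order]
    members = set(gene_set.genes)
    hit_mask = np.array([g in members for g in ranked], dtype=bool)
    n_hit = int(hit_mask.sum())
    if n_hit == 0:
        raise MissingSignatureError(
            f"gene set {gene_set.name!r} has no overlap with the ranking"
        )
    if n_hit == len(ranked):
        raise ValidationError(
            "gene set covers the entire ranking (miss denominator is zero)"
        )
    weights = np.abs(ranked_scores) ** weight_p
    es = _running_sum_es(hit_mask, weights)

    nes = None
    p_value = 1.0
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        null = np.empty(n_permutations)
        n = len(ranked)
        for b in range(n_permutations):
            perm_hits = np.zeros(n, dtype=bool)
            perm_hits[rng.choice(n, size=n_hit, replace=False)] = True
            null[b] = _running_sum_es(perm_hits, weights)
        same_sign = null >= 0 if es >= 0 else null <= 0
        n_same = int(same_sign.sum())
        n_extreme = int(np.sum(np.abs(null[same_sign]) >= abs(es)))
        p_value = (1 + n_extreme) / (1 + n_same)
        denom = np.mean(np.abs(null[same_sign])) if n_same else np.mean(np.abs(null))
        nes = float(es / denom) if denom > 0 else 0.0
    return EnrichmentResult(
        statistic=float(es),
        p_value=float(p_value),
        side="two-sided",
        nes=nes,
        n_permutations=n_permutations,
        seed=seed,
        method=f"gsea-perm-p{weight_p}",
    )


def summarize_by_group(scores: ScoreVector, groups) -> pd.DataFrame:
    """Per-group summary of a score vector.

    Returns one row per group (order of first appearance) with n, mean,
    median, total and ``normalized_n`` = n / max group size, so the
    largest group is exactly 1.0.
    """
    g = pd.Series(np.asarray(groups), index=scores.cell_ids, name="group")
    if len(g) != len(scores):
        raise ValidationError("groups not aligned with scores")
    df = pd.DataFrame({"score": scores.values, "group": g.to_numpy()})
    order = pd.unique(df["group"])
    agg = (
        df.groupby("group", sort=False)["score"]
        .agg(n="size", mean="mean", median="median", total="sum")
        .reindex(order)
        .reset_index()
    )
    agg["normalized_n"] = agg["n"] / agg["n"].max()
    return agg
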