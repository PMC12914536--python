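"""Pathway co-activation statistics.

The headline analysis: Spearman rank correlation between two signatures'
per-cell scores on a cell subset (co-activation), plus activity
stratification into low/mid/high tertiles with rank-based differential
contrasts, and high-vs-low single-gene fold-change contrasts.

p-values for the Spearman test come from one of three routes:

* ``exact`` — full enumeration of all n! rank permutations (n <= 9);
* ``permutation`` — seeded Monte-Carlo permutation;
* ``t`` — the usual t-approximation (scipy's default).

``auto`` picks exact for n <= 9 and the t-approximation otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionMatrix, GeneSignature, ValidationError
from .scoring import ScoreVector, score_signature

EXACT_N_MAX = 9


@dataclass
class CoactivationResult:
    """Spearman co-activation between two score vectors on one subset."""

    signature_x: str
    signature_y: str
    subset: str
    n: int
    rho: float
    p_value: float
    p_method: str
    seed: int | None = None

    def __post_init__(self) -> None:
        if not -1 - 1e-12 <= self.rho <= 1 + 1e-12:
            raise ValidationError("rho outside [-1, 1]")
        if self.n < 3:
            raise ValidationError("n >= 3 required to report a p-value")

    def to_dict(self) -> dict:
        return {
            "signature_x": self.signature_x,
            "signature_y": self.signature_y,
            "subset": self.subset,
            "n": self.n,
            "rho": self.rho,
            "p_value": self.p_value,
            "p_method": self.p_method,
            "seed": self.seed,
        }


@dataclass
class StratificationResult:
    """Low/mid/high (or k-quantile) partition of cells by a score."""

    group_labels: pd.Series  # per-cell stratum name
    boundaries: tuple[float, ...]  # k-1 empirical cutpoints
    group_order: tuple[str, ...]
    stratifier: str

    def cells_in(self, group: str) -> pd.Index:
        return self.group_labels.index[self.group_labels == group]


@dataclass
class StrataContrast:
    """Pairwise rank-sum tests plus an ordered-trend statistic."""

    table: pd.DataFrame  # columns: group_a, group_b, statistic, p_value
    trend_statistic: float
    trend_null_mean: float
    trend_p: float
    test_family: str = "mann-whitney + jonckheere-terpstra"


@dataclass
class HighLowContrast:
    """Fold change of one gene between high and low strata of a score."""

    gene: str
    stratifier: str
    mode: str
    log2_fc: float
    test_p: float
    n_high: int
    n_low: int
    epsilon: float


# ---------------------------------------------------------------------------
# Spearman machinery
# ---------------------------------------------------------------------------

@lru_cache(maxsize=EXACT_N_MAX + 1)
def _all_perms(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.int64)


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise ValidationError("Spearman rho undefined for a constant vector")
    return float(rx @ ry) / denom


def _exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided p by full enumeration of rank permutations (midrank ties)."""
    n = x.size
    if n > EXACT_N_MAX:
        raise ValidationError(f"exact enumeration limited to n <= {EXACT_N_MAX}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    perms = _all_perms(n)
    rho_null = (ryc[perms] @ rxc) / denom
    return float(np.mean(np.abs(rho_null) >= abs(rho) - 1e-12))


def _mc_p(
    x: np.ndarray, y: np.ndarray, rho: float, n_permutations: int, seed: int | None
) -> float:
    rng = np.random.default_rng(seed)
    rxc = stats.rankdata(x)
    ryc = stats.rankdata(y)
    rxc = rxc - rxc.mean()
    ryc = ryc - ryc.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(y.size)
        if abs(float(ryc[perm] @ rxc) / denom) >= abs(rho) - 1e-12:
            count += 1
    return (1 + count) / (1 + n_permutations)


def spearman_coactivation(
    x: ScoreVector | Sequence[float],
    y: ScoreVector | Sequence[float],
    p_method: Literal["auto", "exact", "permutation", "t"] = "auto",
    seed: int | None = None,
    n_permutations: int = 10_000,
    subset: str = "",
) -> CoactivationResult:
    """Spearman correlation and test between two aligned score vectors."""
    name_x = x.signature_name if isinstance(x, ScoreVector) else "x"
    name_y = y.signature_name if isinstance(y, ScoreVector) else "y"
    if isinstance(x, ScoreVector) and isinstance(y, ScoreVector):
        if not x.cell_ids.equals(y.cell_ids):
            raise ValidationError("score vectors are not aligned on the same cells")
    xv = np.asarray(x.values if isinstance(x, ScoreVector) else x, dtype=float)
    yv = np.asarray(y.values if isinstance(y, ScoreVector) else y, dtype=float)
    if xv.size != yv.size:
        raise ValidationError("x and y differ in length")
    n = xv.size
    if n < 3:
        raise ValidationError("need n >= 3")
    rho = _spearman_rho(xv, yv)

    if p_method == "auto":
        p_method = "exact" if n <= EXACT_N_MAX else "t"
    if p_method == "exact":
        p = _exact_p(xv, yv, rho)
    elif p_method == "permutation":
        p = _mc_p(xv, yv, rho, n_permutations, seed)
    elif p_method == "t":
        p = float(stats.spearmanr(xv, yv).pvalue)
    else:
        raise ValidationError(f"unknown p_method {p_method!r}")
    return CoactivationResult(
        signature_x=name_x,
        signature_y=name_y,
        subset=subset,
        n=n,
        rho=rho,
        p_value=min(p, 1.0),
        p_method=p_method,
        seed=seed if p_method == "permutation" else None,
    )


def gene_gene_correlation(
    m: ExpressionMatrix,
    gene_a: str,
    gene_b: str,
    subset=None,
    layer: str = "norm",
    p_method: str = "auto",
    seed: int | None = None,
) -> CoactivationResult:
    """Spearman correlation between two single genes' expression vectors."""
    sub = m if subset is None else m.subset_cells(subset)
    va = sub.gene_vector(gene_a, layer=layer)
    vb = sub.gene_vector(gene_b, layer=layer)
    res = spearman_coactivation(
        va, vb, p_method=p_method, seed=seed,
        subset="all cells" if subset is None else "subset",
    )
    res.signature_x = f"gene:{gene_a}"
    res.signature_y = f"gene:{gene_b}"
    return res


# ---------------------------------------------------------------------------
# stratification and contrasts
# ---------------------------------------------------------------------------

def _strata_names(k: int) -> tuple[str, ...]:
    if k == 2:
        return ("low", "high")
    if k == 3:
        return ("low", "mid", "high")
    return tuple(f"q{i + 1}" for i in range(k))


def stratify_by_score(scores: ScoreVector, k: int = 3) -> StratificationResult:
    """Partition cells into k ordered groups by empirical score quantiles.

    Ties at a boundary are resolved by stable rank order (boundary cells
    fill the lower stratum first), so group sizes always differ by at
    most one regardless of ties.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    n = len(scores)
    if n < k:
        raise ValidationError(f"need at least k={k} cells, got {n}")
    order = np.argsort(scores.values, kind="stable")
    chunks = np.array_split(order, k)
    names = _strata_names(k)
    labels = np.empty(n, dtype=object)
    for name, chunk in zip(names, chunks):
        labels[chunk] = name
    boundaries = tuple(
        float(scores.values[chunks[i][-1]]) for i in range(k - 1)
    )
    return StratificationResult(
        group_labels=pd.Series(labels, index=scores.cell_ids, name="stratum"),
        boundaries=boundaries,
        group_order=names,
        stratifier=scores.signature_name,
    )


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(a.size * b.size / 2), 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def _jonckheere(groups: list[np.ndarray]) -> tuple[float, float, float]:
    """Jonckheere–Terpstra test for an ordered (increasing) alternative.

    Returns (JT statistic, null mean, one-sided p).  Ties between pairs
    count 1/2.  Normal approximation with the no-tie variance; a fully
    constant input returns the null mean with p = 0.5.
    """
    jt = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            less = np.sum(a[:, None] < b[None, :])
            ties = np.sum(a[:, None] == b[None, :])
            jt += float(less) + 0.5 * float(ties)
    sizes = np.array([g.size for g in groups], dtype=float)
    n = sizes.sum()
    mean = (n**2 - np.sum(sizes**2)) / 4.0
    var = (n**2 * (2 * n + 3) - np.sum(sizes**2 * (2 * sizes + 3))) / 72.0
    if var <= 0:
        return jt, mean, 0.5
    z = (jt - mean) / math.sqrt(var)
    p = float(stats.norm.sf(z))
    return jt, mean, p


def contrast_across_strata(
    strata: StratificationResult, other_scores: ScoreVector
) -> StrataContrast:
    """Pairwise rank-sum tests of a second score across ordered strata,
    plus a Jonckheere–Terpstra increasing-trend test."""
    if not strata.group_labels.index.equals(other_scores.cell_ids):
        raise ValidationError("strata and scores are not aligned")
    groups = []
    for name in strata.group_order:
        mask = (strata.group_labels == name).to_numpy()
        if mask.sum() == 0:
            raise ValidationError(f"stratum {name!r} is empty")
        groups.append(other_scores.values[mask])
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            u, p = _ranksum_p(groups[i], groups[j])
            rows.append(
                {
                    "group_a": strata.group_order[i],
                    "group_b": strata.group_order[j],
                    "statistic": u,
                    "p_value": p,
                    "median_a": float(np.median(groups[i])),
                    "median_b": float(np.median(groups[j])),
                }
            )
    jt, jt_mean, jt_p = _jonckheere(groups)
    return StrataContrast(
        table=pd.DataFrame(rows),
        trend_statistic=jt,
        trend_null_mean=jt_mean,
        trend_p=jt_p,
    )


def high_low_gene_contrast(
    m: ExpressionMatrix,
    stratifier: GeneSignature | str,
    target_gene: str,
    mode: Literal["halves", "tertile-extremes"] = "halves",
    layer: str = "norm",
    epsilon: float = 1e-9,
) -> HighLowContrast:
    """Fold change of ``target_gene`` between cells high vs low in a
    stratifying signature or single gene.

    ``halves`` splits at the score median (stable rank order); the
    ``tertile-extremes`` mode contrasts the top vs bottom tertile.
    log2 fold change is computed on group means of the chosen layer with
    pseudocount ``epsilon``; the p-value is a two-sided rank-sum test.
    """
    if isinstance(stratifier, GeneSignature):
        sv = score_signature(m, stratifier, layer=layer)
        strat_name = stratifier.name
    else:
        vals = m.gene_vector(stratifier, layer=layer)
        sv = ScoreVector(
            signature_name=f"gene:{stratifier}",
            values=vals,
            cell_ids=m.cell_ids,
            n_genes_used=1,
            coverage=1.0,
            layer=layer,
        )
        strat_name = f"gene:{stratifier}"
    k = 2 if mode == "halves" else 3
    if mode not in ("halves", "tertile-extremes"):
        raise ValidationError(f"unknown mode {mode!r}")
    strata = stratify_by_score(sv, k=k)
    target = m.gene_vector(target_gene, layer=layer)
    low_mask = (strata.group_labels == "low").to_numpy()
    high_mask = (strata.group_labels == "high").to_numpy()
    lo, hi = target[low_mask], target[high_mask]
    if lo.size == 0 or hi.size == 0:
        raise ValidationError("empty high or low group")
    log2_fc = float(np.log2((hi.mean() + epsilon) / (lo.mean() + epsilon)))
    _, p = _ranksum_p(hi, lo)
    return HighLowContrast(
        gene=target_gene,
        stratifier=strat_name,
        mode=mode,
        log2_fc=log2_fc,
        test_p=p,
        n_high=int(hi.size),
        n_low=int(lo.size),
        epsilon=epsilon,
    )
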