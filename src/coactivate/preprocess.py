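"""Library-size normalization and gene-detection filtering."""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import sparse

from .datamodel import ExpressionMatrix, NormalizationConfig, ValidationError

logger = logging.getLogger(__name__)


def normalize(
    m: ExpressionMatrix, cfg: NormalizationConfig | None = None
) -> ExpressionMatrix:
    """Attach the log-normalized layer: log(pc + counts * target_sum / total).

    Always recomputed from counts, so re-normalizing is idempotent and the
    layer is reproducible from ``counts`` plus the recorded config.  Cells
    with zero total counts are refused (their scale factor is undefined).
    """
    cfg = cfg or NormalizationConfig()
    totals = np.asarray(m.counts.sum(axis=1)).ravel()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        ids = list(m.cell_ids[zero[:10]])
        raise ValidationError(f"cells with zero total counts: {ids}")
    scaled = sparse.csr_matrix(m.counts, dtype=np.float64)
    scale = cfg.target_sum / totals
    scaled = sparse.diags(scale) @ scaled
    norm = scaled.tocsr()
    # log(pc + x) - log(pc) keeps zeros sparse; for pc=1 this is log1p(x).
    norm.data = np.log(cfg.pseudocount + norm.data) - np.log(cfg.pseudocount)
    out = m.copy()
    out.norm = norm
    out.norm_config = cfg
    return out


def detect_genes(
    m: ExpressionMatrix,
    expr_threshold: float = 0.1,
    min_cells: int = 10,
    layer: str = "norm",
) -> pd.Index:
    """Genes expressed above ``expr_threshold`` in strictly more than
    ``min_cells`` cells (both inequalities strict).

    Defaults (0.1, 10) follow the standard trajectory-analysis feature
    filter for single-cell data.
    """
    if expr_threshold < 0:
        raise ValidationError("expr_threshold must be non-negative")
    if min_cells < 0:
        raise ValidationError("min_cells must be non-negative")
    coo = m.layer(layer).tocoo()
    above = coo.data > expr_threshold
    n_above = np.bincount(coo.col[above], minlength=m.n_genes)
    keep = n_above > min_cells
    kept = m.gene_symbols[keep]
    if len(kept) == 0:
        warnings.warn("detect_genes: no genes passed the filter", stacklevel=2)
    logger.info("detect_genes kept %d / %d genes", len(kept), m.n_genes)
    return kept
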