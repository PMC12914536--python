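"""Marker-based cell-type annotation and angiogenic-EC calling.

Cells are labeled directly by marker argmax: each cell gets the panel
cell type whose markers have the highest mean normalized expression.
Cluster-level annotation (the usual practice) is recovered by majority
vote when a clustering is supplied in ``cell_meta``.  Angiogenic
endothelial cells are called from the additive activation-marker score
(Mki67/Cxcr4/Dll4/Aplnr/Esm1 by default), either above a fixed score
threshold or above a quantile of the EC score distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    ExpressionMatrix,
    GeneSignature,
    MarkerSet,
    MissingSignatureError,
    ValidationError,
    validate_panel,
)
from .harmonize import resolve_to_matrix
from .scoring import ScoreVector, score_signature

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class AnnotationResult:
    """Per-cell labels with the argmax margin and the panel used."""

    labels: pd.Series
    margin: pd.Series
    panel: tuple[MarkerSet, ...]

    def counts(self) -> pd.Series:
        return self.labels.value_counts()


@dataclass
class AngiogenicCall:
    """Per-EC angiogenic flag with the activation-score evidence."""

    is_angiogenic: pd.Series
    evidence: ScoreVector
    method: str
    cutoff: float

    @property
    def n_angiogenic(self) -> int:
        return int(self.is_angiogenic.sum())


def annotate_cells(
    m: ExpressionMatrix,
    panel: Sequence[MarkerSet],
    min_margin: float = 0.0,
    layer: str = "norm",
) -> AnnotationResult:
    """Label each cell by the panel with the highest mean marker expression.

    The margin is the difference between the best and second-best panel
    score; cells with margin below ``min_margin`` — including exact ties —
    are labeled ``"unassigned"``.
    """
    validate_panel(panel)
    if min_margin < 0:
        raise ValidationError("min_margin must be >= 0")
    matrix_species = (
        str(m.gene_meta["species"].iloc[0]) if "species" in m.gene_meta else "mouse"
    )
    scores = np.zeros((m.n_cells, len(panel)))
    mat = m.layer(layer)
    for j, ms in enumerate(panel):
        mapping = resolve_to_matrix(
            ms.markers, matrix_species, m.gene_symbols, matrix_species
        )
        if not mapping:
            logger.warning("no markers of %s present in matrix", ms.cell_type)
            scores[:, j] = -np.inf
            continue
        missing = [g for g in ms.markers if g not in mapping]
        if missing:
            logger.warning("markers of %s absent: %s", ms.cell_type, missing)
        cols = m.gene_meta.index.get_indexer(list(mapping.values()))
        scores[:, j] = np.asarray(mat[:, cols].mean(axis=1)).ravel()
    if np.all(np.isneginf(scores)):
        raise MissingSignatureError("no panel markers present in the matrix")

    order = np.argsort(-scores, axis=1, kind="stable")
    best = scores[np.arange(m.n_cells), order[:, 0]]
    second = (
        scores[np.arange(m.n_cells), order[:, 1]]
        if len(panel) > 1
        else np.full(m.n_cells, -np.inf)
    )
    margin = best - second
    margin[~np.isfinite(margin)] = np.inf  # single-set panel: unambiguous
    types = np.array([ms.cell_type for ms in panel], dtype=object)
    labels = types[order[:, 0]].copy()
    labels[(margin < min_margin) | (margin == 0)] = UNASSIGNED
    return AnnotationResult(
        labels=pd.Series(labels, index=m.cell_ids, name="cell_type"),
        margin=pd.Series(np.maximum(margin, 0), index=m.cell_ids, name="margin"),
        panel=tuple(panel),
    )


def select_endothelial(
    m: ExpressionMatrix, annotation: AnnotationResult, label: str = "EC"
) -> ExpressionMatrix:
    """Subset to the cells annotated as endothelial; metadata preserved."""
    if not annotation.labels.index.equals(m.cell_ids):
        raise ValidationError("annotation is not aligned with the matrix")
    mask = (annotation.labels == label).to_numpy()
    if mask.sum() == 0:
        raise ValidationError(
            f"no cells labeled {label!r}; check that the marker panel matches "
            "the matrix gene symbols"
        )
    return m.subset_cells(mask)


def call_angiogenic(
    ec_matrix: ExpressionMatrix,
    activation_markers: GeneSignature,
    method: Literal["threshold", "quantile"] = "quantile",
    cutoff: float = 0.75,
    layer: str = "norm",
) -> AngiogenicCall:
    """Flag angiogenic ECs by their activation-marker score.

    ``quantile`` mode (default, q = 0.75) calls cells whose score exceeds
    the q-quantile of the EC score distribution, so the angiogenic
    fraction is 1 - q up to ties; ``threshold`` mode compares the score
    to a fixed cutoff.
    """
    evidence = score_signature(ec_matrix, activation_markers, layer=layer)
    if method == "quantile":
        if not 0 < cutoff < 1:
            raise ValidationError("quantile cutoff must be in (0, 1)")
        thr = float(np.quantile(evidence.values, cutoff))
    elif method == "threshold":
        thr = float(cutoff)
    else:
        raise ValidationError(f"unknown method {method!r}")
    flags = evidence.values > thr
    return AngiogenicCall(
        is_angiogenic=pd.Series(flags, index=ec_matrix.cell_ids, name="angiogenic"),
        evidence=evidence,
        method=method,
        cutoff=thr,
    )
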