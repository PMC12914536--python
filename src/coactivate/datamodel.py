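"""Core data containers for signature-scoring analyses.

The central object is :class:`ExpressionMatrix`, a cells-by-genes count
matrix with an optional log-normalized layer and per-cell / per-gene
metadata tables.  It is deliberately lighter than :class:`anndata.AnnData`
(conversion is provided) so that the validation rules the pipeline relies
on — integral non-negative counts, unique harmonized gene symbols, a
reproducible normalized layer — can be enforced at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse


class CoactivateError(Exception):
    """Base class for all package errors."""


class FormatError(CoactivateError):
    """A file did not conform to its declared format."""


class ValidationError(CoactivateError):
    """Input data violated an invariant (negative counts, duplicates, ...)."""


class MissingSignatureError(CoactivateError):
    """No gene of a signature was found in the expression matrix."""


VALID_SPECIES = ("mouse", "human", "pig", "macaque")


@dataclass(frozen=True)
class NormalizationConfig:
    """Library-size normalization settings.

    ``norm = log(1 + counts * target_sum / cell_total)`` with the natural
    log.  Defaults match the de facto single-cell standard (scale each
    cell to 10,000 total counts, then log1p).
    """

    target_sum: float = 10_000.0
    log_base: str = "natural"
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.target_sum <= 0:
            raise ValidationError("target_sum must be positive")
        if self.log_base != "natural":
            raise ValidationError("only the natural log is supported")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")


@dataclass(frozen=True)
class GeneSignature:
    """A named, ordered gene list — the unit of scoring."""

    name: str
    genes: tuple[str, ...]
    species: str = "mouse"
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"signature {self.name!r} has no genes")
        if self.species not in VALID_SPECIES:
            raise ValidationError(f"unknown species {self.species!r}")
        dupes = _duplicates(self.genes)
        if dupes:
            raise ValidationError(
                f"signature {self.name!r} has duplicate genes: {sorted(dupes)}"
            )

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class MarkerSet:
    """Markers defining one cell type within an annotation panel."""

    cell_type: str
    markers: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValidationError(f"marker set {self.cell_type!r} is empty")


def validate_panel(panel: Sequence[MarkerSet]) -> None:
    """A marker may appear in at most one MarkerSet within a panel."""
    if not panel:
        raise ValidationError("marker panel is empty")
    seen: dict[str, str] = {}
    for ms in panel:
        for g in ms.markers:
            if g in seen and seen[g] != ms.cell_type:
                raise ValidationError(
                    f"marker {g!r} appears in both {seen[g]!r} and {ms.cell_type!r}"
                )
            seen[g] = ms.cell_type


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for x in items:
        if x in seen:
            dupes.add(x)
        seen.add(x)
    return dupes


@dataclass
class ExpressionMatrix:
    """Cells-by-genes counts with an optional log-normalized layer.

    Attributes
    ----------
    counts
        Sparse CSR matrix of non-negative integral counts, cells as rows.
    cell_meta
        DataFrame indexed by cell id (columns such as ``cell_type``,
        ``stage``, ``batch`` are optional).
    gene_meta
        DataFrame indexed by gene symbol; carries ``species`` and the
        harmonized ``canonical`` symbol.
    norm
        Log-normalized layer (same shape as ``counts``) or None.
    norm_config
        The :class:`NormalizationConfig` used to compute ``norm``; recorded
        for provenance.  Present iff ``norm`` is present.
    """

    counts: sparse.csr_matrix
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame
    norm: sparse.csr_matrix | None = None
    norm_config: NormalizationConfig | None = None

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        n_cells, n_genes = self.counts.shape
        if n_cells == 0 or n_genes == 0:
            raise ValidationError("empty expression matrix refused")
        data = self.counts.data
        if data.size:
            if not np.all(np.isfinite(data)):
                raise ValidationError("counts contain non-finite entries")
            if np.any(data < 0):
                coo = self.counts.tocoo()
                bad = int(np.argmax(coo.data < 0))
                raise ValidationError(
                    f"negative count at cell {coo.row[bad]}, gene {coo.col[bad]}"
                )
            if np.any(data != np.round(data)):
                coo = self.counts.tocoo()
                bad = int(np.argmax(coo.data != np.round(coo.data)))
                raise ValidationError(
                    f"non-integral count at cell {coo.row[bad]}, gene {coo.col[bad]}"
                )
        if len(self.cell_meta) != n_cells:
            raise ValidationError("cell_meta length does not match counts")
        if len(self.gene_meta) != n_genes:
            raise ValidationError("gene_meta length does not match counts")
        dupes = _duplicates(self.gene_meta.index)
        if dupes:
            raise ValidationError(f"duplicate gene symbols: {sorted(dupes)}")
        if self.cell_meta.index.has_duplicates:
            raise ValidationError("duplicate cell ids")
        if (self.norm is None) != (self.norm_config is None):
            raise ValidationError("norm layer and norm_config must be set together")
        if self.norm is not None and self.norm.shape != self.counts.shape:
            raise ValidationError("norm layer shape mismatch")

    # -- basic introspection -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_ids(self) -> pd.Index:
        return self.cell_meta.index

    @property
    def gene_symbols(self) -> pd.Index:
        return self.gene_meta.index

    @property
    def has_norm(self) -> bool:
        return self.norm is not None

    def layer(self, which: str) -> sparse.csr_matrix:
        """Return the requested layer ('counts' or 'norm')."""
        if which == "counts":
            return self.counts
        if which == "norm":
            if self.norm is None:
                raise ValidationError("norm layer not computed; call normalize() first")
            return self.norm
        raise ValidationError(f"unknown layer {which!r}")

    # -- subsetting ----------------------------------------------------------

    def subset_cells(self, mask_or_ids) -> "ExpressionMatrix":
        """Row-subset by boolean mask or list of cell ids; metadata preserved."""
        if isinstance(mask_or_ids, (list, tuple, pd.Index)) and not (
            len(mask_or_ids) and isinstance(mask_or_ids[0], (bool, np.bool_))
        ):
            idx = self.cell_meta.index.get_indexer(list(mask_or_ids))
            if np.any(idx < 0):
                missing = [c for c, i in zip(mask_or_ids, idx) if i < 0]
                raise ValidationError(f"unknown cell ids: {missing[:5]}")
        else:
            mask = np.asarray(mask_or_ids, dtype=bool)
            if mask.shape != (self.n_cells,):
                raise ValidationError("cell mask length mismatch")
            idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValidationError("cell subset is empty")
        return ExpressionMatrix(
            counts=self.counts[idx],
            cell_meta=self.cell_meta.iloc[idx].copy(),
            gene_meta=self.gene_meta.copy(),
            norm=None if self.norm is None else self.norm[idx],
            norm_config=self.norm_config,
        )

    def subset_genes(self, symbols: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_meta.index.get_indexer(list(symbols))
        if np.any(idx < 0):
            missing = [g for g, i in zip(symbols, idx) if i < 0]
            raise ValidationError(f"unknown genes: {missing[:5]}")
        if idx.size == 0:
            raise ValidationError("gene subset is empty")
        return ExpressionMatrix(
            counts=self.counts[:, idx],
            cell_meta=self.cell_meta.copy(),
            gene_meta=self.gene_meta.iloc[idx].copy(),
            norm=None if self.norm is None else self.norm[:, idx],
            norm_config=self.norm_config,
        )

    def gene_vector(self, symbol: str, layer: str = "norm") -> np.ndarray:
        """Dense per-cell expression of one gene."""
        try:
            j = self.gene_meta.index.get_loc(symbol)
        except KeyError:
            raise ValidationError(f"gene {symbol!r} not in matrix") from None
        return np.asarray(self.layer(layer)[:, j].todense()).ravel()

    # -- interop -------------------------------------------------------------

    def to_anndata(self):
        """Convert to :class:`anndata.AnnData` (counts in X, norm as a layer)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.copy(),
            obs=self.cell_meta.copy(),
            var=self.gene_meta.copy(),
        )
        if self.norm is not None:
            adata.layers["norm"] = self.norm.copy()
        return adata

    def copy(self) -> "ExpressionMatrix":
        return replace(
            self,
            counts=self.counts.copy(),
            cell_meta=self.cell_meta.copy(),
            gene_meta=self.gene_meta.copy(),
            norm=None if self.norm is None else self.norm.copy(),
        )
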