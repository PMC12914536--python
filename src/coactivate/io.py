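"""Readers and writers for expression matrices and gene-set files.

Supported formats
-----------------
* ``mtx_dir`` — a 10x-style bundle: ``matrix.mtx`` (MatrixMarket triplet,
  genes x cells on disk, transposed to cells x rows in memory),
  ``features.tsv``, ``barcodes.tsv``, plus optional ``cell_meta.tsv`` /
  ``gene_meta.tsv`` sidecars carrying metadata columns verbatim.
* ``delimited`` — TSV/CSV with a header row of gene symbols and one row
  per cell (first column = cell id).
* GMT for gene signatures and marker panels.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .datamodel import (
    ExpressionMatrix,
    FormatError,
    GeneSignature,
    MarkerSet,
    ValidationError,
)

logger = logging.getLogger(__name__)

MatrixFormat = Literal["mtx_dir", "delimited"]


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_matrix(path, format: MatrixFormat, species: str = "mouse") -> ExpressionMatrix:
    """Read a count matrix; counts populated, norm layer unset."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"path does not exist: {path}")
    if format == "mtx_dir":
        return _read_mtx_dir(path, species)
    if format == "delimited":
        return _read_delimited(path, species)
    raise ValidationError(f"unknown matrix format {format!r}")


def _read_mtx_dir(path: Path, species: str) -> ExpressionMatrix:
    mtx = path / "matrix.mtx"
    features = path / "features.tsv"
    if not features.exists():
        features = path / "genes.tsv"
    barcodes = path / "barcodes.tsv"
    for f in (mtx, features, barcodes):
        if not f.exists():
            raise FormatError(f"mtx_dir bundle missing {f.name} in {path}")
    try:
        mat = spio.mmread(str(mtx))
    except ValueError as exc:
        raise FormatError(f"malformed MatrixMarket file {mtx}: {exc}") from exc
    # 10x convention stores genes x cells; transpose to cells x genes.
    counts = sparse.csr_matrix(mat).T.tocsr()
    feat = pd.read_csv(features, sep="\t", header=None, dtype=str)
    symbols = feat.iloc[:, 1] if feat.shape[1] >= 2 else feat.iloc[:, 0]
    symbols = pd.Index(symbols.astype(str), name="gene")
    cells = pd.read_csv(barcodes, sep="\t", header=None, dtype=str).iloc[:, 0]
    cells = pd.Index(cells.astype(str), name="cell")
    if counts.shape != (len(cells), len(symbols)):
        raise FormatError(
            f"matrix shape {mat.shape} (genes x cells) does not match "
            f"{len(symbols)} features / {len(cells)} barcodes"
        )
    cell_meta = pd.DataFrame(index=cells)
    gene_meta = pd.DataFrame(index=symbols)
    cm_path = path / "cell_meta.tsv"
    if cm_path.exists():
        cell_meta = pd.read_csv(cm_path, sep="\t", index_col=0).loc[cells]
    gm_path = path / "gene_meta.tsv"
    if gm_path.exists():
        gene_meta = pd.read_csv(gm_path, sep="\t", index_col=0).loc[symbols]
    if "species" not in gene_meta.columns:
        gene_meta["species"] = species
    if "canonical" not in gene_meta.columns:
        from .harmonize import harmonize_genes

        gene_meta["canonical"] = harmonize_genes(symbols, species, species)
    return ExpressionMatrix(counts=counts, cell_meta=cell_meta, gene_meta=gene_meta)


def _read_delimited(path: Path, species: str) -> ExpressionMatrix:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if not header:
        raise FormatError(f"empty header line in {path}")
    cols = header.split(sep)[1:]
    dupes = pd.Index(cols)[pd.Index(cols).duplicated()].unique().tolist()
    if dupes:
        raise ValidationError(f"duplicate gene columns in {path}: {dupes}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"non-numeric entries in {path}")
    bad = np.argwhere(~np.isfinite(values) | (values < 0) | (values != np.round(values)))
    if bad.size:
        r, c = bad[0]
        raise ValidationError(
            f"invalid count at row {df.index[r]!r}, gene {df.columns[c]!r} in {path}"
        )
    counts = sparse.csr_matrix(values.astype(np.int64))
    gene_meta = pd.DataFrame(index=pd.Index(df.columns.astype(str), name="gene"))
    gene_meta["species"] = species
    from .harmonize import harmonize_genes

    gene_meta["canonical"] = harmonize_genes(gene_meta.index, species, species)
    cell_meta = pd.DataFrame(index=pd.Index(df.index.astype(str), name="cell"))
    return ExpressionMatrix(counts=counts, cell_meta=cell_meta, gene_meta=gene_meta)


def write_matrix(m: ExpressionMatrix, path, format: MatrixFormat = "mtx_dir") -> None:
    """Write a matrix such that ``read_matrix`` round-trips it exactly."""
    path = Path(path)
    if format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        coo = sparse.coo_matrix(m.counts.T)  # genes x cells on disk
        spio.mmwrite(str(path / "matrix.mtx"), coo, field="integer")
        feat = pd.DataFrame(
            {0: m.gene_symbols, 1: m.gene_symbols, 2: "Gene Expression"}
        )
        feat.to_csv(path / "features.tsv", sep="\t", header=False, index=False)
        pd.Series(m.cell_ids).to_csv(
            path / "barcodes.tsv", sep="\t", header=False, index=False
        )
        m.cell_meta.to_csv(path / "cell_meta.tsv", sep="\t", index_label="cell")
        m.gene_meta.to_csv(path / "gene_meta.tsv", sep="\t", index_label="gene")
    elif format == "delimited":
        dense = pd.DataFrame(
            m.counts.toarray(), index=m.cell_ids, columns=m.gene_symbols
        )
        dense.to_csv(path, sep="\t", index_label="cell")
    else:
        raise ValidationError(f"unknown matrix format {format!r}")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_signatures(path, species: str = "mouse") -> list[GeneSignature]:
    """Parse a GMT file into GeneSignatures, preserving gene order verbatim.

    GMT lines are ``name<TAB>description<TAB>gene1<TAB>...``.  Symbols are
    kept exactly as written (alias resolution happens when a signature is
    matched to a matrix, not here).
    """
    path = Path(path)
    sigs: list[GeneSignature] = []
    names: set[str] = set()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(
                f"{path} line {lineno}: GMT line needs name, description and >=1 gene"
            )
        name, source = parts[0], parts[1]
        genes = tuple(g for g in parts[2:] if g)
        if not genes:
            raise FormatError(f"{path} line {lineno}: no genes in set {name!r}")
        if name in names:
            raise ValidationError(f"{path}: duplicate signature name {name!r}")
        names.add(name)
        sigs.append(GeneSignature(name=name, genes=genes, species=species, source=source))
    if not sigs:
        raise FormatError(f"{path}: no gene sets found")
    return sigs


def write_signatures(sigs: Sequence[GeneSignature], path) -> None:
    with open(path, "w") as fh:
        for s in sigs:
            fh.write("\t".join([s.name, s.source or "-", *s.genes]) + "\n")


def read_marker_panel(path) -> list[MarkerSet]:
    """Parse a GMT file as a marker panel (one cell type per line)."""
    sigs = read_signatures(path)
    return [MarkerSet(cell_type=s.name, markers=s.genes) for s in sigs]


# ---------------------------------------------------------------------------
# packaged defaults
# ---------------------------------------------------------------------------

def _packaged(name: str) -> Path:
    return Path(str(resources.files("coactivate.data").joinpath(name)))


def default_signatures(species: str = "mouse") -> list[GeneSignature]:
    """The four packaged pathway signatures (mouse symbols)."""
    return read_signatures(_packaged("table1_signatures.gmt"), species=species)


def default_signature(name: str, species: str = "mouse") -> GeneSignature:
    for s in default_signatures(species):
        if s.name == name:
            return s
    raise ValidationError(f"no packaged signature named {name!r}")


def default_marker_panel() -> list[MarkerSet]:
    """Literature-standard retinal marker panel (synthetic assembly, editable)."""
    return read_marker_panel(_packaged("retinal_markers.synthetic.gmt"))
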