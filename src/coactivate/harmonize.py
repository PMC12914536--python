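"""Cross-species gene-symbol harmonization.

Gene lists in this domain mix nomenclature eras and species conventions:
mouse symbols are Title-case (``Kdr``), human/pig/macaque symbols are
upper-case (``KDR``), and several genes are cited under retired aliases
(``Tmem173`` for ``Sting1``, ``Mb21d1`` for ``Cgas``).  Harmonization is a
two-step deterministic map: apply the target species' case convention,
then resolve known aliases from the packaged table.  Symbols without an
alias entry pass through unchanged (cross-species alias tables are
incomplete by nature), with a debug log line rather than a failure.

The case rule capitalizes the first character and lower-cases the rest
for mouse; symbols whose convention genuinely deviates (e.g. MHC locus
genes) need an explicit alias entry.
"""

from __future__ import annotations

import logging
from functools import lru_cache
from importlib import resources
from typing import Iterable, Sequence

from .datamodel import VALID_SPECIES, ValidationError

logger = logging.getLogger(__name__)

_UPPER_SPECIES = {"human", "pig", "macaque"}


@lru_cache(maxsize=1)
def _alias_table() -> dict[str, str]:
    """Packaged alias -> canonical map, stored in mouse Title-case."""
    table: dict[str, str] = {}
    path = resources.files("coactivate.data").joinpath("gene_aliases.tsv")
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"gene_aliases.tsv line {lineno}: expected 2 columns")
        alias, canonical = parts
        table[alias] = canonical
    return table


def _apply_case(symbol: str, species: str) -> str:
    if species in _UPPER_SPECIES:
        return symbol.upper()
    # mouse: Title-case
    return symbol[:1].upper() + symbol[1:].lower()


def harmonize_symbol(symbol: str, from_species: str, to_species: str) -> str:
    """Map one symbol to its canonical form in the target species."""
    for sp in (from_species, to_species):
        if sp not in VALID_SPECIES:
            raise ValidationError(f"unknown species tag {sp!r}")
    cased = _apply_case(symbol, to_species)
    table = _alias_table()
    if to_species in _UPPER_SPECIES:
        table = {a.upper(): c.upper() for a, c in table.items()}
    if cased in table:
        canonical = table[cased]
        logger.debug("alias %s -> %s (%s)", cased, canonical, to_species)
        return canonical
    return cased


def harmonize_genes(
    symbols: Iterable[str], from_species: str, to_species: str
) -> list[str]:
    """Harmonize a list of gene symbols; deterministic and idempotent."""
    return [harmonize_symbol(s, from_species, to_species) for s in symbols]


def resolve_to_matrix(
    signature_genes: Sequence[str],
    signature_species: str,
    matrix_symbols: Sequence[str],
    matrix_species: str,
) -> dict[str, str]:
    """Match signature genes against a matrix's gene symbols.

    Both sides are harmonized to the matrix species; returns a map from
    the signature's original symbol to the matching matrix symbol, for
    the genes that were found.  Order follows the signature.
    """
    canon_matrix = {}
    for sym in matrix_symbols:
        canon = harmonize_symbol(sym, matrix_species, matrix_species)
        canon_matrix.setdefault(canon, sym)
    out: dict[str, str] = {}
    for g in signature_genes:
        canon = harmonize_symbol(g, signature_species, matrix_species)
        if canon in canon_matrix:
            out[g] = canon_matrix[canon]
    return out
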