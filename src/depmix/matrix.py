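"""Core containers for gene-dependency score matrices.

A dependency score quantifies how much a cell line's growth is impaired
when one gene is knocked out (CRISPR) or knocked down (shRNA); more
negative means more essential.  Matrices are always oriented genes x
cell lines, with NaN marking untested conditions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "Source",
    "DependencyMatrix",
    "SampleMeta",
    "parse_gene_token",
    "DepMapFormatError",
]


class DepMapFormatError(ValueError):
    """Raised when an input file does not follow the expected dialect."""


class Source(str, Enum):
    CRISPR = "CRISPR"
    SHRNA = "SHRNA"
    COMBINED = "COMBINED"


_GENE_RE = re.compile(r"^\s*(.*\S)\s*\((\d+)\)\s*$")


def parse_gene_token(token: str) -> tuple[str, int | None]:
    """Split a ``"SYMBOL (EntrezID)"`` header into symbol and Entrez id.

    A bare symbol with no parenthesised integer is accepted (Entrez id
    ``None``); an empty token is a format error.
    """
    m = _GENE_RE.match(token)
    if m:
        return m.group(1), int(m.group(2))
    sym = token.strip()
    if not sym:
        raise DepMapFormatError(f"unparseable gene token: {token!r}")
    return sym, None


@dataclass
class DependencyMatrix:
    """Genes x cell-lines dependency score matrix.

    Parameters
    ----------
    values
        DataFrame indexed by gene label (as read, e.g. ``"KRAS (3845)"``)
        with one column per cell line.  NaN marks missing conditions.
    genes
        DataFrame aligned with ``values.index`` carrying ``symbol`` and
        nullable ``entrez`` columns.
    source
        Which screen produced the scores.  ``theta`` is required (and
        only allowed) for :attr:`Source.COMBINED`.
    line_key
        Identifier space of the columns: ``"depmap_id"`` (canonical) or
        ``"ccle_name"`` (shRNA files before alignment).
    ccle_names
        Optional alias Series (index = columns) retained after mapping
        CCLE names to DepMap ids.
    """

    values: pd.DataFrame
    genes: pd.DataFrame
    source: Source
    theta: float | None = None
    line_key: str = "depmap_id"
    ccle_names: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if list(self.genes.index) != list(self.values.index):
            raise ValueError("genes table must be aligned with values index")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene identifiers: {list(dups)[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate cell-line identifiers: {list(dups)[:5]}")
        if self.source is Source.COMBINED:
            if self.theta is None or not 0.0 <= self.theta <= 1.0:
                raise ValueError("combined matrix requires theta in [0, 1]")
        elif self.theta is not None:
            raise ValueError("theta is only meaningful for combined matrices")
        if self.line_key not in ("depmap_id", "ccle_name"):
            raise ValueError(f"unknown line_key {self.line_key!r}")

    # -- conveniences -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_lines(self) -> int:
        return self.values.shape[1]

    @property
    def cell_lines(self) -> pd.Index:
        return self.values.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean frame, True exactly where the score is undefined."""
        return self.values.isna()

    def gene_keys(self) -> pd.Index:
        """Matching keys across screens: Entrez id when present, else symbol.

        Symbols are ambiguous (renamed, shared between loci); the stable
        numeric id is preferred whenever the file provides one.
        """
        ent = self.genes["entrez"]
        keys = np.where(ent.notna(), "e:" + ent.astype("string").str.replace(
            r"\.0$", "", regex=True), "s:" + self.genes["symbol"].astype(str))
        return pd.Index(keys)

    def copy(self) -> "DependencyMatrix":
        return DependencyMatrix(
            values=self.values.copy(),
            genes=self.genes.copy(),
            source=self.source,
            theta=self.theta,
            line_key=self.line_key,
            ccle_names=None if self.ccle_names is None else self.ccle_names.copy(),
        )

    def restrict(self, genes=None, lines=None) -> "DependencyMatrix":
        """Subset to the given gene labels and/or cell-line ids, preserving order."""
        vals = self.values
        gtab = self.genes
        if genes is not None:
            vals = vals.loc[list(genes)]
            gtab = gtab.loc[list(genes)]
        if lines is not None:
            vals = vals[list(lines)]
        ccle = self.ccle_names
        if ccle is not None and lines is not None:
            ccle = ccle.reindex(vals.columns)
        return DependencyMatrix(vals, gtab, self.source, self.theta,
                                self.line_key, ccle)


@dataclass(frozen=True)
class SampleMeta:
    """One cell line's identifiers: canonical DepMap id, CCLE alias, lineage."""

    depmap_id: str
    ccle_name: str
    lineage: str = ""


def meta_frame(meta: "list[SampleMeta] | pd.DataFrame") -> pd.DataFrame:
    """Normalise metadata to a DataFrame with depmap_id/ccle_name/lineage."""
    if isinstance(meta, pd.DataFrame):
        df = meta.copy()
    else:
        df = pd.DataFrame([(m.depmap_id, m.ccle_name, m.lineage) for m in meta],
                          columns=["depmap_id", "ccle_name", "lineage"])
    if df["depmap_id"].duplicated().any():
        raise ValueError("duplicate DepMap ids in sample metadata")
    both = df.dropna(subset=["depmap_id", "ccle_name"])
    if both["ccle_name"].duplicated().any():
        raise ValueError("CCLE name maps to more than one DepMap id")
    return df
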