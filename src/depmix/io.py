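"""Readers and writers for the DepMap CSV dialects.

Two dialects occur in the wild: the CRISPR/CERES file
(``Achilles_gene_effect.csv``) has cell lines in rows keyed by DepMap_ID
and gene columns headed ``"SYMBOL (EntrezID)"``; the shRNA/DEMETER2 file
(``D2_combined_gene_dep_scores.csv``) has genes in rows and cell-line
columns keyed by CCLE name.  Both are transposed/mapped onto one
canonical genes x cell-lines frame keyed by DepMap id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import (DependencyMatrix, DepMapFormatError, Source, meta_frame,
                     parse_gene_token)

__all__ = [
    "read_crispr_matrix",
    "read_shrna_matrix",
    "read_sample_info",
    "read_combined_matrix",
    "align_screens",
    "AlignmentReport",
    "write_matrix_csv",
    "write_table",
    "read_table",
]

#: Tokens accepted as missing in either dialect.
NA_TOKENS = ["", "NA", "NaN", "nan"]


def _gene_table(labels) -> pd.DataFrame:
    rows = []
    for lab in labels:
        try:
            sym, ent = parse_gene_token(str(lab))
        except DepMapFormatError as err:
            raise DepMapFormatError(f"column/row {lab!r}: {err}") from None
        rows.append((sym, ent))
    tab = pd.DataFrame(rows, columns=["symbol", "entrez"], index=labels)
    tab["entrez"] = tab["entrez"].astype("Int64")
    dup = tab.duplicated(subset=["symbol", "entrez"], keep=False)
    if dup.any():
        raise DepMapFormatError(
            f"duplicate gene identifiers: {sorted(set(tab.index[dup]))[:5]}")
    return tab


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0, na_values=NA_TOKENS,
                       keep_default_na=True)


def read_crispr_matrix(path) -> DependencyMatrix:
    """Read a CERES gene-effect CSV (lines x genes) into canonical orientation."""
    raw = _read_csv(path)
    vals = raw.T  # canonical genes x cell lines
    genes = _gene_table(vals.index)
    vals = vals.astype(float)
    return DependencyMatrix(vals, genes, Source.CRISPR, line_key="depmap_id")


def read_shrna_matrix(path) -> DependencyMatrix:
    """Read a DEMETER2 combined gene-dependency CSV (genes x CCLE-named lines)."""
    vals = _read_csv(path)
    genes = _gene_table(vals.index)
    vals = vals.astype(float)
    return DependencyMatrix(vals, genes, Source.SHRNA, line_key="ccle_name")


def read_sample_info(path) -> pd.DataFrame:
    """Read a ``sample_info.csv`` into a depmap_id/ccle_name/lineage frame."""
    raw = pd.read_csv(path)
    cols = {c.lower(): c for c in raw.columns}

    def pick(*names):
        for n in names:
            if n in cols:
                return raw[cols[n]]
        return pd.Series([np.nan] * len(raw))

    df = pd.DataFrame({
        "depmap_id": pick("depmap_id"),
        "ccle_name": pick("ccle_name", "ccle name", "ccle_id", "stripped_cell_line_name"),
        "lineage": pick("lineage").fillna(""),
    })
    if df["depmap_id"].isna().any():
        raise DepMapFormatError(f"{path}: no DepMap_ID column")
    return meta_frame(df)


def read_combined_matrix(path, theta: float) -> DependencyMatrix:
    """Read a combined-score matrix previously written by :func:`write_matrix_csv`."""
    vals = _read_csv(path).astype(float)
    genes = _gene_table(vals.index)
    return DependencyMatrix(vals, genes, Source.COMBINED, theta=theta)


@dataclass(frozen=True)
class AlignmentReport:
    """Counts of gene/line conditions by missingness class after alignment."""

    n_genes: int
    n_lines: int
    both_tested: int
    crispr_only_tested: int
    shrna_only_tested: int
    untested: int
    dropped_ccle_names: tuple[str, ...] = ()

    @property
    def total(self) -> int:
        return self.n_genes * self.n_lines


def align_screens(crispr: DependencyMatrix, shrna: DependencyMatrix, meta,
                  ) -> tuple[DependencyMatrix, DependencyMatrix, AlignmentReport]:
    """Restrict both screens to shared genes and mapped cell lines.

    Genes are matched on Entrez id when both files provide one, else on
    symbol.  shRNA cell lines (CCLE names) are translated to DepMap ids
    via the metadata; unmappable names are dropped with a warning.  Both
    outputs use identical row and column order, so every downstream
    elementwise operation is well defined.
    """
    mdf = meta_frame(meta)

    # map shRNA columns into DepMap-id space if still CCLE-named
    if shrna.line_key == "ccle_name":
        ccle_to_id = mdf.set_index("ccle_name")["depmap_id"].to_dict()
        mapped = [ccle_to_id.get(c) for c in shrna.values.columns]
        keep = [i for i, m in enumerate(mapped) if m is not None]
        dropped = tuple(str(c) for c, m in zip(shrna.values.columns, mapped)
                        if m is None)
        if dropped:
            warnings.warn(
                f"{len(dropped)} shRNA cell line(s) had no DepMap id and were "
                f"excluded: {list(dropped)[:5]}", stacklevel=2)
        svals = shrna.values.iloc[:, keep]
        aliases = pd.Series(list(svals.columns),
                            index=[mapped[i] for i in keep])
        svals = svals.set_axis(list(aliases.index), axis=1)
        shrna = DependencyMatrix(svals, shrna.genes, shrna.source,
                                 line_key="depmap_id", ccle_names=aliases)
    else:
        dropped = ()

    ckeys, skeys = crispr.gene_keys(), shrna.gene_keys()
    shared = set(ckeys) & set(skeys)
    gene_order = [g for g, k in zip(crispr.values.index, ckeys) if k in shared]
    line_order = [l for l in crispr.values.columns if l in set(shrna.values.columns)]
    if not gene_order or not line_order:
        raise ValueError("no shared genes or cell lines between the screens")

    skey_to_label = dict(zip(skeys, shrna.values.index))
    ckey_by_label = dict(zip(crispr.values.index, ckeys))
    shrna_gene_order = [skey_to_label[ckey_by_label[g]] for g in gene_order]

    ca = crispr.restrict(genes=gene_order, lines=line_order)
    sa = shrna.restrict(genes=shrna_gene_order, lines=line_order)
    # carry the crispr gene labels so both frames index identically
    sa = DependencyMatrix(sa.values.set_axis(gene_order),
                          ca.genes.copy(), sa.source,
                          line_key="depmap_id", ccle_names=sa.ccle_names)

    cmiss = ca.values.isna().to_numpy()
    smiss = sa.values.isna().to_numpy()
    report = AlignmentReport(
        n_genes=len(gene_order), n_lines=len(line_order),
        both_tested=int((~cmiss & ~smiss).sum()),
        crispr_only_tested=int((~cmiss & smiss).sum()),
        shrna_only_tested=int((cmiss & ~smiss).sum()),
        untested=int((cmiss & smiss).sum()),
        dropped_ccle_names=dropped,
    )
    return ca, sa, report


def write_matrix_csv(matrix: DependencyMatrix, path) -> None:
    """Write a matrix in the dialect of its source.

    CRISPR matrices are transposed back to lines x genes (Achilles
    layout); shRNA and combined matrices stay genes x lines.
    """
    if matrix.source is Source.CRISPR:
        out = matrix.values.T
        out.index.name = "DepMap_ID"
    else:
        out = matrix.values.copy()
        out.index.name = "gene"
    out.to_csv(path)


def write_table(table: pd.DataFrame, path, index_label: str = "gene") -> None:
    """Write a per-gene result table as TSV, preserving input row order."""
    table.to_csv(path, sep="\t", index_label=index_label)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
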