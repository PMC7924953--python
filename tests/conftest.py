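import numpy as np
import pandas as pd
import pytest

from depmix import (DependencyMatrix, Source, SyntheticSpec, align_screens,
                    combine_scores, default_screen_spec, fit_threshold,
                    generate_paired_screens, impute_cross_method,
                    sample_info_table)


def small_matrix(values, source=Source.CRISPR, theta=None, lines=None):
    """Build a DependencyMatrix from a plain array with generated gene ids."""
    values = np.asarray(values, float)
    genes = [f"G{i + 1:04d} ({1000 + i + 1})" for i in range(values.shape[0])]
    lines = lines or [f"ACH-{j + 1:06d}" for j in range(values.shape[1])]
    gene_tab = pd.DataFrame(
        {"symbol": [g.split(" ")[0] for g in genes],
         "entrez": pd.array(range(1001, 1001 + len(genes)), dtype="Int64")},
        index=genes)
    return DependencyMatrix(pd.DataFrame(values, index=genes, columns=lines),
                            gene_tab, source, theta=theta)


@pytest.fixture(scope="session")
def default_screens():
    """Default synthetic screens with all downstream stages precomputed."""
    spec = default_screen_spec()
    crispr, shrna, truth = generate_paired_screens(spec)
    meta = sample_info_table(spec)
    ca, sa, report = align_screens(crispr, shrna, meta)
    ci, ri = impute_cross_method(ca, sa, seed=1)
    combined = combine_scores(ci, ri, 0.6)
    threshold = fit_threshold(combined)
    return {"spec": spec, "crispr": crispr, "shrna": shrna, "truth": truth,
            "meta": meta, "aligned": (ca, sa), "report": report,
            "imputed": (ci, ri), "combined": combined,
            "threshold": threshold}


@pytest.fixture(scope="session")
def planted_modules():
    """Eight 15-gene co-dependent modules plus 80 uncorrelated essential
    filler genes, combined at theta 0.6 — the clustering benchmark."""
    spec = SyntheticSpec(n_genes=500, n_lines=423,
                         frac_common_essential=0.16, frac_selective=0.24,
                         modules=tuple((15, 0.9) for _ in range(8)),
                         method_bias=(0, 0), seed=7)
    crispr, shrna, truth = generate_paired_screens(spec)
    ca, sa, _ = align_screens(crispr, shrna, sample_info_table(spec))
    ci, ri = impute_cross_method(ca, sa, seed=1)
    combined = combine_scores(ci, ri, 0.6)
    module_genes = list(truth.table.index[truth.table["module"].notna()])
    filler = truth.genes_with_label("common_essential")
    genes = sorted(module_genes + filler)
    return {"spec": spec, "truth": truth,
            "matrix": combined.restrict(genes=genes),
            "module_genes": module_genes, "filler": filler}
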