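"""Score every gene for efficacy and selectivity and call essential genes.

Efficacy is the 1st percentile of a gene's scores across lines (its effect
in sensitive lines); selectivity is the normalised excess of its score
dispersion over what the efficacy predicts.  Commonly essential genes are
efficacious but unselective; selectively essential genes stand out on the
selectivity axis — the more attractive drug-target profile.
"""

from depmix import (align_screens, call_essential_genes, combine_scores,
                    default_screen_spec, fit_threshold, gene_score_table,
                    generate_paired_screens, impute_cross_method,
                    overlap_index, pc1_mixing_ratio, sample_info_table)

spec = default_screen_spec()
crispr, shrna, truth = generate_paired_screens(spec)
ca, sa, _ = align_screens(crispr, shrna, sample_info_table(spec))
print(f"PC1 mixing ratio of the paired score cloud: "
      f"{pc1_mixing_ratio(ca, sa):.3f} "
      "(the theta along the cloud's main axis)")

ci, ri = impute_cross_method(ca, sa, seed=1)

essential_sets = {}
for theta in (0.4, 0.6):
    combined = combine_scores(ci, ri, theta)
    thr = fit_threshold(combined)
    table = gene_score_table(combined, thr, x=1.0)
    essential_sets[theta] = call_essential_genes(table, thr)
    print(f"theta={theta}: T={thr.T:.3f}, "
          f"{len(essential_sets[theta])} essential genes")

print(f"overlap index between the two essential sets: "
      f"{overlap_index(essential_sets[0.4], essential_sets[0.6]):.3f}")

top = table.loc[table["essential"]].nlargest(5, "selectivity")
print("\nmost selective essential genes (theta=0.6, X=1):")
print(top[["efficacy", "selectivity", "n_dependent_lines"]]
      .join(truth.table["label"]).to_string())
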