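"""Mix the two screens into one dependency score and fit the essentiality
threshold.

Conditions measured by only one technology are imputed from the other via
local regression, the combined score S = theta*CRISPR + (1-theta)*shRNA is
formed at theta = 0.6, and the background normal is recovered from the
right half of the pooled score distribution: T is its 0.001 quantile, so
roughly one background condition in a thousand is called essential by
chance.
"""

from depmix import (align_screens, combine_scores, default_screen_spec,
                    essential_conditions, fit_threshold,
                    generate_paired_screens, impute_cross_method,
                    sample_info_table)

spec = default_screen_spec()
crispr, shrna, _ = generate_paired_screens(spec)
ca, sa, report = align_screens(crispr, shrna, sample_info_table(spec))
print(f"aligned: {report.n_genes} genes x {report.n_lines} lines; "
      f"{report.crispr_only_tested} CRISPR-only, "
      f"{report.shrna_only_tested} shRNA-only, "
      f"{report.untested} untested conditions")

ci, ri = impute_cross_method(ca, sa, seed=1)
combined = combine_scores(ci, ri, theta=0.6)
thr = fit_threshold(combined)
print(f"threshold fit: mode={thr.mode:.4f}  mu={thr.mu:.4f}  "
      f"sigma={thr.sigma:.4f}")
print(f"essentiality cutoff T = {thr.T:.4f} "
      "(0.001 background-normal quantile)")

ess = essential_conditions(combined, thr)
print(f"essential conditions: {int(ess.to_numpy().sum())} of "
      f"{ess.size} ({ess.to_numpy().mean():.4f})")
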