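"""Per-gene efficacy and selectivity, essential-gene calls, and Fisher tests.

Efficacy E_{G,X} is the X-th percentile of gene G's scores across cell
lines — how damaging losing G is in a sensitive line.  The dispersion
D = E_{100-X} - E_X measures how much the effect varies across lines.
Commonly essential genes fall on a tight line of E_{100-X} against E_X;
a robust linear regression across genes captures that trend, and the
selectivity S = (D - D_hat) / D_hat is the normalised excess dispersion
over the fit — large S means the gene kills only a subset of lines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import binom, hypergeom
from statsmodels.stats.multitest import multipletests

from .combine import EssentialityThreshold, count_dependent_lines, essential_conditions
from .matrix import DependencyMatrix

__all__ = [
    "efficacy",
    "selectivity_fit",
    "gene_score_table",
    "call_essential_genes",
    "overlap_index",
    "pc1_mixing_ratio",
    "crispr_shrna_inconsistency",
    "fisher_overrepresentation",
    "essential_call_significance",
    "fisher_upper_tail",
]

#: Percentile grid the interactive tool exposes; any X in (0, 50) works.
X_GRID = (1, 2.5, 5, 10, 25)


def fisher_upper_tail(k, M, K, n):
    """One-sided (enrichment) Fisher p for a 2x2 table, vectorised.

    ``P(X >= k)`` for X ~ Hypergeometric(M, K, n): the population has M
    conditions of which K are "in the area"; the gene contributes n of
    them and k landed in the area.  Zero-margin tables give p = 1.
    """
    return hypergeom.sf(np.asarray(k) - 1, M, K, n)


def efficacy(matrix: DependencyMatrix, x: float,
             min_values: int = 20) -> pd.Series:
    """X-th percentile of each gene's non-missing scores.

    Linear interpolation between order statistics; genes with fewer than
    ``min_values`` observed scores get NaN (flagged as undefined).
    """
    if not 0.0 < x < 100.0:
        raise ValueError(f"percentile must be in (0, 100), got {x}")
    vals = matrix.values.to_numpy()
    n_obs = (~np.isnan(vals)).sum(axis=1)
    with np.errstate(all="ignore"):
        pct = np.nanpercentile(vals, x, axis=1)
    pct[n_obs < min_values] = np.nan
    return pd.Series(pct, index=matrix.values.index, name=f"efficacy_{x}")


def _robust_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Huber M-estimate (tuning 1.345) of y = a + b*x across genes.

    Falls back to plain least squares when the relation is numerically
    exact, where the robust scale estimate degenerates to zero.
    """
    if np.ptp(x) <= 0:
        raise ValueError("degenerate regression: predictor has no variance")
    X = sm.add_constant(x)
    ols = sm.OLS(y, X).fit()
    resid_scale = float(np.max(np.abs(ols.resid)))
    data_scale = max(float(np.max(np.abs(y))), 1.0)
    if resid_scale <= 1e-12 * data_scale:
        a, b = ols.params
        return float(a), float(b)
    rlm = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345))
    res = rlm.fit(maxiter=50, tol=1e-8)
    if not np.all(np.isfinite(res.params)):
        raise ValueError("robust regression failed to converge to finite "
                         "coefficients")
    a, b = res.params
    return float(a), float(b)


def selectivity_fit(eff_lo: pd.Series, eff_hi: pd.Series,
                    min_genes: int = 100) -> pd.DataFrame:
    """Regress the upper percentile on efficacy and derive selectivity.

    Returns a frame with columns ``dispersion`` (D), ``expected_dispersion``
    (D_hat from the robust fit), ``residual`` (R = D - D_hat) and
    ``selectivity`` (S = R / D_hat).  Genes in the pathological region
    D_hat <= 0 get NaN selectivity and are flagged in ``selectivity_defined``.
    """
    if not eff_lo.index.equals(eff_hi.index):
        raise ValueError("efficacy series are not aligned")
    ok = eff_lo.notna() & eff_hi.notna()
    if int(ok.sum()) < min_genes:
        raise ValueError(f"need >= {min_genes} genes with both percentiles, "
                         f"got {int(ok.sum())}")
    a, b = _robust_line(eff_lo[ok].to_numpy(), eff_hi[ok].to_numpy())

    disp = eff_hi - eff_lo
    fitted_hi = a + b * eff_lo
    exp_disp = fitted_hi - eff_lo
    resid = disp - exp_disp
    defined = ok & (exp_disp > 0)
    sel = resid.where(defined) / exp_disp.where(defined)
    out = pd.DataFrame({
        "dispersion": disp,
        "expected_dispersion": exp_disp,
        "residual": resid,
        "selectivity": sel,
        "selectivity_defined": defined,
    })
    out.attrs["intercept"] = a
    out.attrs["slope"] = b
    return out


def gene_score_table(matrix: DependencyMatrix,
                     threshold: EssentialityThreshold,
                     x: float = 1.0, min_values: int = 20,
                     min_genes: int = 100) -> pd.DataFrame:
    """Full per-gene score table at percentile level X.

    Columns: efficacy (E_X), upper (E_{100-X}), dispersion, expected
    dispersion, residual, selectivity, essential flag (E_X < T) and the
    number of dependent cell lines.  ``attrs`` carry X and theta.
    """
    eff = efficacy(matrix, x, min_values=min_values)
    upper = efficacy(matrix, 100.0 - x, min_values=min_values)
    fit = selectivity_fit(eff, upper, min_genes=min_genes)
    ess = essential_conditions(matrix, threshold)
    table = pd.DataFrame({
        "symbol": matrix.genes["symbol"],
        "efficacy": eff,
        "upper": upper,
        **{c: fit[c] for c in fit.columns},
        "essential": (eff < threshold.T).fillna(False),
        "n_dependent_lines": count_dependent_lines(ess),
    })
    table.attrs["x"] = x
    table.attrs["theta"] = threshold.theta
    table.attrs["T"] = threshold.T
    table.attrs.update({k: fit.attrs[k] for k in ("intercept", "slope")})
    return table


def call_essential_genes(scores: pd.DataFrame,
                         threshold: EssentialityThreshold) -> set[str]:
    """Genes whose efficacy lies below the essentiality threshold."""
    if scores.attrs.get("theta", threshold.theta) != threshold.theta:
        raise ValueError("score table and threshold use different theta")
    mask = scores["efficacy"] < threshold.T
    return set(scores.index[mask])


def overlap_index(set_a: set, set_b: set) -> float:
    """|A n B| / min(|A|, |B|): 0 for disjoint sets, 1 for nested sets."""
    if not set_a or not set_b:
        raise ValueError("overlap index is undefined for empty sets")
    return len(set_a & set_b) / min(len(set_a), len(set_b))


def pc1_mixing_ratio(crispr: DependencyMatrix,
                     shrna: DependencyMatrix) -> float:
    """Mixing ratio implied by the principal axis of the paired score cloud.

    Pools every doubly-observed condition as a 2-D point (S_CRISPR,
    S_shRNA), takes the leading eigenvector (v_C, v_R) of its covariance,
    fixes the sign so the vector points into the positive quadrant, and
    returns v_C / (v_C + v_R) — the theta for which the combined score
    varies along the cloud's main axis.
    """
    c = crispr.values.to_numpy().ravel()
    r = shrna.values.to_numpy().ravel()
    ok = ~np.isnan(c) & ~np.isnan(r)
    if ok.sum() < 3:
        raise ValueError("too few doubly-observed conditions")
    pts = np.vstack([c[ok], r[ok]])
    cov = np.cov(pts)
    if not np.all(np.isfinite(cov)) or np.allclose(cov, 0):
        raise ValueError("degenerate covariance of the paired scores")
    w, v = np.linalg.eigh(cov)
    vec = v[:, int(np.argmax(w))]
    if vec.sum() < 0:
        vec = -vec
    return float(vec[0] / (vec[0] + vec[1]))


def crispr_shrna_inconsistency(crispr_ess: pd.DataFrame,
                               shrna_ess: pd.DataFrame,
                               alpha: float = 1e-3,
                               valid: pd.DataFrame | None = None,
                               ) -> pd.DataFrame:
    """Per-gene test for method-exclusive essentiality.

    Area A holds conditions essential by CRISPR but not shRNA; area B the
    converse.  For each gene and each area, a one-tailed Fisher's exact
    test asks whether that gene's conditions are enriched in the area
    relative to all other genes' conditions (2x2 of {this gene, rest} x
    {in area, not}).  ``valid`` restricts counting to conditions observed
    in both screens (default: all).
    """
    if not crispr_ess.index.equals(shrna_ess.index) or \
            not crispr_ess.columns.equals(shrna_ess.columns):
        raise ValueError("essentiality matrices are not aligned")
    ce = crispr_ess.to_numpy(bool)
    re_ = shrna_ess.to_numpy(bool)
    ok = np.ones_like(ce) if valid is None else valid.to_numpy(bool)

    out = {"n_conditions": ok.sum(axis=1)}
    total = int(ok.sum())
    for name, area in (("a", ce & ~re_ & ok), ("b", ~ce & re_ & ok)):
        k = area.sum(axis=1)
        big_k = int(k.sum())
        p = fisher_upper_tail(k, total, big_k, out["n_conditions"])
        out[f"n_area_{name}"] = k
        out[f"p_{name}"] = p
        out[f"flag_{name}"] = p < alpha
    df = pd.DataFrame(out, index=crispr_ess.index)
    df.attrs["alpha"] = alpha
    return df


def fisher_overrepresentation(hits: set, universe: set,
                              gene_sets: dict[str, set]) -> pd.DataFrame:
    """One-tailed Fisher enrichment of ``hits`` in each annotated gene set.

    Gene sets are intersected with the universe first.  Reports the raw
    hypergeometric upper-tail p, the sample odds ratio, and
    Benjamini-Hochberg adjusted p-values across sets.
    """
    if not universe:
        raise ValueError("empty universe")
    if not set(hits) <= set(universe):
        raise ValueError("hits must be a subset of the universe")
    m_tot = len(universe)
    n_hits = len(hits)
    rows = []
    for name, gs in gene_sets.items():
        gsu = set(gs) & set(universe)
        k = len(gsu & set(hits))
        big_k = len(gsu)
        p = float(fisher_upper_tail(k, m_tot, big_k, n_hits))
        a, b = k, n_hits - k
        c, d = big_k - k, m_tot - big_k - (n_hits - k)
        odds = np.inf if b * c == 0 and a * d > 0 else (
            np.nan if b * c == 0 else (a * d) / (b * c))
        rows.append((name, big_k, k, p, odds))
    df = pd.DataFrame(rows, columns=["set", "set_size", "n_overlap",
                                     "p", "odds_ratio"]).set_index("set")
    if len(df):
        df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    else:
        df["p_adj"] = []
    return df


def essential_call_significance(n_lines: int, k_dependent: int,
                                p0: float) -> float:
    """Exact binomial upper tail P(K >= k | n, p0).

    The chance that at least ``k_dependent`` of ``n_lines`` cell lines
    would be called dependent if each were an independent false call at
    rate ``p0`` — how surprising a gene's dependent-line count is.
    """
    if not 0 <= k_dependent <= n_lines:
        raise ValueError("k_dependent must be between 0 and n_lines")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    return float(binom.sf(k_dependent - 1, n_lines, p0))
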