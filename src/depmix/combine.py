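"""Cross-method imputation, the combined score, and the essentiality threshold.

The combined dependency score of gene G in line L mixes the two screens,

    S_theta = theta * S_CRISPR + (1 - theta) * S_shRNA,   0 <= theta <= 1.

Before mixing, a condition measured by only one technology has its
missing counterpart imputed from the observed one by local polynomial
regression over all doubly-observed conditions; conditions measured by
neither stay missing.

Essential conditions are defined against a global threshold T: the
pooled score distribution is near-normal with a heavy left tail (the
essential effects), so the clean right half is used to recover the
background normal.  A kernel density estimate locates the mode, the data
at or above the mode are reflected about it, and the mean and standard
deviation of that folded sample give mu and sigma.  T is the 0.001
quantile of Normal(mu, sigma); a score below T is an essential
condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import signal
from scipy.stats import norm

from .matrix import DependencyMatrix, Source

__all__ = [
    "EssentialityThreshold",
    "impute_cross_method",
    "combine_scores",
    "fit_threshold",
    "essential_conditions",
    "count_dependent_lines",
]

#: Normal quantile behind the threshold definition, Phi^-1(0.001).
Z_TAIL = float(norm.ppf(0.001))


@dataclass(frozen=True)
class EssentialityThreshold:
    """Fitted background distribution and essentiality cutoff for one matrix."""

    source: Source
    theta: float | None
    mu: float
    sigma: float
    mode: float
    T: float
    tail_prob: float = 0.001

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def to_dict(self) -> dict:
        return {"source": self.source.value, "theta": self.theta,
                "mu": self.mu, "sigma": self.sigma, "mode": self.mode,
                "T": self.T, "tail_prob": self.tail_prob}

    @classmethod
    def from_dict(cls, d) -> "EssentialityThreshold":
        d = dict(d)
        d["source"] = Source(d["source"])
        return cls(**d)


def _check_aligned(a: DependencyMatrix, b: DependencyMatrix) -> None:
    if list(a.values.index) != list(b.values.index) or \
            list(a.values.columns) != list(b.values.columns):
        raise ValueError("matrices are not aligned; run align_screens first")


def _loess_curve(x: np.ndarray, y: np.ndarray, frac: float) -> tuple[np.ndarray, np.ndarray]:
    """Fit a lowess curve y ~ x and return it as a sorted step-free polyline."""
    span = x.max() - x.min()
    fitted = sm.nonparametric.lowess(y, x, frac=frac, it=2,
                                     delta=0.005 * span, return_sorted=True)
    gx, gy = fitted[:, 0], fitted[:, 1]
    keep = np.concatenate([[True], np.diff(gx) > 0])
    return gx[keep], gy[keep]


def _predict_curve(gx: np.ndarray, gy: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Interpolate on the fitted curve, extrapolating linearly at the ends."""
    y = np.interp(x, gx, gy)
    if len(gx) >= 2:
        lo_slope = (gy[1] - gy[0]) / (gx[1] - gx[0])
        hi_slope = (gy[-1] - gy[-2]) / (gx[-1] - gx[-2])
        below = x < gx[0]
        above = x > gx[-1]
        y[below] = gy[0] + lo_slope * (x[below] - gx[0])
        y[above] = gy[-1] + hi_slope * (x[above] - gx[-1])
    return y


def impute_cross_method(crispr: DependencyMatrix, shrna: DependencyMatrix,
                        seed: int = 0, frac: float = 0.3,
                        max_points: int = 200_000,
                        ) -> tuple[DependencyMatrix, DependencyMatrix]:
    """Fill conditions missing in exactly one screen from the other screen.

    Two local-regression curves are fitted on the doubly-observed
    conditions (CRISPR as a function of shRNA, and the converse) and
    evaluated at the observed score of each singly-missing condition.
    Observed values are never altered, and conditions missing in both
    screens stay missing.  For speed the curves are fitted on a seeded
    random subsample of at most ``max_points`` doubly-observed pairs;
    predictions outside the fitted range are extrapolated linearly from
    the nearest curve segment.
    """
    _check_aligned(crispr, shrna)
    c = crispr.values.to_numpy(copy=True)
    r = shrna.values.to_numpy(copy=True)
    cmiss, rmiss = np.isnan(c), np.isnan(r)
    both_obs = ~cmiss & ~rmiss
    n_obs = int(both_obs.sum())
    if n_obs < 100:
        raise ValueError(
            f"only {n_obs} doubly-observed conditions; need >= 100 to fit")

    xs = r[both_obs]
    ys = c[both_obs]
    if n_obs > max_points:
        sel = np.random.default_rng(seed).choice(n_obs, size=max_points,
                                                 replace=False)
        xs, ys = xs[sel], ys[sel]

    fill_c = cmiss & ~rmiss
    if fill_c.any():
        gx, gy = _loess_curve(xs, ys, frac)
        c[fill_c] = _predict_curve(gx, gy, r[fill_c])
    fill_r = rmiss & ~cmiss
    if fill_r.any():
        gx, gy = _loess_curve(ys, xs, frac)
        r[fill_r] = _predict_curve(gx, gy, c[fill_r])

    ci = crispr.copy()
    ci.values.iloc[:, :] = c
    ri = shrna.copy()
    ri.values.iloc[:, :] = r
    return ci, ri


def combine_scores(crispr: DependencyMatrix, shrna: DependencyMatrix,
                   theta: float) -> DependencyMatrix:
    """Elementwise weighted average of the two (imputed, aligned) screens."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must be in [0, 1], got {theta}")
    _check_aligned(crispr, shrna)
    vals = theta * crispr.values + (1.0 - theta) * shrna.values
    return DependencyMatrix(vals, crispr.genes.copy(), Source.COMBINED,
                            theta=theta)


def _kde_mode(values: np.ndarray, gridsize: int = 512) -> float:
    """Locate the dominant mode of the pooled score density.

    The kernel density estimate (Gaussian kernel, Silverman bandwidth,
    FFT-binned on a 512-point grid) gives the coarse peak; a quadratic
    fit to the log-density over the contiguous region where the density
    exceeds 60% of the peak refines it.  Near the mode the log-density
    of the clean background is parabolic, so the vertex estimate is far
    more stable than the raw grid argmax.
    """
    kde = sm.nonparametric.KDEUnivariate(values)
    kde.fit(kernel="gau", bw="silverman", fft=True, gridsize=gridsize)
    dens, supp = kde.density, kde.support
    i = int(np.argmax(dens))

    peaks, props = signal.find_peaks(dens, height=0.5 * dens[i],
                                     prominence=0.05 * dens[i])
    if len(peaks) > 1:
        warnings.warn("score density has a competing secondary mode; "
                      "using the global maximum", stacklevel=3)

    thr = 0.6 * dens[i]
    lo = i
    while lo > 0 and dens[lo - 1] >= thr:
        lo -= 1
    hi = i
    while hi < len(dens) - 1 and dens[hi + 1] >= thr:
        hi += 1
    if hi - lo >= 2:
        coef = np.polyfit(supp[lo:hi + 1], np.log(dens[lo:hi + 1]), 2)
        if coef[0] < 0:
            vertex = -coef[1] / (2.0 * coef[0])
            if supp[lo] <= vertex <= supp[hi]:
                return float(vertex)
    return float(supp[i])


def fit_threshold(matrix: DependencyMatrix, tail_prob: float = 0.001,
                  min_values: int = 10_000, gridsize: int = 512,
                  ) -> EssentialityThreshold:
    """Fit the essentiality threshold T from the pooled score distribution.

    Scores at or above the KDE mode are reflected about the mode; the
    folded sample's mean and standard deviation estimate the background
    Normal(mu, sigma), and T is set so that a background score falls
    below it with probability ``tail_prob``.
    """
    vals = matrix.values.to_numpy().ravel()
    vals = vals[~np.isnan(vals)]
    if vals.size < min_values:
        raise ValueError(
            f"need >= {min_values} observed scores to fit a threshold, "
            f"got {vals.size}")
    mode = _kde_mode(vals, gridsize=gridsize)
    right = vals[vals >= mode]
    folded = np.concatenate([right, 2.0 * mode - right])
    mu = float(folded.mean())
    sigma = float(folded.std())
    T = mu + sigma * float(norm.ppf(tail_prob))
    theta = matrix.theta
    return EssentialityThreshold(source=matrix.source, theta=theta,
                                 mu=mu, sigma=sigma, mode=mode, T=T,
                                 tail_prob=tail_prob)


def essential_conditions(matrix: DependencyMatrix,
                         threshold: EssentialityThreshold) -> pd.DataFrame:
    """Boolean frame: True where the score is observed and below T."""
    if threshold.source is not matrix.source or \
            (matrix.source is Source.COMBINED and threshold.theta != matrix.theta):
        raise ValueError("threshold was fitted on a different score matrix "
                         f"({threshold.source.value}, theta={threshold.theta})")
    return (matrix.values < threshold.T) & matrix.values.notna()


def count_dependent_lines(essential: pd.DataFrame) -> pd.Series:
    """Per-gene number of cell lines called dependent (row sums)."""
    return essential.sum(axis=1).astype(int)
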