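"""ECHODOTS: ensemble clustering with hierarchy over DBSCAN on t-SNE.

A single t-SNE embedding of essential genes (from their Spearman
distance matrix) followed by DBSCAN yields clusters that depend on the
random initial layout.  ECHODOTS runs the embedding many times with
different seeds, clusters each layout with DBSCAN, and keeps only the
gene groupings that the runs agree on: a co-association matrix records
how often each gene pair lands in the same cluster, pairs co-clustered
in a majority of runs are linked, and the connected components of that
link graph are the consensus clusters.  Each gene carries a membership
probability — the average fraction of its consensus co-members it was
actually clustered with per run — so weakly supported assignments are
visible rather than silently hardened.

DBSCAN's neighbourhood radius is tied to the layout scale: eps = L / d,
where L is the coordinate range of the embedding and d a granularity
denominator.  Small d merges everything; the lower bound d0 is chosen as
the smallest d whose consensus does not produce one dominant cluster
(size ratio of the two largest clusters below a threshold).  Running at
several d >= d0 yields nested large/medium/small cluster levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import rankdata
from sklearn.cluster import DBSCAN
from sklearn.manifold import TSNE

from .matrix import DependencyMatrix

__all__ = [
    "EchodotsConfig",
    "EmbeddingRun",
    "ClusterAssignment",
    "spearman_distance",
    "embed_once",
    "dbscan_partition",
    "consensus_partition",
    "select_d0",
    "run_echodots",
]


@dataclass(frozen=True)
class EchodotsConfig:
    """Tunable parameters of the ensemble clustering.

    ``d_values`` are the granularity denominators (ascending; larger d =
    tighter clusters); ``n_runs`` the number of seeded t-SNE + DBSCAN
    repetitions entering the consensus; ``min_pts`` the DBSCAN core-point
    threshold (2 allows two-gene clusters, singletons become noise);
    ``d0_ratio_threshold`` the largest tolerated size ratio between the
    two biggest consensus clusters when selecting the lower bound d0.
    """

    d_values: tuple[int, ...] = (65, 100, 141)
    n_runs: int = 200
    perplexity: float = 30.0
    tsne_iters: int = 1000
    min_pts: int = 2
    d0_ratio_threshold: float = 5.0
    base_seed: int = 0

    def __post_init__(self):
        if list(self.d_values) != sorted(self.d_values) or \
                len(set(self.d_values)) != len(self.d_values):
            raise ValueError("d_values must be strictly ascending")
        if any(d <= 0 for d in self.d_values):
            raise ValueError("d_values must be positive")
        if self.n_runs < 2:
            raise ValueError("need at least 2 runs for a consensus")
        if self.min_pts < 2:
            raise ValueError("min_pts must be >= 2")
        if self.perplexity <= 0 or self.tsne_iters < 250:
            raise ValueError("invalid t-SNE settings")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["d_values"] = list(self.d_values)
        return d


@dataclass
class EmbeddingRun:
    """One seeded t-SNE layout: 2-D coordinates and their range L."""

    seed: int
    coords: np.ndarray
    L: float


@dataclass
class ClusterAssignment:
    """Consensus labels at every granularity plus the cluster hierarchy.

    ``assignment`` is indexed by gene with, per granularity prefix P
    (L/M/S for three d values), columns ``P_label`` (e.g. ``"S12"``,
    NaN for noise), ``P_prob`` and ``P_noise``.  ``hierarchy`` maps each
    finer cluster to the coarser cluster holding the plurality of its
    genes, with a flag where the finer cluster is not a clean subset.
    """

    assignment: pd.DataFrame
    hierarchy: pd.DataFrame
    config: EchodotsConfig
    prefixes: tuple[str, ...] = ()
    d0: int | None = None


def spearman_distance(matrix: "DependencyMatrix | pd.DataFrame") -> pd.DataFrame:
    """Pairwise 1 - Spearman correlation between gene score profiles.

    Correlations use pairwise-complete cell lines.  A gene with a
    constant (or all-missing) profile has undefined correlation; its
    distances are set to 1 (the uncorrelated value) with a warning.
    """
    vals = matrix.values if isinstance(matrix, DependencyMatrix) else matrix
    if vals.shape[0] < 3:
        raise ValueError("need at least 3 genes")
    arr = vals.to_numpy(float)
    if not np.isnan(arr).any():
        ranks = rankdata(arr, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.corrcoef(ranks)
    else:
        rho = vals.T.corr(method="spearman").to_numpy()
    bad = ~np.isfinite(rho)
    if bad.any():
        warnings.warn("constant or empty gene profiles: undefined "
                      "correlations set to 0 (distance 1)", stacklevel=2)
        rho[bad] = 0.0
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    return pd.DataFrame(dist, index=vals.index, columns=vals.index)


def embed_once(dist: pd.DataFrame, seed: int,
               config: EchodotsConfig) -> EmbeddingRun:
    """One t-SNE layout of the distance matrix, deterministic in the seed."""
    n = dist.shape[0]
    perplexity = config.perplexity
    if n <= 3 * perplexity:
        perplexity = max(2.0, (n - 1) / 3.0)
        warnings.warn(f"perplexity reduced to {perplexity:g} for {n} genes",
                      stacklevel=2)
    tsne = TSNE(n_components=2, metric="precomputed", init="random",
                perplexity=perplexity, max_iter=config.tsne_iters,
                random_state=seed, n_jobs=1)
    coords = tsne.fit_transform(dist.to_numpy())
    L = float(np.max(coords.max(axis=0) - coords.min(axis=0)))
    return EmbeddingRun(seed=seed, coords=coords, L=L)


def dbscan_partition(run: EmbeddingRun, d: float,
                     min_pts: int = 2) -> tuple[float, np.ndarray]:
    """DBSCAN on one layout with radius eps = L / d.

    Returns ``(eps, labels)`` where labels are integers with -1 marking
    noise (genes clustered with nothing at this granularity).
    """
    if d <= 0:
        raise ValueError("d must be positive")
    eps = run.L / d
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(run.coords)
    return eps, labels


def _coassociation(partitions: list[np.ndarray]) -> np.ndarray:
    n = len(partitions[0])
    acc = np.zeros((n, n))
    for labels in partitions:
        lab = np.asarray(labels)
        same = (lab[:, None] == lab[None, :]) & (lab[:, None] >= 0)
        acc += same
    acc /= len(partitions)
    np.fill_diagonal(acc, 1.0)
    return acc


def consensus_partition(partitions: list[np.ndarray],
                        majority: float = 0.5,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Majority-vote consensus over an ensemble of hard partitions.

    Builds the co-association matrix A (fraction of runs co-clustering
    each pair; noise points co-cluster with nothing), links pairs with
    A > ``majority``, and takes connected components.  Components of
    size >= 2 are the consensus clusters, relabelled 0,1,... in
    decreasing size; singletons get label -1 (noise).  The membership
    probability of gene g is the mean co-association between g and its
    consensus co-members — equivalently, the average over runs of the
    fraction of co-members g was clustered with.  A noise gene reports
    the probability of its best-supported cluster (0 if none exist).
    """
    if len(partitions) < 2:
        raise ValueError("need at least 2 partitions")
    n = len(partitions[0])
    if any(len(p) != n for p in partitions):
        raise ValueError("partitions cover different gene lists")
    A = _coassociation(partitions)
    link = A > majority
    np.fill_diagonal(link, False)
    n_comp, comp = connected_components(csr_matrix(link), directed=False)

    sizes = np.bincount(comp, minlength=n_comp)
    cluster_comps = [c for c in range(n_comp) if sizes[c] >= 2]
    # stable ids: decreasing size, ties broken by smallest member index
    first_member = {c: int(np.argmax(comp == c)) for c in cluster_comps}
    cluster_comps.sort(key=lambda c: (-sizes[c], first_member[c]))
    comp_to_label = {c: i for i, c in enumerate(cluster_comps)}

    labels = np.array([comp_to_label.get(c, -1) for c in comp])
    prob = np.zeros(n)
    members = {lab: np.flatnonzero(labels == lab)
               for lab in comp_to_label.values()}
    for g in range(n):
        if labels[g] >= 0:
            co = members[labels[g]]
            co = co[co != g]
            prob[g] = A[g, co].mean() if len(co) else 1.0
        else:
            best = 0.0
            for co in members.values():
                best = max(best, float(A[g, co].mean()))
            prob[g] = best
    return labels, prob


def _ensemble_embeddings(dist: pd.DataFrame,
                         config: EchodotsConfig) -> list[EmbeddingRun]:
    return [embed_once(dist, config.base_seed + i, config)
            for i in range(config.n_runs)]


def _consensus_for_d(runs: list[EmbeddingRun], d: int,
                     config: EchodotsConfig) -> tuple[np.ndarray, np.ndarray]:
    parts = [dbscan_partition(r, d, config.min_pts)[1] for r in runs]
    return consensus_partition(parts)


def _size_ratio(labels: np.ndarray) -> float:
    sizes = np.sort(np.bincount(labels[labels >= 0]))[::-1] if \
        (labels >= 0).any() else np.array([])
    if len(sizes) < 2:
        return np.inf
    return float(sizes[0] / sizes[1])


def select_d0(dist: pd.DataFrame, d_grid: list[int], config: EchodotsConfig,
              embeddings: list[EmbeddingRun] | None = None) -> int:
    """Smallest granularity d whose consensus avoids one dominant cluster.

    Noise points are excluded from the size ratio.  Raises if no d in
    the grid qualifies, advising a wider grid.
    """
    if embeddings is None:
        embeddings = _ensemble_embeddings(dist, config)
    for d in sorted(d_grid):
        labels, _ = _consensus_for_d(embeddings, d, config)
        if _size_ratio(labels) <= config.d0_ratio_threshold:
            return int(d)
    raise ValueError("no granularity in the grid avoids a dominant cluster; "
                     "extend d_grid to larger values")


def _prefixes(k: int, d_values) -> tuple[str, ...]:
    if k == 3:
        return ("L", "M", "S")
    if k == 2:
        return ("L", "S")
    if k == 1:
        return ("S",)
    return tuple(f"D{d}" for d in d_values)


def run_echodots(matrix: "DependencyMatrix | pd.DataFrame",
                 config: EchodotsConfig | None = None,
                 check_d0: bool = False) -> ClusterAssignment:
    """Full ensemble clustering of essential genes at every granularity.

    One Spearman distance matrix and one set of ``n_runs`` seeded t-SNE
    layouts are shared across all granularities; only DBSCAN and the
    consensus are re-run per d.  Ascending d values map to coarse-to-fine
    prefixes (L/M/S for three), and each finer cluster is linked to the
    coarser cluster containing the plurality of its genes; links where
    the finer cluster is not fully contained are flagged as hierarchy
    violations, not repaired.
    """
    config = config or EchodotsConfig()
    dist = spearman_distance(matrix)
    genes = list(dist.index)
    runs = _ensemble_embeddings(dist, config)

    d0 = None
    if check_d0:
        d0 = select_d0(dist, list(config.d_values), config, embeddings=runs)
        if any(d < d0 for d in config.d_values):
            raise ValueError(f"granularities below d0={d0} would merge most "
                             "genes into one cluster")

    prefixes = _prefixes(len(config.d_values), config.d_values)
    cols: dict[str, object] = {}
    level_labels: dict[str, np.ndarray] = {}
    for prefix, d in zip(prefixes, config.d_values):
        labels, prob = _consensus_for_d(runs, d, config)
        level_labels[prefix] = labels
        cols[f"{prefix}_label"] = [f"{prefix}{l}" if l >= 0 else None
                                   for l in labels]
        cols[f"{prefix}_prob"] = prob
        cols[f"{prefix}_noise"] = labels < 0
    assignment = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))

    rows = []
    for (fine_p, coarse_p) in zip(prefixes[:0:-1], prefixes[-2::-1]):
        fine, coarse = level_labels[fine_p], level_labels[coarse_p]
        for lab in sorted(set(fine[fine >= 0])):
            members = np.flatnonzero(fine == lab)
            parents = coarse[members]
            named = parents[parents >= 0]
            if len(named) == 0:
                parent, n_in = None, 0
            else:
                vals, cnts = np.unique(named, return_counts=True)
                order = np.lexsort((vals, -cnts))
                parent = int(vals[order[0]])
                n_in = int(cnts[order[0]])
            violation = n_in < len(members)
            rows.append((fine_p, f"{fine_p}{lab}", coarse_p,
                         f"{coarse_p}{parent}" if parent is not None else None,
                         len(members), n_in, violation))
    hierarchy = pd.DataFrame(rows, columns=[
        "child_level", "child", "parent_level", "parent",
        "n_child", "n_in_parent", "violation"])
    return ClusterAssignment(assignment=assignment, hierarchy=hierarchy,
                             config=config, prefixes=prefixes, d0=d0)
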