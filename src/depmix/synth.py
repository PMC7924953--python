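"""Synthetic paired CRISPR/shRNA screens with known ground truth.

The generator emulates the gross features of genome-wide dependency
screens: a near-normal background of no-effect scores, a heavy left tail
contributed by commonly essential genes (strongly negative in almost
every line) and selectively essential genes (negative only in a subset
of lines), planted co-dependent gene modules whose score profiles
correlate across lines, method-exclusive artifacts (genes scored
essential by only one technology), and realistic missingness (a large
fraction of conditions tested by CRISPR only, small fractions tested by
shRNA only or by neither).

Both screens observe the same underlying biological effect plus
independent measurement noise, so cross-method imputation and the
combined score have signal to exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .matrix import DependencyMatrix, Source

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_paired_screens",
    "default_screen_spec",
    "sample_info_table",
]

_LINEAGES = ["LUNG", "BREAST", "SKIN", "OVARY", "PANCREAS", "BONE",
             "KIDNEY", "LIVER", "BRAIN", "BLOOD"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic paired screen.

    Score units follow the CERES/DEMETER2 convention: background scores
    centre on 0, essential effects are negative shifts of a few tenths
    to around one unit.
    """

    n_genes: int = 2000
    n_lines: int = 100
    n_lineages: int = 5
    frac_common_essential: float = 0.05
    frac_selective: float = 0.05
    selective_penetrance: float = 0.10
    effect_mean: float = -1.2
    effect_sd: float = 0.2
    background_sd: float = 0.2
    #: planted modules as (size, latent-profile correlation); module genes
    #: are drawn from the selective class and share one dependent-line set.
    modules: tuple[tuple[int, float], ...] = ()
    #: (n CRISPR-only essential, n shRNA-only essential) artifact genes.
    method_bias: tuple[int, int] = (0, 0)
    #: (crispr_only_tested, shrna_only_tested, untested) condition rates.
    missing_rates: tuple[float, float, float] = (0.20, 0.0028, 0.0007)
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_common_essential", "frac_selective",
                     "selective_penetrance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(r < 0 for r in self.missing_rates) or sum(self.missing_rates) >= 1:
            raise ValueError("missing rates must be nonnegative and sum to < 1")
        if self.n_genes < 1 or self.n_lines < 1:
            raise ValueError("need at least one gene and one cell line")
        if self.background_sd <= 0 or self.effect_sd < 0:
            raise ValueError("background_sd must be > 0, effect_sd >= 0")
        counts = self._class_counts()
        if counts["common"] + counts["selective"] + sum(self.method_bias) > self.n_genes:
            raise ValueError("gene classes exceed n_genes")
        if sum(size for size, _ in self.modules) > counts["selective"]:
            raise ValueError("module sizes exceed the selective gene pool")
        for size, corr in self.modules:
            if size < 2 or not 0.0 <= corr <= 1.0:
                raise ValueError(f"invalid module ({size}, {corr})")

    def _class_counts(self) -> dict[str, int]:
        return {
            "common": round(self.frac_common_essential * self.n_genes),
            "selective": round(self.frac_selective * self.n_genes),
        }

    def to_dict(self) -> dict:
        d = asdict(self)
        d["modules"] = [list(m) for m in self.modules]
        d["method_bias"] = list(self.method_bias)
        d["missing_rates"] = list(self.missing_rates)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticSpec":
        d = dict(d)
        if "modules" in d:
            d["modules"] = tuple((int(s), float(c)) for s, c in d["modules"])
        if "method_bias" in d:
            d["method_bias"] = tuple(int(x) for x in d["method_bias"])
        if "missing_rates" in d:
            d["missing_rates"] = tuple(float(x) for x in d["missing_rates"])
        spec = cls(**d)
        spec.validate()
        return spec


@dataclass
class GroundTruth:
    """What was planted: per-gene class, module id, and dependent lines.

    ``table`` is indexed by gene label with columns ``label`` (one of
    background / common_essential / selective / crispr_only / shrna_only),
    ``module`` (nullable integer id).  ``dependent_lines`` maps each gene
    to the set of DepMap ids where an essential effect was planted
    (empty for background genes).
    """

    table: pd.DataFrame
    dependent_lines: dict[str, set[str]]

    def genes_with_label(self, label: str) -> list[str]:
        return list(self.table.index[self.table["label"] == label])

    def module_members(self, module_id: int) -> list[str]:
        return list(self.table.index[self.table["module"] == module_id])


def default_screen_spec() -> SyntheticSpec:
    """A desk-scale spec mirroring the structure of a genome-wide screen.

    2,000 genes x 100 lines keeps every pipeline stage fast while leaving
    enough conditions (200,000) for stable threshold fits.  Missingness
    rates match the aggregate rates observed in paired DepMap releases
    (~20% CRISPR-only-tested, 0.28% shRNA-only, 0.07% untested).
    """
    return SyntheticSpec(
        n_genes=2000,
        n_lines=100,
        n_lineages=5,
        frac_common_essential=0.05,
        frac_selective=0.05,
        selective_penetrance=0.10,
        effect_mean=-1.2,
        effect_sd=0.2,
        background_sd=0.2,
        modules=((20, 0.9), (20, 0.9), (20, 0.9), (20, 0.9)),
        method_bias=(20, 5),
        missing_rates=(0.20, 0.0028, 0.0007),
        seed=0,
    )


def sample_info_table(spec: SyntheticSpec) -> pd.DataFrame:
    """Deterministic cell-line metadata (DepMap id, CCLE name, lineage)."""
    lineages = [_LINEAGES[i % spec.n_lineages] for i in range(spec.n_lines)]
    depmap_ids = [f"ACH-{i + 1:06d}" for i in range(spec.n_lines)]
    ccle = [f"SYN{i + 1:04d}_{lin}" for i, lin in enumerate(lineages)]
    return pd.DataFrame({"depmap_id": depmap_ids, "ccle_name": ccle,
                         "lineage": lineages})


def _gene_labels(n: int) -> list[str]:
    return [f"G{i + 1:05d} ({100000 + i + 1})" for i in range(n)]


def generate_paired_screens(spec: SyntheticSpec,
                            ) -> tuple[DependencyMatrix, DependencyMatrix, GroundTruth]:
    """Simulate one CRISPR and one shRNA screen over the same lines.

    The biological truth for a condition is background variation plus a
    planted negative effect; each screen adds its own measurement noise.
    Background variance is split evenly between a shared biological
    component and per-method noise, so paired background scores correlate
    at 0.5 — enough structure for cross-method imputation to learn.
    Module genes mix a shared per-line latent factor into their
    biological background at the requested correlation and additionally
    share one dependent-line set, which is what makes their full score
    profiles strongly rank-correlated.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_g, n_l = spec.n_genes, spec.n_lines
    counts = spec._class_counts()
    n_common, n_sel = counts["common"], counts["selective"]
    n_cbias, n_sbias = spec.method_bias

    labels = np.array(["background"] * n_g, dtype=object)
    pos = 0
    idx_common = np.arange(pos, pos + n_common); pos += n_common
    idx_sel = np.arange(pos, pos + n_sel); pos += n_sel
    idx_cbias = np.arange(pos, pos + n_cbias); pos += n_cbias
    idx_sbias = np.arange(pos, pos + n_sbias); pos += n_sbias
    labels[idx_common] = "common_essential"
    labels[idx_sel] = "selective"
    labels[idx_cbias] = "crispr_only"
    labels[idx_sbias] = "shrna_only"

    genes = _gene_labels(n_g)
    meta = sample_info_table(spec)
    lines = list(meta["depmap_id"])

    bio_sd = spec.background_sd / np.sqrt(2.0)
    meas_sd = spec.background_sd / np.sqrt(2.0)

    # biological background, with module genes sharing a latent line profile
    bio = rng.standard_normal((n_g, n_l))
    module_of = np.full(n_g, -1)
    module_lines: dict[int, np.ndarray] = {}
    sel_cursor = 0
    for mid, (size, corr) in enumerate(spec.modules):
        members = idx_sel[sel_cursor:sel_cursor + size]
        sel_cursor += size
        module_of[members] = mid
        latent = rng.standard_normal(n_l)
        bio[members] = (np.sqrt(corr) * latent
                        + np.sqrt(1.0 - corr) * bio[members])
    bio *= bio_sd

    # planted essential effects (negative shifts), per condition
    n_dep = max(1, round(spec.selective_penetrance * n_l))
    effect_shared = np.zeros((n_g, n_l))
    effect_c = np.zeros((n_g, n_l))
    effect_r = np.zeros((n_g, n_l))
    dependent: dict[str, set[str]] = {g: set() for g in genes}

    def draw_effect(k):
        return rng.normal(spec.effect_mean, spec.effect_sd, size=k)

    for i in idx_common:
        effect_shared[i, :] = draw_effect(n_l)
        dependent[genes[i]] = set(lines)
    for mid in range(len(spec.modules)):
        module_lines[mid] = rng.choice(n_l, size=n_dep, replace=False)
    for i in idx_sel:
        mid = module_of[i]
        if mid >= 0:
            cols = module_lines[mid]
        else:
            cols = rng.choice(n_l, size=n_dep, replace=False)
        effect_shared[i, cols] = draw_effect(len(cols))
        dependent[genes[i]] = {lines[j] for j in cols}
    for i in idx_cbias:
        effect_c[i, :] = draw_effect(n_l)
        dependent[genes[i]] = set(lines)
    for i in idx_sbias:
        effect_r[i, :] = draw_effect(n_l)
        dependent[genes[i]] = set(lines)

    s_c = bio + effect_shared + effect_c + rng.standard_normal((n_g, n_l)) * meas_sd
    s_r = bio + effect_shared + effect_r + rng.standard_normal((n_g, n_l)) * meas_sd

    # missingness, one independent draw per condition
    r1, r2, r3 = spec.missing_rates
    u = rng.random((n_g, n_l))
    s_r[u < r1] = np.nan                       # CRISPR-only-tested
    s_c[(u >= r1) & (u < r1 + r2)] = np.nan    # shRNA-only-tested
    both = (u >= r1 + r2) & (u < r1 + r2 + r3)  # untested
    s_c[both] = np.nan
    s_r[both] = np.nan

    gene_tab = pd.DataFrame(
        {"symbol": [g.split(" ")[0] for g in genes],
         "entrez": pd.array([100000 + i + 1 for i in range(n_g)], dtype="Int64")},
        index=genes)
    cvals = pd.DataFrame(s_c, index=genes, columns=lines)
    rvals = pd.DataFrame(s_r, index=genes, columns=list(meta["ccle_name"]))

    crispr = DependencyMatrix(cvals, gene_tab.copy(), Source.CRISPR,
                              line_key="depmap_id")
    shrna = DependencyMatrix(rvals, gene_tab.copy(), Source.SHRNA,
                             line_key="ccle_name")

    truth_tab = pd.DataFrame(
        {"label": labels,
         "module": pd.array([m if m >= 0 else None for m in module_of],
                            dtype="Int64")},
        index=genes)
    # background genes have no dependent lines by construction
    for g, lab in zip(genes, labels):
        if lab == "background":
            dependent[g] = set()
    return crispr, shrna, GroundTruth(truth_tab, dependent)
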