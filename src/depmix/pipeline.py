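"""End-to-end orchestration: align, impute, combine, score, cluster, graph.

The pipeline is deterministic given its config: a single global seed is
expanded into independent per-stage seeds through ``numpy``'s
SeedSequence, so rerunning with the same config reproduces every output
bit for bit.  Each written artifact gets a JSON provenance sidecar
recording the parameters and seeds that produced it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .combine import (combine_scores, essential_conditions, fit_threshold,
                      impute_cross_method)
from .echodots import ClusterAssignment, EchodotsConfig, run_echodots
from .io import (align_screens, read_crispr_matrix, read_sample_info,
                 read_shrna_matrix, write_matrix_csv, write_table)
from .matrix import DependencyMatrix
from .scores import call_essential_genes, gene_score_table
from .synth import SyntheticSpec, generate_paired_screens, sample_info_table

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "stage_seed"]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the global seed."""
    digest = sum((i + 1) * b for i, b in enumerate(stage.encode())) % (2 ** 31)
    h = np.random.SeedSequence([seed, digest])
    return int(h.generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one full analysis run."""

    crispr_path: str | None = None
    shrna_path: str | None = None
    sample_info_path: str | None = None
    synthetic: SyntheticSpec | None = None
    theta: float = 0.6
    x_percentile: float = 1.0
    echodots: EchodotsConfig = field(default_factory=EchodotsConfig)
    out_dir: str = "depmix_out"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"theta must be in [0, 1], got {self.theta}")
        if not 0.0 < self.x_percentile < 50.0:
            raise ValueError("x_percentile must be in (0, 50)")
        has_files = all(p is not None for p in
                        (self.crispr_path, self.shrna_path,
                         self.sample_info_path))
        if not has_files and self.synthetic is None:
            raise ValueError("provide input paths or a synthetic spec")

    def to_dict(self) -> dict:
        d = {
            "crispr_path": self.crispr_path,
            "shrna_path": self.shrna_path,
            "sample_info_path": self.sample_info_path,
            "synthetic": None if self.synthetic is None else self.synthetic.to_dict(),
            "theta": self.theta,
            "x_percentile": self.x_percentile,
            "echodots": self.echodots.to_dict(),
            "out_dir": self.out_dir,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            d["synthetic"] = SyntheticSpec.from_dict(d["synthetic"])
        if d.get("echodots") is not None and not isinstance(
                d["echodots"], EchodotsConfig):
            e = dict(d["echodots"])
            e["d_values"] = tuple(e.get("d_values", (65, 100, 141)))
            d["echodots"] = EchodotsConfig(**e)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class PipelineResult:
    combined: DependencyMatrix
    threshold: object
    scores: pd.DataFrame
    essential_genes: set[str]
    clusters: ClusterAssignment
    report: object


def _sidecar(path: Path, payload: dict) -> None:
    payload = {"depmix_version": __version__, **payload}
    path.with_suffix(path.suffix + ".prov.json").write_text(
        json.dumps(payload, indent=2, default=str) + "\n")


def load_inputs(config: PipelineConfig):
    """Load or simulate the raw paired screens plus cell-line metadata."""
    if config.synthetic is not None:
        crispr, shrna, _ = generate_paired_screens(config.synthetic)
        meta = sample_info_table(config.synthetic)
    else:
        crispr = read_crispr_matrix(config.crispr_path)
        shrna = read_shrna_matrix(config.shrna_path)
        meta = read_sample_info(config.sample_info_path)
    return crispr, shrna, meta


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Run every stage and (optionally) write artifacts under ``out_dir``."""
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)

    crispr, shrna, meta = load_inputs(config)
    ca, sa, report = align_screens(crispr, shrna, meta)
    ci, ri = impute_cross_method(ca, sa, seed=stage_seed(config.seed, "impute"))
    combined = combine_scores(ci, ri, config.theta)
    threshold = fit_threshold(combined)
    scores = gene_score_table(combined, threshold, x=config.x_percentile)
    essential = call_essential_genes(scores, threshold)

    ess_matrix = combined.restrict(genes=sorted(essential))
    echodots_cfg = EchodotsConfig(**{
        **config.echodots.to_dict(),
        "d_values": tuple(config.echodots.d_values),
        "base_seed": stage_seed(config.seed, "echodots"),
    })
    clusters = run_echodots(ess_matrix, echodots_cfg)

    if write:
        params = {"theta": config.theta, "x": config.x_percentile,
                  "seed": config.seed}
        combined_path = out / "combined.csv"
        write_matrix_csv(combined, combined_path)
        _sidecar(combined_path, {**params, "stage": "combine",
                                 "alignment": vars(report)})
        (out / "threshold.json").write_text(
            json.dumps(threshold.to_dict(), indent=2) + "\n")
        scores_path = out / "scores.tsv"
        write_table(scores, scores_path)
        _sidecar(scores_path, {**params, "stage": "score",
                               "threshold": threshold.to_dict()})
        clusters_path = out / "clusters.tsv"
        write_table(clusters.assignment, clusters_path)
        _sidecar(clusters_path, {**params, "stage": "cluster",
                                 "echodots": echodots_cfg.to_dict()})
        write_table(clusters.hierarchy.set_index("child"),
                    out / "hierarchy.tsv", index_label="child")
        config.to_yaml(out / "config.yaml")
    return PipelineResult(combined=combined, threshold=threshold,
                          scores=scores, essential_genes=essential,
                          clusters=clusters, report=report)


def summarize(out_dir) -> str:
    """Read-only summary of a finished run's outputs."""
    out = Path(out_dir)
    if not (out / "scores.tsv").exists():
        raise FileNotFoundError(f"no pipeline outputs under {out}")
    scores = pd.read_csv(out / "scores.tsv", sep="\t", index_col=0)
    thr = json.loads((out / "threshold.json").read_text())
    lines = [
        f"threshold: T={thr['T']:.4f} (mu={thr['mu']:.4f}, "
        f"sigma={thr['sigma']:.4f}, theta={thr['theta']})",
        f"genes scored: {len(scores)}",
        f"essential genes: {int((scores['efficacy'] < thr['T']).sum())}",
    ]
    cl_path = out / "clusters.tsv"
    if cl_path.exists():
        cl = pd.read_csv(cl_path, sep="\t", index_col=0)
        for col in cl.columns:
            if col.endswith("_label"):
                prefix = col[:-6]
                n_clusters = cl[col].dropna().nunique()
                noise = float(cl[f"{prefix}_noise"].mean())
                lines.append(f"clusters[{prefix}]: {n_clusters} "
                             f"(noise fraction {noise:.2f})")
    return "\n".join(lines)
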