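"""End-to-end pipeline: config → simulated or loaded inputs → report bundle.

Each stage is an ordinary function reading and writing the TSV/BED/JSON
interchange formats, so the CLI subcommands and :func:`run_pipeline` produce
identical artifacts.  All randomness flows from the single configured seed,
and the summary JSON is written with sorted keys so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io as adio
from .binding import (
    PeakSet,
    binding_calls_table,
    binding_enrichment_in_sets,
    call_body_bound,
    call_promoter_bound,
    cobinding_venn,
    consistent_peaks,
)
from .core import ValidationError
from .model import GermlineAntagonismModel
from .restore import category_enrichment, enrichment_table
from .simulate import SimConfig, simulate_experiment, simulate_peaks


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, loadable from one YAML file."""

    out_dir: str = "antagde_out"
    seed: int = 0
    q_cutoff: float = 0.05
    alpha: float = 1e-3
    normalize: bool = True
    pi0_smoother: str = "poly"
    promoter_window: int = 500
    promoter_min_overlap: int = 200
    body_min_fraction: float = 0.5
    simulate: dict | None = field(default_factory=dict)  # SimConfig overrides; None = use input paths
    inputs: dict = field(default_factory=dict)  # matrix/samples/annotation/calls/peaks paths

    def __post_init__(self) -> None:
        if not 0 < self.q_cutoff <= 1:
            raise ValidationError(f"q_cutoff must be in (0, 1], got {self.q_cutoff}")
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.promoter_min_overlap < 1 or self.promoter_window < 0:
            raise ValidationError("invalid promoter binding parameters")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = asdict(self)
        payload.pop("out_dir", None)
        canon = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Paths and in-memory summary of one pipeline run."""

    out_dir: Path
    summary: dict
    results: object  # GermlineAntagonismResults


def _sim_config(cfg: PipelineConfig) -> SimConfig:
    overrides = dict(cfg.simulate or {})
    overrides.setdefault("seed", cfg.seed)
    return SimConfig(**overrides)


def stage_simulate(cfg: PipelineConfig, out: Path) -> dict:
    """Generate the synthetic bundle and write every interchange file."""
    sim_cfg = _sim_config(cfg)
    matrix, annotation, calls, truth = simulate_experiment(sim_cfg)
    peaks = simulate_peaks(truth, annotation, sim_cfg)
    data = adio.ensure_dir(out / "data")
    adio.write_expression_matrix(matrix, data / "matrix.tsv", data / "samples.tsv")
    adio.write_annotation(annotation, data / "annotation.tsv")
    adio.write_detection_calls(calls, data / "calls.tsv")
    truth_out = truth.table.copy()
    truth_out.index.name = "gene"
    truth_out.to_csv(data / "truth.tsv", sep="\t")
    peaks_dir = adio.ensure_dir(data / "peaks")
    peak_paths: dict[str, list[str]] = {}
    for factor, reps in peaks.items():
        peak_paths[factor] = []
        for ps in reps:
            path = peaks_dir / f"{factor}_{ps.replicate}.bed"
            adio.write_bed(ps.intervals, path)
            peak_paths[factor].append(str(path))
    return {
        "matrix": str(data / "matrix.tsv"),
        "samples": str(data / "samples.tsv"),
        "annotation": str(data / "annotation.tsv"),
        "calls": str(data / "calls.tsv"),
        "truth": str(data / "truth.tsv"),
        "peaks": peak_paths,
    }


def stage_analyze(cfg: PipelineConfig, inputs: dict, out: Path):
    """Normalize, contrast, classify, restore; write tables and summaries."""
    model = GermlineAntagonismModel.from_files(
        inputs["matrix"],
        inputs["samples"],
        inputs["annotation"],
        calls_path=inputs.get("calls"),
        q_cutoff=cfg.q_cutoff,
        alpha=cfg.alpha,
        normalize=cfg.normalize,
        pi0_smoother=cfg.pi0_smoother,
    )
    results = model.fit()
    tables = adio.ensure_dir(out / "tables")
    for label, tab in results.contrasts.items():
        tab.to_csv(tables / f"contrast_{label}.tsv", sep="\t", index=False)
    defining = {
        "mes-4_vs_WT": results.contrasts["mes-4_vs_WT"],
        "double_vs_mes-4": results.contrasts["double_vs_mes-4"],
    }
    for name in ("X-up", "A-up", "A-down", "non-antagonistic"):
        adio.write_gene_set(results.gene_sets[name], defining, tables / f"set_{name}.tsv")
    with open(out / "box_stats.json", "w") as fh:
        json.dump(
            {name: prof.box_stats for name, prof in results.profiles.items()},
            fh, indent=2, sort_keys=True,
        )
    with open(out / "restoration.json", "w") as fh:
        json.dump(
            {
                name: {"verdict": v.verdict, "alpha": v.alpha, "p_values": v.p_values, "medians": v.medians}
                for name, v in results.restoration.items()
            },
            fh, indent=2, sort_keys=True,
        )
    return results


def stage_enrich(cfg: PipelineConfig, inputs: dict, results, out: Path) -> dict:
    """Expression-category enrichment of each antagonistic class."""
    annotation = adio.read_annotation(inputs["annotation"])
    if "category" not in annotation.columns:
        return {}
    universe = annotation.index
    category_map = annotation["category"]
    tables = adio.ensure_dir(out / "tables")
    summaries = {}
    for name in ("X-up", "A-up", "A-down"):
        gs = results.gene_sets[name]
        if len(gs) == 0:
            continue
        res = category_enrichment(gs, category_map, universe)
        enrichment_table(res).to_csv(tables / f"enrichment_{name}.tsv", sep="\t", index=False)
        summaries[name] = {
            r.category: {"observed": r.observed, "expected": r.expected,
                         "p_enrichment": r.p_enrichment, "p_depletion": r.p_depletion}
            for r in res
        }
    return summaries


def stage_bind(cfg: PipelineConfig, inputs: dict, results, out: Path) -> dict:
    """Binding calls, co-binding Venns, and binding enrichment in the classes."""
    peak_paths = inputs.get("peaks") or {}
    if not peak_paths:
        return {}
    annotation = adio.read_annotation(inputs["annotation"])
    universe = frozenset(annotation.index)
    calls = {}
    for factor, paths in peak_paths.items():
        reps = [
            PeakSet(factor=factor, replicate=f"rep{i + 1}", intervals=adio.read_bed(p))
            for i, p in enumerate(paths)
        ]
        merged = consistent_peaks(reps) if len(reps) >= 2 else reps[0]
        promoter = call_promoter_bound(
            merged, annotation, window=cfg.promoter_window, min_overlap=cfg.promoter_min_overlap
        )
        body = call_body_bound(merged, annotation, min_fraction=cfg.body_min_fraction)
        promoter.body_bound = body.body_bound
        promoter.params.update(body.params)
        calls[factor] = promoter
    tables = adio.ensure_dir(out / "tables")
    binding_calls_table(list(calls.values())).to_csv(tables / "binding_calls.tsv", sep="\t")

    summary: dict = {"venns": {}, "enrichment": {}}
    factors = list(calls)
    if "MES-4" in calls:
        for other in factors:
            if other == "MES-4":
                continue
            venn = cobinding_venn(calls["MES-4"], calls[other], universe, "body", "promoter")
            summary["venns"][f"MES-4_body~{other}_promoter"] = {
                "a_only": venn["a_only"], "b_only": venn["b_only"], "both": venn["both"],
                "log10_p": venn["overlap_test"].log10_p,
            }
    class_sets = {k: results.gene_sets[k] for k in ("X-up", "A-up", "A-down") if len(results.gene_sets[k])}
    if class_sets:
        bound_map = {
            f: c.bound_genes("body" if f == "MES-4" else "promoter") for f, c in calls.items()
        }
        enr = binding_enrichment_in_sets(bound_map, class_sets, universe)
        enrichment_table(enr).to_csv(tables / "binding_enrichment.tsv", sep="\t", index=False)
        summary["enrichment"] = {
            r.category: {"observed": r.observed, "expected": r.expected,
                         "p_enrichment": r.p_enrichment, "p_depletion": r.p_depletion}
            for r in enr
        }
    return summary


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Run every stage and write the provenance-stamped report bundle."""
    out = adio.ensure_dir(cfg.out_dir)
    if cfg.simulate is not None:
        inputs = stage_simulate(cfg, out)
    else:
        inputs = dict(cfg.inputs)
        for key in ("matrix", "samples", "annotation"):
            if key not in inputs:
                raise ValidationError(f"pipeline inputs lack {key!r}")
            if not Path(inputs[key]).exists():
                raise ValidationError(f"input path does not exist: {inputs[key]}")
    results = stage_analyze(cfg, inputs, out)
    enrich_summary = stage_enrich(cfg, inputs, results, out)
    bind_summary = stage_bind(cfg, inputs, results, out)

    summary = {
        "analysis": results.summary_dict(),
        "category_enrichment": enrich_summary,
        "binding": bind_summary,
        "provenance": {
            "package": "antagde",
            "version": __version__,
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "q_cutoff": cfg.q_cutoff,
            "alpha": cfg.alpha,
            "promoter_window": cfg.promoter_window,
            "promoter_min_overlap": cfg.promoter_min_overlap,
            "body_min_fraction": cfg.body_min_fraction,
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(out / "summary.txt", "w") as fh:
        fh.write(results.summary())
    return ReportBundle(out_dir=out, summary=summary, results=results)
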