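"""End-to-end pipeline: prep -> network -> modules -> pivots -> DE -> overlap.

A single :class:`PipelineConfig` (YAML-serializable) drives the run; all
randomness flows from one seed fanned out deterministically to stage-local
generators via ``numpy.random.SeedSequence``.  Every stage writes its
artifact to the output directory and contributes record counts to a JSON run
manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expression import ExpressionMatrix
from . import simulate, prep
from .network import load_ppi, edge_correlation, write_network
from .mcl import mcl_cluster
from .modules import (select_functional_modules, find_intermodular_hubs,
                      identify_pivots, pivot_module_report)
from .de import stage_de, venn_overlap

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "load_config", "run_pipeline"]


@dataclass
class SyntheticBlock:
    n_genes: int = 1000
    stages: list[str] = field(default_factory=lambda: list(simulate.EMBRYO_STAGES))
    replicates_per_stage: int = 3
    modules: list[list[float]] = field(default_factory=lambda: [[20, 0.9], [20, 0.9]])
    n_pivots: int = 3
    pivot_companions: int = 0
    noise_sd: float = 0.5
    p_within: float = 0.9
    p_hub_to_module: float = 0.5
    p_background: float = 0.01
    hub_out_edges: int = 2
    terms_per_module: int = 2
    annotation_noise: float = 0.0
    de_spec: dict = field(default_factory=lambda: {"4cell|8cell": [10, 3.0]})


@dataclass
class InputPaths:
    expression: str = ""
    annotation: str = ""
    ppi: str = ""
    go: str = ""
    units: str = "counts"
    lengths: str = ""


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, with the study's default thresholds."""

    seed: int = 0
    out_dir: str = "pivotnet_out"
    synthetic: SyntheticBlock | None = field(default_factory=SyntheticBlock)
    inputs: InputPaths | None = None
    # expression prep
    tpm_threshold: float = 1.0
    replicate_fraction: float = 0.5
    # network
    edge_q_cutoff: float = 0.01
    # modules / pivots
    min_module_size: int = 10
    enrichment_q_cutoff: float = 0.05
    hub_min_degree: int = 10
    pivot_p_cutoff: float = 0.05
    # MCL
    mcl_inflation: float = 2.0
    mcl_expansion: int = 2
    mcl_loop_weight: float = 1.0
    mcl_prune_threshold: float = 1e-5
    mcl_max_iterations: int = 100
    mcl_tolerance: float = 1e-6
    # differential expression
    de_contrasts: list[list[str]] = field(default_factory=lambda: [["4cell", "8cell"]])
    de_q_cutoff: float = 0.05
    de_fc_cutoff: float = 1.4
    ttest_variant: str = "welch"

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def validate_config(config: PipelineConfig) -> list[str]:
    """Return ALL range violations, not just the first."""
    errors = []

    def check(cond: bool, msg: str) -> None:
        if not cond:
            errors.append(msg)

    check((config.synthetic is None) != (config.inputs is None),
          "exactly one of 'synthetic' or 'inputs' must be configured")
    check(config.tpm_threshold >= 0, "tpm_threshold must be >= 0")
    check(0 <= config.replicate_fraction <= 1,
          "replicate_fraction must be in [0, 1]")
    check(0 <= config.edge_q_cutoff <= 1, "edge_q_cutoff must be in [0, 1]")
    check(config.min_module_size >= 1, "min_module_size must be >= 1")
    check(0 <= config.enrichment_q_cutoff <= 1,
          "enrichment_q_cutoff must be in [0, 1]")
    check(config.hub_min_degree >= 1, "hub_min_degree must be >= 1")
    check(0 <= config.pivot_p_cutoff <= 1, "pivot_p_cutoff must be in [0, 1]")
    check(config.mcl_inflation > 0, "mcl_inflation must be positive")
    check(config.mcl_expansion >= 1, "mcl_expansion must be >= 1")
    check(config.mcl_loop_weight > 0, "mcl_loop_weight must be positive")
    check(0 <= config.de_q_cutoff <= 1, "de_q_cutoff must be in [0, 1]")
    check(config.de_fc_cutoff >= 1, "de_fc_cutoff must be >= 1")
    check(config.ttest_variant in ("welch", "student"),
          "ttest_variant must be 'welch' or 'student'")
    if config.synthetic is not None:
        s = config.synthetic
        check(sum(int(m[0]) for m in s.modules) <= s.n_genes,
              "module sizes must not exceed n_genes")
        check(s.replicates_per_stage >= 2, "replicates_per_stage must be >= 2")
        for name in ("p_within", "p_hub_to_module", "p_background",
                     "annotation_noise"):
            check(0 <= getattr(s, name) <= 1, f"{name} must be in [0, 1]")
    return errors


def load_config(path) -> PipelineConfig:
    """Parse a YAML config file; raises with the full error list if invalid."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    synthetic = raw.pop("synthetic", None)
    inputs = raw.pop("inputs", None)
    config = PipelineConfig(
        synthetic=SyntheticBlock(**synthetic) if synthetic is not None else None,
        inputs=InputPaths(**inputs) if inputs is not None else None,
        **raw,
    )
    if synthetic is None and inputs is None:
        config.synthetic = SyntheticBlock()
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid configuration:\n" + "\n".join(f"- {e}" for e in errors))
    return config


def _parse_contrast(key: str) -> tuple[str, str]:
    a, b = key.split("|")
    return a, b


def _load_or_generate(config: PipelineConfig, seeds):
    if config.synthetic is not None:
        s = config.synthetic
        de_spec = {_parse_contrast(k): tuple(v) for k, v in s.de_spec.items()}
        expr, truth = simulate.generate_stage_expression(
            n_genes=s.n_genes, stages=s.stages,
            replicates_per_stage=s.replicates_per_stage,
            modules=[tuple(m) for m in s.modules], de_spec=de_spec,
            noise_sd=s.noise_sd, n_pivots=s.n_pivots,
            pivot_companions=s.pivot_companions, seed=seeds[0],
        )
        ppi_table = simulate.generate_ppi(
            truth, p_within=s.p_within, p_hub_to_module=s.p_hub_to_module,
            p_background=s.p_background, hub_min_degree=config.hub_min_degree,
            hub_out_edges=s.hub_out_edges, seed=seeds[1],
        )
        go_table = simulate.generate_go_annotations(
            truth, terms_per_module=s.terms_per_module,
            annotation_noise=s.annotation_noise, seed=seeds[2],
        )
        return expr, ppi_table, go_table, truth
    paths = config.inputs
    expr = ExpressionMatrix.from_tsv(paths.expression, paths.annotation,
                                     units=paths.units,
                                     lengths_path=paths.lengths or None)
    ppi_table = pd.read_csv(paths.ppi, sep="\t")
    go_table = pd.read_csv(paths.go, sep="\t")
    return expr, ppi_table, go_table, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and return the run manifest."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid configuration:\n" + "\n".join(f"- {e}" for e in errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence(config.seed).spawn(4)]
    manifest: dict = {
        "pivotnet_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "counts": {},
    }
    counts = manifest["counts"]

    # --- inputs -------------------------------------------------------------
    stage = "inputs"
    try:
        expr, ppi_table, go_table, truth = _load_or_generate(config, seeds)
        expr.to_tsv(out / "expression.tsv", out / "samples.tsv")
        ppi_table.to_csv(out / "ppi.tsv", sep="\t", index=False)
        go_table.to_csv(out / "go_annotations.tsv", sep="\t", index=False)
        if truth is not None:
            truth.to_json(out / "truth.json")
        counts["genes_input"] = len(expr.gene_ids)
        counts["ppi_edges_input"] = len(ppi_table)

        # --- prep -------------------------------------------------------------
        stage = "prep"
        if expr.units == "counts" and expr.lengths is not None:
            tpm = prep.compute_tpm(expr)
        elif expr.units == "TPM":
            tpm = expr
        else:
            raise ValueError(f"cannot normalize units {expr.units!r} without lengths")
        expressed = prep.filter_expressed(tpm, threshold=config.tpm_threshold,
                                          replicate_fraction=config.replicate_fraction)
        tpm = tpm.subset_genes(expressed)
        log_expr = prep.log2_transform(tpm)
        tpm.to_tsv(out / "tpm_filtered.tsv", out / "samples.tsv")
        counts["genes_expressed"] = len(expressed)

        # --- network ------------------------------------------------------------
        stage = "network"
        ppi = load_ppi(ppi_table)
        coexpr = edge_correlation(ppi, log_expr, q_cutoff=config.edge_q_cutoff)
        write_network(coexpr, out / "coexpression_network.tsv",
                      out / "coexpression_network.gml")
        counts["ppi_edges_deduplicated"] = ppi.number_of_edges()
        counts["edges_tested"] = coexpr.graph["n_tested"]
        counts["edges_retained"] = coexpr.number_of_edges()
        counts["network_nodes"] = coexpr.number_of_nodes()

        # --- modules ------------------------------------------------------------
        stage = "modules"
        if coexpr.number_of_nodes() > 0:
            clusters = mcl_cluster(
                coexpr, inflation=config.mcl_inflation,
                expansion=config.mcl_expansion,
                loop_weight=config.mcl_loop_weight,
                prune_threshold=config.mcl_prune_threshold,
                max_iterations=config.mcl_max_iterations,
                tolerance=config.mcl_tolerance,
            )
            universe = set(coexpr.nodes)
            modules = select_functional_modules(
                clusters, go_table, universe,
                min_size=config.min_module_size,
                q_cutoff=config.enrichment_q_cutoff,
            )
        else:
            from .modules import ModuleSet
            clusters, modules = [], ModuleSet([], [], [])
        modules.to_frame().to_csv(out / "clusters.tsv", sep="\t", index=False)
        modules.enrichment_frame().to_csv(out / "module_enrichment.tsv", sep="\t",
                                          index=False)
        counts["clusters"] = len(clusters)
        counts["functional_modules"] = len(modules.functional_indices)

        # --- pivots -------------------------------------------------------------
        stage = "pivots"
        hubs = find_intermodular_hubs(coexpr, modules,
                                      min_degree=config.hub_min_degree)
        pivots = identify_pivots(hubs, coexpr, modules,
                                 p_cutoff=config.pivot_p_cutoff)
        report = pivot_module_report(pivots, modules, coexpr)
        report.to_csv(out / "pivot_report.tsv", sep="\t", index=False)
        counts["intermodular_hubs"] = len(hubs)
        counts["pivot_genes"] = len(pivots)
        manifest["pivots"] = sorted(p.gene for p in pivots)

        # --- differential expression ---------------------------------------------
        stage = "de"
        de_tables = {}
        for a, b in config.de_contrasts:
            de = stage_de(tpm, a, b, q_cutoff=config.de_q_cutoff,
                          fc_cutoff=config.de_fc_cutoff,
                          variant=config.ttest_variant)
            de_tables[(a, b)] = de
            de.to_csv(out / f"de_{a}_vs_{b}.tsv", sep="\t")
            counts[f"de_genes_{a}_vs_{b}"] = int(de["significant"].sum())

        # --- overlap --------------------------------------------------------------
        stage = "venn"
        if len(de_tables) >= 2:
            for direction in ("up", "down"):
                gene_sets = [
                    set(t.index[t["significant"] & (t["direction"] == direction)])
                    for t in de_tables.values()
                ]
                labels = [f"{a}_vs_{b}" for a, b in de_tables]
                summary = venn_overlap(gene_sets, labels)
                with open(out / f"venn_{direction}.json", "w") as fh:
                    json.dump(summary.to_dict(), fh, indent=1)
                counts[f"venn_{direction}_union"] = summary.union
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest
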