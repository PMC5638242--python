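"""End-to-end orchestration: screens -> expression -> regulatory -> flow -> significance.

A single YAML config names the six inputs and all stage thresholds (each
defaulting to the published analysis values). Every stage writes its
intermediate artifact to the output directory, and a JSON manifest records
input hashes, parameters, library versions and seeds so a rerun with the
same config reproduces the same outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io as pio
from . import expression as expr_mod
from . import regulatory as reg_mod
from . import screens
from . import significance as sig_mod
from .exceptions import PolyflowError, ValidationError
from .flow import FlowParams, DEFAULT_EXCLUDED_NODES

STAGES = ["screen_hits", "expression", "regulatory_network", "flow_model", "significance"]


@dataclass
class PipelineConfig:
    # input paths
    screen: str
    activity: str
    sirna: str
    expression: str
    interactome: str
    outdir: str
    regulatory: str | None = None  # prebuilt TF->gene TSV ...
    genome: str | None = None  # ... or build it from these four
    peaks: list[str] = field(default_factory=list)
    pwms: str | None = None
    tss: str | None = None
    expressed_genes: str | None = None  # optional explicit list for kinase filter
    # stage thresholds (published defaults)
    toxicity_floor_lu: float = screens.TOXICITY_FLOOR_LU
    reduction_threshold: float = screens.REDUCTION_THRESHOLD
    activity_change_threshold: float = screens.ACTIVITY_CHANGE_THRESHOLD
    genetic_fdr_max: float = screens.GENETIC_FDR_MAX
    genetic_si_deviation_min: float = screens.GENETIC_SI_DEVIATION_MIN
    genetic_survival_min: float = screens.GENETIC_SURVIVAL_MIN
    validated_capacity: float = screens.VALIDATED_CAPACITY
    genetic_capacity_mode: str = "si"
    q_max: float = expr_mod.Q_MAX
    fc_min: float = expr_mod.FC_MIN
    fpkm_floor: float = expr_mod.FPKM_FLOOR
    delta_fpkm_min: float = expr_mod.DELTA_FPKM_MIN
    tss_window: int = reg_mod.DEFAULT_TSS_WINDOW
    # flow / significance
    gamma: float = 20.0
    edge_capacity: float = 0.005
    flow_tolerance: float = 1e-8
    excluded_nodes: list[str] = field(default_factory=lambda: sorted(DEFAULT_EXCLUDED_NODES))
    n_random: int = 100
    p_max: float = sig_mod.P_MAX
    evidence_min: int = sig_mod.EVIDENCE_MIN
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def flow_params(self) -> FlowParams:
        return FlowParams(
            gamma=self.gamma,
            edge_capacity=self.edge_capacity,
            flow_tolerance=self.flow_tolerance,
            excluded_nodes=frozenset(n.upper() for n in self.excluded_nodes),
        )

    def input_paths(self) -> dict[str, str]:
        paths = {
            "screen": self.screen,
            "activity": self.activity,
            "sirna": self.sirna,
            "expression": self.expression,
            "interactome": self.interactome,
        }
        if self.regulatory:
            paths["regulatory"] = self.regulatory
        else:
            for name in ("genome", "pwms", "tss"):
                value = getattr(self, name)
                if value:
                    paths[name] = value
            for i, p in enumerate(self.peaks):
                paths[f"peaks_{i}"] = p
        if self.expressed_genes:
            paths["expressed_genes"] = self.expressed_genes
        return paths


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_inputs(config: PipelineConfig) -> dict:
    """Format and consistency checks; returns {'errors': [...], 'warnings': [...]}."""
    errors: list[str] = []
    warns: list[str] = []
    for name, path in config.input_paths().items():
        if not Path(path).exists():
            errors.append(f"{name}: file not found: {path}")
    if not config.regulatory and not (
        config.genome and config.pwms and config.tss and config.peaks
    ):
        errors.append("either a regulatory TSV or genome+peaks+pwms+tss must be given")
    if errors:
        return {"errors": errors, "warnings": warns}

    try:
        interactome = pio.read_interactome(config.interactome)
        bad = interactome[
            (interactome["confidence"] <= 0) | (interactome["confidence"] > 1)
        ]
        if len(bad):
            errors.append(f"interactome: {len(bad)} confidences outside (0, 1]")
        sirna = pio.read_sirna_table(config.sirna)
        if (sirna["si"] <= 0).any():
            errors.append("siRNA table contains non-positive SI values")
        pio.read_expression_table(config.expression)
        pio.read_screen_table(config.screen)
        pio.read_activity_matrix(config.activity)
        nodes = set(interactome["protein_a"]) | set(interactome["protein_b"])
        hits = set(sirna.loc[sirna["fdr"] < config.genetic_fdr_max, "gene"])
        if hits and not (hits & nodes):
            errors.append("no overlap between screen hit symbols and interactome nodes")
        if config.regulatory:
            pio.read_regulatory(config.regulatory)
        else:
            reg_mod.read_transfac_pwms(config.pwms)
            for p in config.peaks:
                bed = pio.read_bed(p)
                if not bed[["chrom", "start"]].equals(
                    bed.sort_values(["chrom", "start"])[["chrom", "start"]].reset_index(drop=True)
                ):
                    warns.append(f"peak file {p} is not coordinate-sorted")
            pio.read_tss_bed(config.tss)
    except PolyflowError as exc:
        errors.append(str(exc))
    except OSError as exc:
        errors.append(f"I/O error: {exc}")
    return {"errors": errors, "warnings": warns}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all five stages; returns the run manifest (also written to disk).

    A stage failure writes a ``<stage>.failed`` marker, keeps earlier
    outputs, and re-raises with the failing stage named.
    """
    report = validate_inputs(config)
    if report["errors"]:
        raise ValidationError("; ".join(report["errors"]))
    for w in report["warnings"]:
        warnings.warn(w)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "inputs": {k: _sha256(v) for k, v in config.input_paths().items()},
        "parameters": asdict(config),
        "versions": _versions(),
        "stages": [],
    }
    state: dict = {}
    for stage in STAGES:
        t0 = time.perf_counter()
        try:
            outputs = _STAGE_FUNCS[stage](config, state, outdir)
        except Exception as exc:
            (outdir / f"{stage}.failed").write_text(str(exc))
            raise PolyflowError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"].append(
            {
                "name": stage,
                "outputs": outputs,
                "seconds": round(time.perf_counter() - t0, 3),
            }
        )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _versions() -> dict:
    import numpy, scipy, networkx
    from importlib.metadata import version

    return {
        "polyflow": version("polyflow"),
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "networkx": networkx.__version__,
    }


def _stage_screen_hits(config: PipelineConfig, state: dict, outdir: Path) -> list[str]:
    screen = pio.read_screen_table(config.screen)
    calls = screens.call_inhibitor_hits(
        screen, config.toxicity_floor_lu, config.reduction_threshold
    )
    calls_df = pd.DataFrame(
        [(c.inhibitor, c.excluded_reason, c.max_reduction, c.is_hit) for c in calls],
        columns=["inhibitor", "excluded_reason", "max_reduction", "is_hit"],
    )
    hit_inhibitors = [c.inhibitor for c in calls if c.is_hit]
    profiles = pio.read_activity_matrix(config.activity)
    if config.expressed_genes:
        expressed = pio.read_gene_list(config.expressed_genes)
    else:
        expr = pio.read_expression_table(config.expression)
        expressed = set(
            expr.loc[expr[["fpkm_a", "fpkm_b"]].max(axis=1) >= config.fpkm_floor, "gene"]
        )
    kinase_hits = screens.map_kinase_hits(
        hit_inhibitors, profiles, expressed, config.activity_change_threshold
    )
    genetic_hits = screens.select_genetic_hits(
        pio.read_sirna_table(config.sirna),
        config.genetic_fdr_max,
        config.genetic_si_deviation_min,
        config.genetic_survival_min,
        config.validated_capacity,
        config.genetic_capacity_mode,
    )
    pio.write_table(calls_df, outdir / "inhibitor_calls.tsv")
    pio.write_input_nodes(kinase_hits, outdir / "kinase_hits.tsv")
    pio.write_input_nodes(genetic_hits, outdir / "genetic_hits.tsv")
    state.update(kinase_hits=kinase_hits, genetic_hits=genetic_hits)
    return ["inhibitor_calls.tsv", "kinase_hits.tsv", "genetic_hits.tsv"]


def _stage_expression(config: PipelineConfig, state: dict, outdir: Path) -> list[str]:
    table = pio.read_expression_table(config.expression)
    de = expr_mod.select_de_genes(
        table, config.q_max, config.fc_min, config.fpkm_floor, config.delta_fpkm_min
    )
    pio.write_input_nodes(de, outdir / "de_genes.tsv")
    state["de_genes"] = de
    return ["de_genes.tsv"]


def _stage_regulatory(config: PipelineConfig, state: dict, outdir: Path) -> list[str]:
    if config.regulatory:
        reg = pio.read_regulatory(config.regulatory)
        state["regulatory"] = reg
        pio.write_table(reg, outdir / "regulatory_edges.tsv")
        return ["regulatory_edges.tsv"]
    genome = pio.read_fasta(config.genome)
    peak_sets = [pio.read_bed(p) for p in config.peaks]
    master = reg_mod.merge_peak_sets(peak_sets)
    pwms = reg_mod.read_transfac_pwms(config.pwms)
    tss = pio.read_tss_bed(config.tss)
    matches = reg_mod.scan_motifs(genome, master, pwms)
    reg = reg_mod.build_tf_gene_network(matches, tss, config.tss_window)
    # enrichment background: genes with >= 1 master peak within the TSS window
    background = set()
    for _, g in tss.iterrows():
        sub = master[master["chrom"] == g["chrom"]]
        lo, hi = g["tss"] - config.tss_window, g["tss"] + config.tss_window
        if ((sub["end"] > lo) & (sub["start"] < hi)).any():
            background.add(g["gene"])
    de_names = {n.name for n in state["de_genes"]}
    enrich = reg_mod.tf_enrichment(reg, de_names, background)
    pio.write_table(master, outdir / "master_peaks.tsv")
    pio.write_table(reg, outdir / "regulatory_edges.tsv")
    pio.write_table(enrich, outdir / "tf_enrichment.tsv")
    state["regulatory"] = reg
    return ["master_peaks.tsv", "regulatory_edges.tsv", "tf_enrichment.tsv"]


def _stage_flow(config: PipelineConfig, state: dict, outdir: Path) -> list[str]:
    from .flow import solve

    interactome = pio.read_interactome(config.interactome)
    state["interactome"] = interactome
    solution = solve(
        state["kinase_hits"],
        state["genetic_hits"],
        state["de_genes"],
        interactome,
        state["regulatory"],
        config.flow_params(),
    )
    state["solution"] = solution
    pio.write_table(solution.edges, outdir / "solution_edges.tsv")
    sif = solution.edges[solution.edges["kind"].isin(["ppi", "reg"])]
    with open(outdir / "solution.sif", "w") as fh:
        for _, e in sif.iterrows():
            fh.write(f"{e['source']}\t{e['commodity']}\t{e['target']}\n")
    node_rows = [
        (node, *(flows.get(k, 0.0) for k in solution.commodities))
        for node, flows in sorted(solution.node_flow.items())
    ]
    nodes_df = pd.DataFrame(
        node_rows, columns=["node"] + [f"flow_{k}" for k in solution.commodities]
    )
    pio.write_table(nodes_df, outdir / "solution_nodes.tsv")
    return ["solution_edges.tsv", "solution.sif", "solution_nodes.tsv"]


def _stage_significance(config: PipelineConfig, state: dict, outdir: Path) -> list[str]:
    table, _ = sig_mod.assess_nodes(
        state["kinase_hits"],
        state["genetic_hits"],
        state["de_genes"],
        state["interactome"],
        state["regulatory"],
        config.flow_params(),
        n_random=config.n_random,
        seed=config.seed,
        p_max=config.p_max,
        evidence_min=config.evidence_min,
    )
    candidates = sig_mod.select_candidates(table, config.p_max, config.evidence_min)
    table.to_csv(outdir / "node_assessment.tsv", sep="\t", index=False, na_rep="NA")
    candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False, na_rep="NA")
    state["assessment"] = table
    return ["node_assessment.tsv", "candidates.tsv"]


_STAGE_FUNCS = {
    "screen_hits": _stage_screen_hits,
    "expression": _stage_expression,
    "regulatory_network": _stage_regulatory,
    "flow_model": _stage_flow,
    "significance": _stage_significance,
}
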