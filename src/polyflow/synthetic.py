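"""Ground-truthed synthetic scenarios for the whole pipeline.

A scenario emulates all six inputs the analysis consumes — a two-arm
inhibitor viability screen, an inhibitor x kinase activity matrix, an siRNA
screen table, a differential-expression table, an open-chromatin layer
(genome, peaks, PWMs, TSS annotation) and a weighted protein-protein
interactome — with planted structure: known synergizing inhibitors whose
drug-arm dose-response drops well below the vehicle arm, known genetic hits
passing the SI/FDR/survival filters, and signaling paths from hits through
high-confidence interactome edges to TFs whose motifs are planted in peaks
near the TSSs of planted differentially expressed genes.

The interactome is a preferential-attachment (Barabasi-Albert) graph, giving
the heavy-tailed degree distribution of curated interactomes together with a
connectivity guarantee; edge confidences are Beta(4, 2) by default,
right-skewed toward high confidence. The chemical screen uses 8 inhibitor
concentrations log-spaced over 3 decades with 2 replicates per point.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import networkx as nx
import pandas as pd

from .exceptions import ConfigurationError, SizingError
from .regulatory import ALPHABET, PWM
from . import io as pio

CONCENTRATIONS = np.logspace(-2, 1, 8)  # uM, 3 decades

# dose-response curve parameters (LU scale); vehicle arm stays above the
# 50 000 LU toxicity floor except for designated toxic decoys
VEHICLE_CURVE = dict(b=1.3, c=75_000.0, d=110_000.0, e=0.3)
SYNERGIZER_GEM_CURVE = dict(b=1.3, c=30_000.0, d=100_000.0, e=0.2)
TOXIC_VEHICLE_CURVE = dict(b=1.3, c=30_000.0, d=110_000.0, e=0.3)

GENE_SPACING = 12_000
FIRST_TSS = 6_000
PEAK_WIDTH = 200
MOTIF_LENGTH = 8


@dataclass
class ScenarioConfig:
    n_proteins: int = 200
    n_tfs: int = 20
    n_genes: int = 100
    n_inhibitors: int = 20
    n_planted_synergizers: int = 3
    n_planted_genetic_hits: int = 15
    n_planted_paths: int = 8
    path_length: int = 2  # interactome hops from hit to TF
    noise_sd_lu: float = 3000.0
    confidence_beta_params: tuple[float, float] = (4.0, 2.0)
    seed: int = 0
    attachment_m: int = 2
    n_toxic_decoys: int = 2
    targets_per_tf: int = 2
    extra_targets_per_tf: int = 2

    def validate(self) -> None:
        counts = dict(
            n_proteins=self.n_proteins,
            n_tfs=self.n_tfs,
            n_genes=self.n_genes,
            n_inhibitors=self.n_inhibitors,
            n_planted_synergizers=self.n_planted_synergizers,
            n_planted_genetic_hits=self.n_planted_genetic_hits,
            n_planted_paths=self.n_planted_paths,
            path_length=self.path_length,
        )
        for name, value in counts.items():
            if value < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {value}")
        if self.n_planted_synergizers + self.n_toxic_decoys > self.n_inhibitors:
            raise ConfigurationError(
                "n_planted_synergizers + toxic decoys exceed n_inhibitors"
            )
        a, b = self.confidence_beta_params
        if a <= 0 or b <= 0:
            raise ConfigurationError("confidence beta shape parameters must be positive")
        if self.noise_sd_lu < 0:
            raise ConfigurationError("noise_sd_lu must be non-negative")

    @property
    def proteins(self) -> list[str]:
        return [f"P{i:04d}" for i in range(self.n_proteins)]

    @property
    def tfs(self) -> list[str]:
        return [f"TF{i:03d}" for i in range(self.n_tfs)]

    @property
    def genes(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    @property
    def inhibitors(self) -> list[str]:
        return [f"INH{i:03d}" for i in range(self.n_inhibitors)]


@dataclass
class Truth:
    """Planted ground truth for a scenario."""

    synergizers: list[str]
    toxic_decoys: list[str]
    kinase_hits: dict[str, float]  # kinase -> percent activity under a synergizer
    genetic_hits: list[str]
    validated_genetic_hits: list[str]
    paths: list[list[str]]  # hit, intermediates..., terminal TF
    intermediates: list[str]
    de_genes: dict[str, str]  # gene -> up/down
    regulatory_edges: list[tuple[str, str, float]]
    expressed_genes: list[str]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class SyntheticScenario:
    config: ScenarioConfig
    interactome: pd.DataFrame
    regulatory_edges: pd.DataFrame
    screen_table: pd.DataFrame
    activity_matrix: pd.DataFrame
    sirna_table: pd.DataFrame
    expression_table: pd.DataFrame
    genome: dict[str, str]
    peaks: pd.DataFrame
    tss: pd.DataFrame
    pwms: list[PWM]
    truth: Truth


def weibull_curve(x, b, c, d, e):
    x = np.asarray(x, dtype=float)
    return c + (d - c) * np.exp(-np.exp(b * (np.log(x) - np.log(e))))


def _child_rng(config: ScenarioConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def generate_interactome(config: ScenarioConfig) -> pd.DataFrame:
    """Connected preferential-attachment graph over proteins and TFs.

    TF labels are scattered over the degree distribution by a random label
    permutation. Confidences are Beta(a, b) draws in (0, 1).
    """
    config.validate()
    rng = _child_rng(config, 0)
    labels = config.proteins + config.tfs
    n = len(labels)
    if n <= config.attachment_m:
        raise ConfigurationError("need more nodes than the attachment parameter")
    g = nx.barabasi_albert_graph(n, config.attachment_m, seed=int(rng.integers(2**31)))
    perm = rng.permutation(n)
    a, b = config.confidence_beta_params
    rows = []
    for u, v in sorted(g.edges()):
        conf = float(np.clip(rng.beta(a, b), 1e-6, 1.0))
        rows.append((labels[perm[u]], labels[perm[v]], conf))
    return pd.DataFrame(rows, columns=["protein_a", "protein_b", "confidence"])


def plant_pathways(
    interactome: pd.DataFrame, config: ScenarioConfig
) -> tuple[pd.DataFrame, Truth]:
    """Plant hits, signaling paths and regulatory targets; returns the
    augmented interactome (missing path edges added at confidence >= 0.97)
    and the ground truth."""
    config.validate()
    rng = _child_rng(config, 1)
    proteins, tfs, genes = config.proteins, config.tfs, config.genes

    n_kinase_hits = max(1, (config.n_planted_paths + 1) // 2)
    n_intermediates = (config.path_length - 1) * config.n_planted_paths
    need = n_kinase_hits + config.n_planted_genetic_hits + n_intermediates
    if need > config.n_proteins:
        raise SizingError(
            f"{config.n_proteins} proteins cannot host {need} planted roles"
        )
    if config.n_planted_paths > config.n_tfs * 4:
        raise SizingError("too many planted paths for the TF pool")

    picked = [str(p) for p in rng.choice(proteins, size=need, replace=False)]
    kinase_hit_names = sorted(picked[:n_kinase_hits])
    genetic_hits = sorted(picked[n_kinase_hits : n_kinase_hits + config.n_planted_genetic_hits])
    intermediate_pool = list(picked[n_kinase_hits + config.n_planted_genetic_hits :])

    path_tfs = [tfs[i % config.n_tfs] for i in range(config.n_planted_paths)]
    paths = []
    for i in range(config.n_planted_paths):
        start = (
            kinase_hit_names[(i // 2) % len(kinase_hit_names)]
            if i % 2 == 0
            else genetic_hits[(i // 2) % len(genetic_hits)]
        )
        inters = [
            intermediate_pool.pop() for _ in range(config.path_length - 1)
        ]
        paths.append([start] + inters + [path_tfs[i]])

    # ensure planted routes exist and are low-cost
    und = {}
    for a_, b_, conf in zip(
        interactome["protein_a"], interactome["protein_b"], interactome["confidence"]
    ):
        key = (a_, b_) if a_ <= b_ else (b_, a_)
        und[key] = max(und.get(key, 0.0), float(conf))
    for path in paths:
        for u, v in zip(path[:-1], path[1:]):
            key = (u, v) if u <= v else (v, u)
            conf = float(rng.uniform(0.97, 0.995))
            und[key] = max(und.get(key, 0.0), conf)
    interactome = pd.DataFrame(
        [(a_, b_, c_) for (a_, b_), c_ in sorted(und.items())],
        columns=["protein_a", "protein_b", "confidence"],
    )

    # regulatory layer: planted DE targets per path TF, plus decoy targets
    gene_pool = list(rng.permutation(genes))
    de_genes: dict[str, str] = {}
    reg_edges: list[tuple[str, str, float]] = []
    for tf in dict.fromkeys(path_tfs):  # unique, order-preserving
        for _ in range(config.targets_per_tf):
            if not gene_pool:
                raise SizingError("gene universe too small for planted targets")
            gene = gene_pool.pop()
            de_genes[gene] = "up" if rng.random() < 0.7 else "down"
            reg_edges.append((tf, gene, 1.0))
    for tf in tfs:
        for _ in range(config.extra_targets_per_tf):
            gene = str(rng.choice(genes))
            if (tf, gene) not in {(t, g) for t, g, _ in reg_edges}:
                reg_edges.append((tf, gene, 1.0))

    intermediates = sorted(
        {node for path in paths for node in path[1:-1]}
    )
    syn = list(config.inhibitors[: config.n_planted_synergizers])
    toxic = list(
        config.inhibitors[
            config.n_planted_synergizers : config.n_planted_synergizers
            + config.n_toxic_decoys
        ]
    )
    kinase_hits = {
        name: float(rng.uniform(0.0, 45.0)) if i % 4 else float(rng.uniform(155.0, 180.0))
        for i, name in enumerate(kinase_hit_names)
    }
    validated = genetic_hits[::3]
    truth = Truth(
        synergizers=syn,
        toxic_decoys=toxic,
        kinase_hits=kinase_hits,
        genetic_hits=genetic_hits,
        validated_genetic_hits=validated,
        paths=paths,
        intermediates=intermediates,
        de_genes=de_genes,
        regulatory_edges=sorted(reg_edges),
        expressed_genes=sorted(proteins + tfs),
    )
    return interactome, truth


def generate_screen_table(config: ScenarioConfig, truth: Truth) -> pd.DataFrame:
    """Two-arm viability screen with Weibull-shaped dose responses.

    Planted synergizers' drug arm sits >= 40% below the vehicle arm at the
    top concentrations; non-synergizers share one curve in both arms; toxic
    decoys dip below 50 000 LU in the vehicle arm.
    """
    rng = _child_rng(config, 2)
    rows = []
    for inhibitor in config.inhibitors:
        toxic = inhibitor in truth.toxic_decoys
        synergizer = inhibitor in truth.synergizers
        veh_curve = TOXIC_VEHICLE_CURVE if toxic else VEHICLE_CURVE
        gem_curve = SYNERGIZER_GEM_CURVE if synergizer else veh_curve
        for conc in CONCENTRATIONS:
            means = {
                "vehicle": float(weibull_curve(conc, **veh_curve)),
                "gemcitabine": float(weibull_curve(conc, **gem_curve)),
            }
            for arm, mean in means.items():
                for rep in (1, 2):
                    lu = mean + rng.normal(0.0, config.noise_sd_lu) if config.noise_sd_lu else mean
                    rows.append((inhibitor, float(conc), arm, rep, max(float(lu), 0.0)))
    return pd.DataFrame(
        rows, columns=["inhibitor", "concentration", "arm", "replicate", "lu"]
    )


def generate_activity_matrix(config: ScenarioConfig, truth: Truth) -> pd.DataFrame:
    """Inhibitor x kinase percent-activity matrix (100 = untreated).

    Planted kinase hits get their planted activity under an assigned
    synergizer; everything else hovers near 100. One non-synergizer decoy
    inhibitor strongly affects a few non-planted kinases, which must not
    become hits downstream.
    """
    rng = _child_rng(config, 3)
    hit_names = sorted(truth.kinase_hits)
    others = [p for p in config.proteins if p not in truth.kinase_hits]
    profiled = hit_names + sorted(rng.choice(others, size=min(30, len(others)), replace=False))
    mat = pd.DataFrame(
        np.clip(rng.normal(100.0, 5.0, size=(config.n_inhibitors, len(profiled))), 0, None),
        index=config.inhibitors,
        columns=profiled,
    )
    for i, kinase in enumerate(hit_names):
        synergizer = truth.synergizers[i % len(truth.synergizers)]
        mat.loc[synergizer, kinase] = truth.kinase_hits[kinase]
    decoys = [i for i in config.inhibitors if i not in truth.synergizers]
    if decoys and len(profiled) > len(hit_names):
        decoy_inh = decoys[-1]
        for kinase in profiled[len(hit_names) :][:3]:
            mat.loc[decoy_inh, kinase] = float(rng.uniform(0.0, 30.0))
    return mat.round(2)


def generate_expression_and_sirna_tables(
    config: ScenarioConfig, truth: Truth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression and siRNA tables where planted rows pass every filter and
    every decoy row violates at least one criterion."""
    rng = _child_rng(config, 4)

    expr_rows = []
    decoy_modes = ["q", "fc", "floor", "delta"]
    for i, gene in enumerate(config.genes):
        if gene in truth.de_genes:
            a = float(rng.uniform(2.0, 20.0))
            fc = float(rng.uniform(2.0, 6.0))
            b = a * fc if truth.de_genes[gene] == "up" else a / fc
            q = float(rng.uniform(0.001, 0.01))
        else:
            mode = decoy_modes[i % len(decoy_modes)]
            if mode == "q":
                a, b, q = 5.0, 15.0, float(rng.uniform(0.2, 0.9))
            elif mode == "fc":
                a, b, q = 10.0, 12.0, float(rng.uniform(0.001, 0.01))
            elif mode == "floor":
                a, b, q = 0.02, 0.08, float(rng.uniform(0.001, 0.01))
            else:  # high fold change but tiny absolute difference
                a, b, q = 0.15, 0.6, float(rng.uniform(0.001, 0.01))
        fold = b / a if a > 0 else np.inf
        expr_rows.append((gene, round(a, 4), round(b, 4), round(fold, 4), round(q, 5)))
    expression = pd.DataFrame(expr_rows, columns=pio.EXPRESSION_COLUMNS)

    sirna_rows = []
    hit_set = set(truth.genetic_hits)
    validated = set(truth.validated_genetic_hits)
    violations = ["fdr", "si", "survival"]
    for i, gene in enumerate(config.proteins):
        if gene in hit_set:
            enhancer = rng.random() < 0.7
            si = 1.0 + float(rng.uniform(0.35, 1.0)) if enhancer else float(
                rng.uniform(0.3, 0.65)
            )
            fdr = float(rng.uniform(0.001, 0.04))
            survival = float(rng.uniform(0.55, 0.95))
        else:
            mode = violations[i % len(violations)]
            si = 1.0 + float(rng.uniform(-0.25, 0.25)) if mode == "si" else 1.0 + float(
                rng.choice([-1, 1]) * rng.uniform(0.35, 0.9)
            )
            fdr = float(rng.uniform(0.1, 0.9)) if mode == "fdr" else float(
                rng.uniform(0.001, 0.04)
            )
            survival = float(rng.uniform(0.05, 0.45)) if mode == "survival" else float(
                rng.uniform(0.55, 0.95)
            )
        sirna_rows.append(
            (gene, round(si, 4), round(fdr, 5), round(survival, 4), gene in validated)
        )
    sirna = pd.DataFrame(sirna_rows, columns=pio.SIRNA_COLUMNS)
    return expression, sirna


def generate_regulatory_artifacts(
    config: ScenarioConfig, truth: Truth
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame, list[PWM]]:
    """Genome, TSS annotation, peak set and PWMs realizing the planted
    TF->gene edges: each edge gets a peak near its target's TSS containing
    the TF's motif consensus (on a random strand)."""
    rng = _child_rng(config, 5)
    chrom = "chr1"
    length = FIRST_TSS + config.n_genes * GENE_SPACING + FIRST_TSS
    seq = rng.choice(list(ALPHABET), size=length)

    tss = pd.DataFrame(
        {
            "gene": config.genes,
            "chrom": chrom,
            "tss": [FIRST_TSS + i * GENE_SPACING for i in range(config.n_genes)],
            "strand": "+",
        }
    )
    tss_pos = dict(zip(tss["gene"], tss["tss"]))

    pwms = []
    consensus = {}
    for tf in config.tfs:
        bases = rng.choice(list(ALPHABET), size=MOTIF_LENGTH)
        matrix = np.full((MOTIF_LENGTH, 4), 0.02)
        for j, base in enumerate(bases):
            matrix[j, ALPHABET.index(base)] = 0.94
        pwms.append(PWM(tf=tf, matrix=matrix, threshold=0.85))
        consensus[tf] = "".join(bases)

    comp = str.maketrans("ACGT", "TGCA")
    peak_rows = []
    per_gene_count: dict[str, int] = {}
    for tf, gene, _ in truth.regulatory_edges:
        idx = per_gene_count.get(gene, 0)
        per_gene_count[gene] = idx + 1
        start = tss_pos[gene] - 3500 + idx * (PEAK_WIDTH + 100)
        motif = consensus[tf]
        if rng.random() < 0.5:
            motif = motif.translate(comp)[::-1]
        offset = start + 60 + int(rng.integers(0, PEAK_WIDTH - 60 - MOTIF_LENGTH))
        seq[offset : offset + MOTIF_LENGTH] = list(motif)
        peak_rows.append((chrom, start, start + PEAK_WIDTH))
    # background peaks outside every TSS window
    for i in range(0, config.n_genes, 5):
        start = FIRST_TSS + i * GENE_SPACING + 5600
        peak_rows.append((chrom, start, start + PEAK_WIDTH))
    peaks = (
        pd.DataFrame(sorted(set(peak_rows)), columns=["chrom", "start", "end"])
        .reset_index(drop=True)
    )
    return {chrom: "".join(seq)}, tss, peaks, pwms


def generate_scenario(config: ScenarioConfig) -> SyntheticScenario:
    """Deterministic full scenario for a given config (seed included)."""
    config.validate()
    interactome = generate_interactome(config)
    interactome, truth = plant_pathways(interactome, config)
    screen = generate_screen_table(config, truth)
    activity = generate_activity_matrix(config, truth)
    expression, sirna = generate_expression_and_sirna_tables(config, truth)
    genome, tss, peaks, pwms = generate_regulatory_artifacts(config, truth)
    regulatory = pd.DataFrame(
        truth.regulatory_edges, columns=["tf", "gene", "weight"]
    )
    return SyntheticScenario(
        config=config,
        interactome=interactome,
        regulatory_edges=regulatory,
        screen_table=screen,
        activity_matrix=activity,
        sirna_table=sirna,
        expression_table=expression,
        genome=genome,
        peaks=peaks,
        tss=tss,
        pwms=pwms,
        truth=truth,
    )


def write_scenario(scenario: SyntheticScenario, outdir) -> dict[str, str]:
    """Write every input artifact plus the truth JSON; returns the path map."""
    from .regulatory import write_transfac_pwms

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "interactome": out / "interactome.tsv",
        "regulatory": out / "regulatory.tsv",
        "screen": out / "screen.tsv",
        "activity": out / "activity.tsv",
        "sirna": out / "sirna.tsv",
        "expression": out / "expression.tsv",
        "genome": out / "genome.fa",
        "peaks": out / "peaks.bed",
        "tss": out / "tss.bed",
        "pwms": out / "pwms.prf",
        "expressed": out / "expressed_genes.txt",
        "truth": out / "truth.json",
    }
    pio.write_gene_list(scenario.truth.expressed_genes, paths["expressed"])
    pio.write_table(scenario.interactome, paths["interactome"])
    pio.write_table(scenario.regulatory_edges, paths["regulatory"])
    pio.write_screen_table(scenario.screen_table, paths["screen"])
    pio.write_activity_matrix(scenario.activity_matrix, paths["activity"])
    pio.write_table(scenario.sirna_table, paths["sirna"])
    pio.write_table(scenario.expression_table, paths["expression"])
    pio.write_fasta(scenario.genome, paths["genome"])
    pio.write_bed(scenario.peaks, paths["peaks"])
    pio.write_tss_bed(scenario.tss, paths["tss"])
    write_transfac_pwms(scenario.pwms, paths["pwms"])
    paths["truth"].write_text(scenario.truth.to_json())
    return {k: str(v) for k, v in paths.items()}
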