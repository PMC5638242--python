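"""Node significance, evidence scores and gamma robustness.

Statistical significance of a network node is judged against a
commodity-specific null: the optimization is re-run on inputs whose
identities are resampled uniformly from the interactome (capacities kept as
a multiset), once per commodity while the other commodity's inputs stay
fixed. Within every solved network a node's flow of a given commodity is
rank-normalized (rank / number of flow-carrying nodes, average ranks on
ties) so networks of different sizes are comparable; the empirical p-value
is (k + 1) / (n + 1), with k the number of null networks whose value reaches
the real one. Nodes never seen in the null networks get the sentinel -1;
original input nodes get NA.

Biological support is an evidence score: the number of distinct experimental
input nodes with a directed positive-flow path to the node. Candidates need
a flow p-value <= 0.05 in some commodity (no multiple-testing correction,
matching the selection rule the scores were designed for) and an evidence
score >= 3.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd
from scipy.stats import rankdata

from .exceptions import SizingError
from .flow import FlowParams, SolutionNetwork, solve
from .screens import InputNode

P_MAX = 0.05
EVIDENCE_MIN = 3
GAMMA_GRID = (14, 16, 18, 20, 22)
LEAVE_OUT_FRACTION = 0.2
N_RANDOM = 100


def randomize_commodity_inputs(
    inputs: list[InputNode], universe: set[str], rng: np.random.Generator
) -> list[InputNode]:
    """Resample input identities uniformly without replacement; keep capacities."""
    pool = sorted(universe)
    if len(pool) < len(inputs):
        raise SizingError(
            f"universe of {len(pool)} nodes cannot host {len(inputs)} inputs"
        )
    names = rng.choice(pool, size=len(inputs), replace=False)
    return [
        InputNode(str(name), inp.commodity, inp.capacity)
        for name, inp in zip(names, inputs)
    ]


def rank_normalized_flows(solution: SolutionNetwork, commodity: str) -> dict[str, float]:
    """Node flow -> rank fraction within this network for one commodity."""
    tol = solution.params.flow_tolerance
    nodes = [n for n, fl in solution.node_flow.items() if fl.get(commodity, 0.0) > tol]
    if not nodes:
        return {}
    flows = np.array([solution.node_flow[n][commodity] for n in nodes])
    ranks = rankdata(flows, method="average") / len(nodes)
    return dict(zip(nodes, ranks))


def compute_flow_pvalues(
    real_solution: SolutionNetwork,
    random_solutions_by_commodity: dict[str, list[SolutionNetwork]],
    original_inputs: dict[str, set[str]],
) -> pd.DataFrame:
    """Per-node, per-commodity empirical flow p-values.

    Sentinels: -1 when the node never carries the commodity's flow in any
    null network; NaN (written as NA) when the node was an original input of
    that commodity, or a transcript sink node.
    """
    commodities = real_solution.commodities
    real_ranks = {k: rank_normalized_flows(real_solution, k) for k in commodities}
    random_ranks = {
        k: [rank_normalized_flows(sol, k) for sol in sols]
        for k, sols in random_solutions_by_commodity.items()
    }
    for k, sols in random_solutions_by_commodity.items():
        if len(sols) == 0:
            raise SizingError(f"no random networks for commodity {k}")
    rows = []
    for node in sorted(real_solution.node_flow):
        rec = {"node": node}
        for k in commodities:
            if node.endswith("_mRNA") or node in original_inputs.get(k, set()):
                rec[f"p_{k}"] = np.nan
                continue
            batch = random_ranks[k]
            values = [r[node] for r in batch if node in r]
            if not values:
                rec[f"p_{k}"] = -1.0
                continue
            real_value = real_ranks[k].get(node, 0.0)
            # absent-from-a-null-network means zero flow there
            ge = sum(1 for r in batch if r.get(node, 0.0) >= real_value)
            rec[f"p_{k}"] = (ge + 1) / (len(batch) + 1)
        rows.append(rec)
    return pd.DataFrame(rows)


def evidence_scores(
    solution: SolutionNetwork, hit_inputs: list[InputNode]
) -> dict[str, int]:
    """Number of distinct hit inputs upstream of each node via positive-flow edges."""
    g = nx.DiGraph()
    mask = solution.edges["kind"].isin(["ppi", "reg"])
    g.add_edges_from(
        zip(solution.edges.loc[mask, "source"], solution.edges.loc[mask, "target"])
    )
    scores = {n: 0 for n in solution.node_flow}
    for name in sorted({h.name for h in hit_inputs}):
        if name not in g:
            continue
        for v in nx.descendants(g, name):
            if v != name and v in scores:
                scores[v] += 1
    return scores


def select_candidates(
    assessments: pd.DataFrame, p_max: float = P_MAX, evidence_min: int = EVIDENCE_MIN
) -> pd.DataFrame:
    """Candidate targets: some defined p <= p_max and evidence >= evidence_min."""
    p_cols = [c for c in assessments.columns if c.startswith("p_")]
    defined = assessments[p_cols].where(lambda p: (p >= 0) & p.notna())
    ok_p = (defined <= p_max).any(axis=1)
    sel = assessments[ok_p & (assessments["evidence_score"] >= evidence_min)]
    return sel.sort_values(
        ["evidence_score", "node"], ascending=[False, True], ignore_index=True
    )


def assess_nodes(
    kinase_hits: list[InputNode],
    genetic_hits: list[InputNode],
    de_genes: list[InputNode],
    interactome: pd.DataFrame,
    regulatory_edges: pd.DataFrame,
    params: FlowParams,
    n_random: int = N_RANDOM,
    seed: int = 0,
    p_max: float = P_MAX,
    evidence_min: int = EVIDENCE_MIN,
) -> tuple[pd.DataFrame, SolutionNetwork]:
    """Full node assessment: solve, randomize per commodity, score, select.

    Returns the assessment table (node, p_genetic, p_kinase, evidence_score,
    selected) and the real solution network.
    """
    real = solve(kinase_hits, genetic_hits, de_genes, interactome, regulatory_edges, params)
    excl = {n.upper() for n in params.excluded_nodes}
    universe = (
        set(interactome["protein_a"]) | set(interactome["protein_b"])
    ) - excl
    hit_sets = {"kinase": kinase_hits, "genetic": genetic_hits}
    seeds = np.random.SeedSequence(seed).spawn(len(real.commodities))
    randoms: dict[str, list[SolutionNetwork]] = {}
    for k, ss in zip(real.commodities, seeds):
        rng = np.random.default_rng(ss)
        batch = []
        for _ in range(n_random):
            rand_hits = dict(hit_sets)
            rand_hits[k] = randomize_commodity_inputs(hit_sets[k], universe, rng)
            batch.append(
                solve(
                    rand_hits["kinase"],
                    rand_hits["genetic"],
                    de_genes,
                    interactome,
                    regulatory_edges,
                    params,
                )
            )
        randoms[k] = batch
    original = {k: {h.name for h in hit_sets[k]} for k in real.commodities}
    table = compute_flow_pvalues(real, randoms, original)
    scores = evidence_scores(real, kinase_hits + genetic_hits)
    table["evidence_score"] = table["node"].map(scores).fillna(0).astype(int)
    selected = select_candidates(table, p_max, evidence_min)
    table["selected"] = table["node"].isin(selected["node"])
    return table, real


def jackknife_gamma(
    kinase_hits: list[InputNode],
    genetic_hits: list[InputNode],
    de_genes: list[InputNode],
    interactome: pd.DataFrame,
    regulatory_edges: pd.DataFrame,
    base_params: FlowParams,
    gamma_grid: tuple = GAMMA_GRID,
    leave_out_fraction: float = LEAVE_OUT_FRACTION,
    reps: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Leave-out robustness over a gamma grid.

    Per gamma and repetition, a fraction of one commodity's inputs is dropped
    (commodities alternate), the network is re-solved, and edge-level
    sensitivity (original edges recovered) and specificity (leave-out edges
    present in the original) are computed. Returns per-gamma means and the
    gamma maximizing mean(sensitivity + specificity).
    """
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    hit_sets = {"kinase": kinase_hits, "genetic": genetic_hits}
    rows = []
    for gamma in gamma_grid:
        params = replace(base_params, gamma=float(gamma))
        full = solve(
            kinase_hits, genetic_hits, de_genes, interactome, regulatory_edges, params
        )
        e_full = full.interaction_edges()
        sens, spec = [], []
        for rep in range(reps):
            k = full.commodities[rep % len(full.commodities)]
            hits = hit_sets[k]
            n_drop = int(round(leave_out_fraction * len(hits)))
            n_drop = min(n_drop, max(len(hits) - 1, 0))
            keep_idx = set(range(len(hits)))
            if n_drop > 0:
                drop = rng.choice(len(hits), size=n_drop, replace=False)
                keep_idx -= set(int(i) for i in drop)
            reduced = dict(hit_sets)
            reduced[k] = [h for i, h in enumerate(hits) if i in keep_idx]
            frac = solve(
                reduced["kinase"],
                reduced["genetic"],
                de_genes,
                interactome,
                regulatory_edges,
                params,
            )
            e_frac = frac.interaction_edges()
            inter = len(e_full & e_frac)
            sens.append(inter / len(e_full) if e_full else 1.0)
            spec.append(inter / len(e_frac) if e_frac else 1.0)
        rows.append((float(gamma), float(np.mean(sens)), float(np.mean(spec))))
    result = pd.DataFrame(rows, columns=["gamma", "sensitivity", "specificity"])
    best = float(
        result.loc[(result["sensitivity"] + result["specificity"]).idxmax(), "gamma"]
    )
    return result, best
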