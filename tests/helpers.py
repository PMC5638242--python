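"""Independent oracles and small instance builders shared across tests.

Everything here is deliberately brute-force and kept independent of the code
paths it checks: the path-flow LP re-derives the flow optimum from an
exhaustive simple-path enumeration, the motif oracle scores every window
directly from the sequence, and peak merging is reproduced with a per-base
boolean mask.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd
from scipy.optimize import linprog

from polyflow.flow import FlowNetwork
from polyflow.regulatory import PWM
from polyflow.screens import InputNode

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def path_flow_optimum(network: FlowNetwork) -> tuple[float, float]:
    """Exhaustive path-flow formulation of the same optimization.

    Enumerates every simple source->sink path per commodity and optimizes
    flows on paths subject to the shared group capacities and the source-arc
    capacities. Returns (objective value, total delivered flow).
    """
    arcs = network.arcs
    g = nx.DiGraph()
    for i, a in enumerate(arcs):
        g.add_edge(a.source, a.target, idx=i)
    paths: list[tuple[str, list[int]]] = []
    for k in network.commodities:
        src = network.source_name(k)
        if src not in g or FlowNetwork.SINK not in g:
            continue
        for p in nx.all_simple_paths(g, src, FlowNetwork.SINK):
            idxs = [g[u][v]["idx"] for u, v in zip(p[:-1], p[1:])]
            if all(arcs[i].kind != "source" or arcs[i].commodity == k for i in idxs):
                paths.append((k, idxs))
    if not paths:
        return 0.0, 0.0
    gamma = network.params.gamma
    c = np.array([sum(arcs[i].cost for i in idxs) - gamma for _, idxs in paths])
    rows = []
    b = []
    for gi, cap in enumerate(network.group_caps):
        members = {i for i, a in enumerate(arcs) if a.group == gi}
        rows.append([sum(1 for i in idxs if i in members) for _, idxs in paths])
        b.append(cap)
    for ai, arc in enumerate(arcs):
        if arc.kind == "source":
            rows.append([1.0 if ai in idxs else 0.0 for _, idxs in paths])
            b.append(arc.capacity)
    res = linprog(c, A_ub=np.array(rows), b_ub=np.array(b), bounds=(0, None), method="highs")
    assert res.success, res.message
    return float(res.fun), float(res.x.sum())


def brute_force_scan(seq: str, pwm: PWM) -> set[tuple[int, str, float]]:
    """Score every window on both strands directly; return passing matches."""
    lo = pwm.log_odds()
    mn, mx = lo.min(axis=1).sum(), lo.max(axis=1).sum()
    span = (mx - mn) or 1.0
    out = set()
    L = len(pwm)
    for i in range(len(seq) - L + 1):
        window = seq[i : i + L].upper()
        if any(b not in "ACGT" for b in window):
            continue
        for strand in "+-":
            w = window if strand == "+" else window.translate(COMPLEMENT)[::-1]
            raw = sum(lo[j, "ACGT".index(b)] for j, b in enumerate(w))
            score = (raw - mn) / span
            if score >= pwm.threshold:
                out.add((i, strand, round(score, 9)))
    return out


def mask_union(peak_sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-base boolean-mask union of interval sets (single or multi chrom)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for df in peak_sets:
        for _, r in df.iterrows():
            by_chrom.setdefault(r["chrom"], []).append((int(r["start"]), int(r["end"])))
    rows = []
    for chrom in sorted(by_chrom):
        size = max(e for _, e in by_chrom[chrom]) + 1
        mask = np.zeros(size, dtype=bool)
        for s, e in by_chrom[chrom]:
            mask[s:e] = True
        padded = np.concatenate([[False], mask, [False]])
        diff = np.diff(padded.astype(int))
        starts = np.where(diff == 1)[0]
        ends = np.where(diff == -1)[0]
        rows += [(chrom, int(s), int(e)) for s, e in zip(starts, ends)]
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def random_flow_instance(rng: np.random.Generator, n_proteins=10, n_tfs=3, n_genes=4):
    """A small random but connected flow instance (hits, DE genes, layers)."""
    labels = [f"N{i}" for i in range(n_proteins)] + [f"T{i}" for i in range(n_tfs)]
    g = nx.barabasi_albert_graph(len(labels), 2, seed=int(rng.integers(2**31)))
    perm = rng.permutation(len(labels))
    ia = pd.DataFrame(
        [
            (labels[perm[u]], labels[perm[v]], float(rng.uniform(0.2, 0.95)))
            for u, v in sorted(g.edges())
        ],
        columns=["protein_a", "protein_b", "confidence"],
    )
    genes = [f"G{i}" for i in range(n_genes)]
    reg = pd.DataFrame(
        [
            (f"T{t}", str(rng.choice(genes)), float(rng.uniform(0.5, 1.0)))
            for t in range(n_tfs)
            for _ in range(2)
        ],
        columns=["tf", "gene", "weight"],
    ).drop_duplicates(["tf", "gene"])
    prot = [f"N{i}" for i in range(n_proteins)]
    kin = [
        InputNode(str(n), "kinase", float(rng.uniform(0.5, 3.0)))
        for n in rng.choice(prot, size=2, replace=False)
    ]
    gen = [
        InputNode(str(n), "genetic", float(rng.uniform(0.5, 3.0)))
        for n in rng.choice(prot, size=2, replace=False)
    ]
    de = [InputNode(g_, "expression", float(rng.uniform(0.3, 2.0))) for g_ in genes]
    return kin, gen, de, ia, reg


def derive_inputs(scenario):
    """Run the three selection stages on a synthetic scenario."""
    from polyflow.expression import select_de_genes
    from polyflow.screens import call_inhibitor_hits, map_kinase_hits, select_genetic_hits

    calls = call_inhibitor_hits(scenario.screen_table)
    hit_inhibitors = [c.inhibitor for c in calls if c.is_hit]
    kin = map_kinase_hits(
        hit_inhibitors, scenario.activity_matrix, set(scenario.truth.expressed_genes)
    )
    gen = select_genetic_hits(scenario.sirna_table)
    de = select_de_genes(scenario.expression_table)
    return calls, kin, gen, de
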