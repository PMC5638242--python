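"""Two-commodity minimum-cost flow over the PPI + TF->gene interactome.

Each experimental hit class (kinase targets of synergizing inhibitors,
genetic modifiers from the siRNA screen) is a flow commodity with its own
virtual source; differentially expressed transcripts drain into a single
shared sink. Flow is routed through the protein-protein interactome
(undirected edges expanded to antiparallel arcs sharing one capacity pool)
and the TF->gene regulatory layer. Edge cost is -ln(confidence), so cheap
paths are chains of high-confidence interactions.

The linear program is

    minimize   sum_e cost_e * (sum_k f_ek)  -  gamma * sum_k (flow out of S_k)
    subject to per-commodity conservation at every interior node,
               per-commodity source-edge capacities (inputs normalized to
               sum to 1 per commodity),
               shared capacity sum_k f_ek <= cap_e on interactome,
               regulatory and sink edges, and f >= 0.

gamma trades delivered flow against summed edge cost: larger gamma admits
more, costlier paths and hence a larger solution network.

Transcript sinks are distinct nodes from proteins: a DE gene's sink node is
"<GENE>_mRNA", so a TF that is itself differentially expressed appears both
as a protein node and as a transcript node, as in the underlying model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .exceptions import InputError, SolverError
from .screens import InputNode

DEFAULT_EDGE_CAPACITY = 0.005
DEFAULT_FLOW_TOLERANCE = 1e-8
DEFAULT_EXCLUDED_NODES = frozenset({"EP300", "P300", "UBC"})
MRNA_SUFFIX = "_mRNA"


@dataclass(frozen=True)
class FlowParams:
    gamma: float = 20.0
    edge_capacity: float = DEFAULT_EDGE_CAPACITY
    flow_tolerance: float = DEFAULT_FLOW_TOLERANCE
    excluded_nodes: frozenset = DEFAULT_EXCLUDED_NODES
    cost_mode: str = "neg_log"  # or "inverse"

    def __post_init__(self):
        if self.gamma < 0:
            raise InputError("gamma must be >= 0")
        if self.edge_capacity <= 0:
            raise InputError("edge_capacity must be > 0")


@dataclass
class Arc:
    source: str
    target: str
    cost: float
    kind: str  # source | ppi | reg | sink
    commodity: str | None = None  # owning commodity for source arcs
    capacity: float = np.inf  # per-commodity cap for source arcs
    group: int = -1  # shared-capacity group index; -1 = none


@dataclass
class FlowNetwork:
    commodities: list[str]
    arcs: list[Arc]
    group_caps: list[float]
    nodes: list[str]  # interior (real) nodes, sorted
    params: FlowParams

    @staticmethod
    def source_name(commodity: str) -> str:
        return f"__SOURCE_{commodity}__"

    SINK = "__SINK__"


@dataclass
class SolutionNetwork:
    """Positive-flow subnetwork extracted from the solved LP."""

    edges: pd.DataFrame  # source, target, kind, commodity, flow
    node_flow: dict[str, dict[str, float]]  # node -> commodity -> incoming flow
    total_flow: dict[str, float]  # commodity -> flow leaving its source
    objective: float
    params: FlowParams
    commodities: list[str]

    @property
    def nodes(self) -> set[str]:
        return set(self.node_flow)

    def node_fractions(self, node: str) -> dict[str, float]:
        flows = self.node_flow.get(node, {})
        total = sum(flows.values())
        if total <= 0:
            return {k: 0.0 for k in flows}
        return {k: v / total for k, v in flows.items()}

    def interaction_edges(self) -> set[tuple[str, str]]:
        """Directed positive-flow interactome/regulatory edges (any commodity)."""
        mask = self.edges["kind"].isin(["ppi", "reg"])
        return set(zip(self.edges.loc[mask, "source"], self.edges.loc[mask, "target"]))


def _edge_cost(weight: float, mode: str) -> float:
    if weight <= 0 or weight > 1:
        raise InputError(f"edge confidence/weight {weight} outside (0, 1]")
    return (1.0 / weight) if mode == "inverse" else float(-np.log(weight))


def _normalized_inputs(hits: list[InputNode]) -> dict[str, float]:
    caps: dict[str, float] = {}
    for h in hits:
        if h.capacity <= 0:
            raise InputError(f"input node {h.name} has non-positive capacity")
        caps[h.name] = max(caps.get(h.name, 0.0), h.capacity)
    total = sum(caps.values())
    return {n: c / total for n, c in sorted(caps.items())}


def build_flow_graph(
    kinase_hits: list[InputNode],
    genetic_hits: list[InputNode],
    de_genes: list[InputNode],
    interactome: pd.DataFrame,
    regulatory_edges: pd.DataFrame,
    params: FlowParams,
) -> FlowNetwork:
    """Assemble the layered flow graph.

    Excluded nodes (promiscuous cofactors, by default P300/EP300 and UBC) are
    removed from the interactome first; hits not present in the remaining
    interactome are dropped with a warning; regulatory edges are restricted
    to TFs in the interactome and to selected DE genes.
    """
    excl = {n.upper() for n in params.excluded_nodes}
    ia = interactome[
        ~interactome["protein_a"].isin(excl) & ~interactome["protein_b"].isin(excl)
    ]
    ia = ia[ia["protein_a"] != ia["protein_b"]]
    # canonical undirected key; duplicates keep the highest confidence
    und = {}
    for a, b, conf in zip(ia["protein_a"], ia["protein_b"], ia["confidence"]):
        key = (a, b) if a <= b else (b, a)
        und[key] = max(und.get(key, 0.0), float(conf))
    ppi_nodes = {n for key in und for n in key}

    commodities = ["kinase", "genetic"]
    hit_sets = {"kinase": kinase_hits, "genetic": genetic_hits}
    arcs: list[Arc] = []
    group_caps: list[float] = []

    for k in commodities:
        inside = [h for h in hit_sets[k] if h.name in ppi_nodes]
        dropped = {h.name for h in hit_sets[k]} - {h.name for h in inside}
        if dropped:
            warnings.warn(
                f"{len(dropped)} {k} hit(s) absent from the interactome dropped: "
                + ", ".join(sorted(dropped)[:5])
            )
        if not inside:
            continue
        for name, cap in _normalized_inputs(inside).items():
            arcs.append(
                Arc(FlowNetwork.source_name(k), name, 0.0, "source", commodity=k, capacity=cap)
            )

    for (a, b), conf in sorted(und.items()):
        g = len(group_caps)
        group_caps.append(params.edge_capacity)
        cost = _edge_cost(conf, params.cost_mode)
        arcs.append(Arc(a, b, cost, "ppi", group=g))
        arcs.append(Arc(b, a, cost, "ppi", group=g))

    de_caps = _normalized_inputs(de_genes) if de_genes else {}
    n_comm = len(commodities)
    reg = regulatory_edges[
        regulatory_edges["tf"].isin(ppi_nodes) & regulatory_edges["gene"].isin(de_caps)
    ]
    reg = reg.sort_values(["tf", "gene"])
    for tf, gene, w in zip(reg["tf"], reg["gene"], reg["weight"]):
        g = len(group_caps)
        group_caps.append(params.edge_capacity)
        arcs.append(Arc(tf, gene + MRNA_SUFFIX, _edge_cost(float(w), params.cost_mode), "reg", group=g))

    reachable_genes = set(reg["gene"])
    for gene, cap in de_caps.items():
        if gene not in reachable_genes:
            continue
        g = len(group_caps)
        group_caps.append(cap * n_comm)
        arcs.append(Arc(gene + MRNA_SUFFIX, FlowNetwork.SINK, 0.0, "sink", group=g))

    interior = sorted(
        {a.source for a in arcs if not a.source.startswith("__")}
        | {a.target for a in arcs if a.target != FlowNetwork.SINK}
    )
    return FlowNetwork(commodities, arcs, group_caps, interior, params)


def solve_multicommodity_flow(network: FlowNetwork) -> SolutionNetwork:
    """Solve the shared-capacity min-cost/max-flow LP (HiGHS, deterministic)."""
    arcs, params = network.arcs, network.params
    # variables: one per (arc, commodity); source arcs only for their owner
    var_arc: list[int] = []
    var_comm: list[str] = []
    for ai, arc in enumerate(arcs):
        for k in network.commodities:
            if arc.kind == "source" and arc.commodity != k:
                continue
            var_arc.append(ai)
            var_comm.append(k)
    n_var = len(var_arc)
    if n_var == 0:
        return _empty_solution(network)

    cost = np.array(
        [
            arcs[ai].cost - (params.gamma if arcs[ai].kind == "source" else 0.0)
            for ai in var_arc
        ]
    )
    bounds = [
        (0.0, arcs[ai].capacity if arcs[ai].kind == "source" else None) for ai in var_arc
    ]

    node_idx = {n: i for i, n in enumerate(network.nodes)}
    comm_idx = {k: i for i, k in enumerate(network.commodities)}
    n_nodes = len(network.nodes)

    rows, cols, vals = [], [], []
    for vi, (ai, k) in enumerate(zip(var_arc, var_comm)):
        arc = arcs[ai]
        base = comm_idx[k] * n_nodes
        if arc.target in node_idx:
            rows.append(base + node_idx[arc.target])
            cols.append(vi)
            vals.append(1.0)
        if arc.source in node_idx:
            rows.append(base + node_idx[arc.source])
            cols.append(vi)
            vals.append(-1.0)
    A_eq = sparse.coo_matrix(
        (vals, (rows, cols)), shape=(len(network.commodities) * n_nodes, n_var)
    ).tocsr()
    keep = np.diff(A_eq.indptr) > 0  # nodes untouched by any arc need no row
    A_eq = A_eq[keep]
    b_eq = np.zeros(A_eq.shape[0])

    g_rows, g_cols, g_vals = [], [], []
    for vi, ai in enumerate(var_arc):
        if arcs[ai].group >= 0:
            g_rows.append(arcs[ai].group)
            g_cols.append(vi)
            g_vals.append(1.0)
    A_ub = sparse.coo_matrix(
        (g_vals, (g_rows, g_cols)), shape=(len(network.group_caps), n_var)
    ).tocsr()
    b_ub = np.asarray(network.group_caps, dtype=float)

    res = linprog(
        cost, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs"
    )
    if res.status == 3:
        raise AssertionError("unbounded LP despite finite capacities")
    if not res.success:
        raise SolverError(f"LP failed (status {res.status}): {res.message}")
    return extract_solution(network, var_arc, var_comm, res.x, res.fun)


def extract_solution(
    network: FlowNetwork,
    var_arc: list[int],
    var_comm: list[str],
    x: np.ndarray,
    objective: float,
    flow_tolerance: float | None = None,
) -> SolutionNetwork:
    """Drop sub-tolerance flows and summarize per-node commodity flows."""
    tol = network.params.flow_tolerance if flow_tolerance is None else flow_tolerance
    arcs = network.arcs
    rows = []
    node_flow: dict[str, dict[str, float]] = {}
    total_flow = {k: 0.0 for k in network.commodities}
    for ai, k, f in zip(var_arc, var_comm, x):
        if f <= tol:
            continue
        arc = arcs[ai]
        rows.append((arc.source, arc.target, arc.kind, k, float(f)))
        if arc.kind == "source":
            total_flow[k] += float(f)
        if arc.target in (FlowNetwork.SINK,):
            continue
        node_flow.setdefault(arc.target, {c: 0.0 for c in network.commodities})
        node_flow[arc.target][k] += float(f)
    edges = pd.DataFrame(rows, columns=["source", "target", "kind", "commodity", "flow"])
    edges = edges.sort_values(["kind", "source", "target", "commodity"], ignore_index=True)
    return SolutionNetwork(
        edges, node_flow, total_flow, float(objective), network.params, network.commodities
    )


def _empty_solution(network: FlowNetwork) -> SolutionNetwork:
    return SolutionNetwork(
        pd.DataFrame(columns=["source", "target", "kind", "commodity", "flow"]),
        {},
        {k: 0.0 for k in network.commodities},
        0.0,
        network.params,
        network.commodities,
    )


def solve(
    kinase_hits: list[InputNode],
    genetic_hits: list[InputNode],
    de_genes: list[InputNode],
    interactome: pd.DataFrame,
    regulatory_edges: pd.DataFrame,
    params: FlowParams,
) -> SolutionNetwork:
    """Build and solve in one call."""
    network = build_flow_graph(
        kinase_hits, genetic_hits, de_genes, interactome, regulatory_edges, params
    )
    return solve_multicommodity_flow(network)


def capacity_excess(network: FlowNetwork, solution: SolutionNetwork) -> float:
    """Largest violation of any shared capacity group (<= 0 means feasible)."""
    arc_group = {
        (a.source, a.target): (a.group, network.group_caps[a.group])
        for a in network.arcs
        if a.group >= 0
    }
    used: dict[int, float] = {}
    caps: dict[int, float] = {}
    for _, e in solution.edges.iterrows():
        entry = arc_group.get((e["source"], e["target"]))
        if entry is None:
            continue
        g, cap = entry
        used[g] = used.get(g, 0.0) + e["flow"]
        caps[g] = cap
    if not used:
        return 0.0
    return max(used[g] - caps[g] for g in used)


def conservation_residuals(solution: SolutionNetwork) -> dict[tuple[str, str], float]:
    """|inflow - outflow| per (interior node, commodity); used by invariant tests."""
    residuals: dict[tuple[str, str], float] = {}
    for k in solution.commodities:
        sub = solution.edges[solution.edges["commodity"] == k]
        inflow: dict[str, float] = {}
        outflow: dict[str, float] = {}
        for _, e in sub.iterrows():
            inflow[e["target"]] = inflow.get(e["target"], 0.0) + e["flow"]
            outflow[e["source"]] = outflow.get(e["source"], 0.0) + e["flow"]
        for node in set(inflow) | set(outflow):
            if node.startswith("__"):
                continue
            residuals[(node, k)] = abs(inflow.get(node, 0.0) - outflow.get(node, 0.0))
    return residuals
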