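"""Randomization p-values, evidence scores, candidate rules, gamma jackknife."""

import numpy as np
import pandas as pd
import pytest

from polyflow.exceptions import SizingError
from polyflow.flow import FlowParams, SolutionNetwork, solve
from polyflow.screens import InputNode
from polyflow.significance import (
    compute_flow_pvalues,
    evidence_scores,
    jackknife_gamma,
    randomize_commodity_inputs,
    rank_normalized_flows,
    select_candidates,
)

PARAMS = FlowParams(gamma=1.0)


def _solution(node_flow, edges=None):
    edge_df = pd.DataFrame(
        edges or [], columns=["source", "target", "kind", "commodity", "flow"]
    )
    return SolutionNetwork(
        edges=edge_df,
        node_flow=node_flow,
        total_flow={"kinase": 0.0, "genetic": 0.0},
        objective=0.0,
        params=PARAMS,
        commodities=["kinase", "genetic"],
    )


INPUTS = [InputNode("A", "kinase", 2.0), InputNode("B", "kinase", 3.0)]
UNIVERSE = {f"U{i}" for i in range(10)}


def test_randomization_preserves_capacity_multiset_and_is_deterministic():
    a = randomize_commodity_inputs(INPUTS, UNIVERSE, np.random.default_rng(5))
    b = randomize_commodity_inputs(INPUTS, UNIVERSE, np.random.default_rng(5))
    assert [(n.name, n.capacity) for n in a] == [(n.name, n.capacity) for n in b]
    assert sorted(n.capacity for n in a) == [2.0, 3.0]
    assert {n.name for n in a} <= UNIVERSE
    assert len({n.name for n in a}) == 2


def test_randomization_uniform_over_universe():
    """Each universe member drawn with frequency 2/10 within 3 binomial SEs."""
    rng = np.random.default_rng(0)
    counts = {u: 0 for u in UNIVERSE}
    n = 1000
    for _ in range(n):
        for node in randomize_commodity_inputs(INPUTS, UNIVERSE, rng):
            counts[node.name] += 1
    p = len(INPUTS) / len(UNIVERSE)
    se = np.sqrt(p * (1 - p) / n)
    for u, c in counts.items():
        assert abs(c / n - p) <= 3 * se


def test_randomization_requires_large_enough_universe():
    with pytest.raises(SizingError):
        randomize_commodity_inputs(INPUTS, {"X"}, np.random.default_rng(0))


def test_rank_normalization_averages_ties():
    sol = _solution({"A": {"kinase": 0.1}, "B": {"kinase": 0.1}, "C": {"kinase": 0.3}})
    ranks = rank_normalized_flows(sol, "kinase")
    assert ranks == {"A": 0.5, "B": 0.5, "C": 1.0}


def test_pvalue_sentinels_and_counting_rule():
    real = _solution(
        {
            "TOP": {"kinase": 0.9, "genetic": 0.0},
            "TIED": {"kinase": 0.1, "genetic": 0.0},
            "NOVEL": {"kinase": 0.5, "genetic": 0.0},
            "INP": {"kinase": 0.4, "genetic": 0.0},
        }
    )
    rng = np.random.default_rng(1)
    nulls = []
    for _ in range(100):
        nulls.append(
            _solution(
                {
                    "TOP": {"kinase": float(rng.uniform(0.01, 0.2)), "genetic": 0.0},
                    "TIED": {"kinase": 0.1, "genetic": 0.0},
                    "FILLER": {"kinase": 0.05, "genetic": 0.0},
                    "INP": {"kinase": float(rng.uniform(0.3, 0.9)), "genetic": 0.0},
                }
            )
        )
    table = compute_flow_pvalues(
        real, {"kinase": nulls, "genetic": nulls}, {"kinase": {"INP"}, "genetic": set()}
    ).set_index("node")
    # TOP's real rank beats all 100 nulls -> (0+1)/101
    assert table.loc["TOP", "p_kinase"] == pytest.approx(1 / 101)
    # TIED ties every null at the same rank value -> p = 1
    assert table.loc["TIED", "p_kinase"] == pytest.approx(1.0)
    # NOVEL never appears in any null network -> sentinel -1
    assert table.loc["NOVEL", "p_kinase"] == -1.0
    # original inputs are not assessed
    assert np.isnan(table.loc["INP", "p_kinase"])


def test_evidence_score_chain_and_brute_force_dag():
    edges = [("H", "A", "ppi", "kinase", 0.01), ("A", "B", "ppi", "kinase", 0.01)]
    sol = _solution(
        {"H": {"kinase": 0.01}, "A": {"kinase": 0.01}, "B": {"kinase": 0.01}}, edges
    )
    scores = evidence_scores(sol, [InputNode("H", "kinase", 1.0)])
    assert scores == {"H": 0, "A": 1, "B": 1}

    rng = np.random.default_rng(8)
    nodes = [f"N{i}" for i in range(15)]
    dag = [
        (nodes[i], nodes[j], "ppi", "kinase", 0.01)
        for i in range(15)
        for j in range(i + 1, 15)
        if rng.random() < 0.2
    ]
    hits = [InputNode(n, "kinase", 1.0) for n in rng.choice(nodes[:5], 3, replace=False)]
    sol = _solution({n: {"kinase": 0.01} for n in nodes}, dag)
    scores = evidence_scores(sol, hits)

    adj = {}
    for u, v, *_ in dag:
        adj.setdefault(u, []).append(v)

    def reach(u):
        seen, stack = set(), [u]
        while stack:
            x = stack.pop()
            for y in adj.get(x, []):
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return seen

    expected = {n: 0 for n in nodes}
    for h in {h.name for h in hits}:
        for v in reach(h):
            if v != h:
                expected[v] += 1
    assert scores == expected


def test_evidence_score_monotone_under_edge_addition():
    edges = [("H1", "A", "ppi", "kinase", 0.01), ("H2", "B", "ppi", "kinase", 0.01)]
    nf = {n: {"kinase": 0.01} for n in "H1 H2 A B".split()}
    hits = [InputNode("H1", "kinase", 1.0), InputNode("H2", "kinase", 1.0)]
    before = evidence_scores(_solution(nf, edges), hits)
    after = evidence_scores(_solution(nf, edges + [("B", "A", "ppi", "kinase", 0.01)]), hits)
    assert all(after[n] >= before[n] for n in nf)
    assert after["A"] == 2


def test_candidate_selection_boundaries():
    table = pd.DataFrame(
        {
            "node": ["ON_BOUNDARY", "HIGH_P", "SENTINEL_OK", "UNDEFINED"],
            "p_kinase": [0.05, 0.99, -1.0, -1.0],
            "p_genetic": [0.5, 0.06, 0.01, np.nan],
            "evidence_score": [3, 10, 5, 8],
        }
    )
    picked = set(select_candidates(table)["node"])
    assert picked == {"ON_BOUNDARY", "SENTINEL_OK"}
    assert select_candidates(table, evidence_min=4)["node"].tolist() == ["SENTINEL_OK"]


def test_jackknife_identity_when_nothing_left_out(small_scenario):
    from helpers import derive_inputs

    _, kin, gen, de = derive_inputs(small_scenario)
    table, best = jackknife_gamma(
        kin,
        gen,
        de,
        small_scenario.interactome,
        small_scenario.regulatory_edges,
        FlowParams(gamma=14.0),
        gamma_grid=(14.0, 20.0),
        leave_out_fraction=0.0,
        reps=2,
        seed=0,
    )
    assert (table["sensitivity"] == 1.0).all()
    assert (table["specificity"] == 1.0).all()
    assert best in (14.0, 20.0)


def test_jackknife_matches_direct_set_arithmetic(small_scenario):
    """Sensitivity/specificity equal a naive recomputation of the edge-set
    overlap for the same leave-out draws."""
    from helpers import derive_inputs

    _, kin, gen, de = derive_inputs(small_scenario)
    ia, reg = small_scenario.interactome, small_scenario.regulatory_edges
    gamma = 18.0
    table, _ = jackknife_gamma(
        kin, gen, de, ia, reg, FlowParams(gamma=gamma),
        gamma_grid=(gamma,), leave_out_fraction=0.2, reps=2, seed=42,
    )
    # replicate the draw sequence
    rng = np.random.default_rng(42)
    full = solve(kin, gen, de, ia, reg, FlowParams(gamma=gamma)).interaction_edges()
    hit_sets = {"kinase": kin, "genetic": gen}
    sens, spec = [], []
    for rep in range(2):
        k = ["kinase", "genetic"][rep % 2]
        hits = hit_sets[k]
        n_drop = min(int(round(0.2 * len(hits))), len(hits) - 1)
        drop = set(int(i) for i in rng.choice(len(hits), size=n_drop, replace=False))
        reduced = dict(hit_sets)
        reduced[k] = [h for i, h in enumerate(hits) if i not in drop]
        frac = solve(
            reduced["kinase"], reduced["genetic"], de, ia, reg, FlowParams(gamma=gamma)
        ).interaction_edges()
        inter = len(full & frac)
        sens.append(inter / len(full))
        spec.append(inter / len(frac))
    assert table.loc[0, "sensitivity"] == pytest.approx(np.mean(sens))
    assert table.loc[0, "specificity"] == pytest.approx(np.mean(spec))


def test_pvalues_conservative_under_exchangeable_inputs(small_scenario):
    """When the 'real' inputs are drawn from the same null as the
    randomizations, the unconditional per-node p-values must be
    super-uniform: P(p <= x) <= x (plus ties mass at 1)."""
    from helpers import derive_inputs

    _, kin, gen, de = derive_inputs(small_scenario)
    ia, reg = small_scenario.interactome, small_scenario.regulatory_edges
    universe = set(ia["protein_a"]) | set(ia["protein_b"])
    rng = np.random.default_rng(17)
    gen_fixed = randomize_commodity_inputs(gen, universe, rng)
    sols = [
        solve(
            randomize_commodity_inputs(kin, universe, rng),
            gen_fixed, de, ia, reg, FlowParams(gamma=20.0),
        )
        for _ in range(31)
    ]
    ranks = [rank_normalized_flows(s, "kinase") for s in sols]
    real, nulls = ranks[0], ranks[1:]
    ps = []
    for node in set().union(*map(set, ranks)):
        if not any(node in r for r in nulls):
            continue
        rv = real.get(node, 0.0)
        ge = sum(1 for r in nulls if r.get(node, 0.0) >= rv)
        ps.append((ge + 1) / (len(nulls) + 1))
    ps = np.array(ps)
    assert ps.size > 20
    for x in (0.1, 0.25, 0.5):
        assert (ps <= x).mean() <= x + 0.05
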