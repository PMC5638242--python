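from polyflow import (
    ScenarioConfig, generate_scenario, FlowParams, solve,
    call_inhibitor_hits, map_kinase_hits, select_genetic_hits, select_de_genes,
)

scenario = generate_scenario(ScenarioConfig(seed=1))
calls = call_inhibitor_hits(scenario.screen_table)
hits = [c.inhibitor for c in calls if c.is_hit]
kinase = map_kinase_hits(hits, scenario.activity_matrix, set(scenario.truth.expressed_genes))
genetic = select_genetic_hits(scenario.sirna_table)
de = select_de_genes(scenario.expression_table)
print("hit inhibitors:", hits)
print("kinase hits:", len(kinase), "genetic hits:", len(genetic), "DE genes:", len(de))

solution = solve(kinase, genetic, de, scenario.interactome,
                 scenario.regulatory_edges, FlowParams(gamma=20.0))
print("delivered flow:", {k: round(v, 4) for k, v in solution.total_flow.items()})
print("network size:", len(solution.nodes), "nodes,",
      int(solution.edges["kind"].isin(["ppi", "reg"]).sum()), "interaction edges")
planted = set(scenario.truth.intermediates)
print("planted intermediates carrying flow:",
      f"{len(planted & solution.nodes)}/{len(planted)}")
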