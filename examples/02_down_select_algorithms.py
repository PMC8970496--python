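"""Stages 2-3: match user needs against the algorithm knowledge base.

Loads the shipped comparative matrix (14 algorithms x 11 characteristics)
and scores every algorithm against two scenario presets. The weighted score
counts supported requirements; algorithms above half the attainable score
survive the majority cut, and hard constraints (k-only parameters, a
complexity cap) filter absolutely.
"""

import clusterselect as cs

kb = cs.load_kb()
print(f"knowledge base: {len(kb)} algorithm profiles\n")

for scenario in ("explosives", "gene_expression"):
    req = cs.get_preset(scenario)
    result = cs.select(kb, req)
    print(f"--- {scenario} (attainable score {req.max_score:g}) ---")
    for r in result.ranked[:5]:
        gaps = f", {len(r.unknown)} unknown" if r.unknown else ""
        print(f"  {r.algorithm:28s} score {r.score:4.1f}/{r.max_score:g}{gaps}")
    print(f"  selected: {', '.join(result.selected)}\n")
# In the gene-expression scenario only two algorithms both support high
# dimensions and stay within the n^2 efficiency cap.
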