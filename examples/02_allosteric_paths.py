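"""Allosteric pathway extraction on a planted two-domain benchmark.

Generates a dumbbell structure in which the only connection between two
domains is a known channel of beads, weights the residue contact graph by
PRS coupling, and checks that shortest paths and the most-mediated residue
recover the planted channel.
"""

import prspath as pp

model, channel = pp.make_dumbbell(n_per_domain=10, channel_residues=3, seed=1)
n = 10
print(f"dumbbell: {model.n_atoms} residues, planted channel = {channel}")

cov = pp.anm_covariance(pp.build_anm_hessian(model, cutoff_rc=16.0))
prs = pp.prs_scan(cov, pp.analytic_force_set())
graph = pp.assign_edge_weights(pp.build_contact_graph(model, contact_cutoff=10.0), prs)

sources = list(range(1, n + 1))                       # every domain-A residue
sinks = list(range(n + len(channel) + 1, model.n_atoms + 1))  # every domain-B residue
paths = pp.all_pairs_paths(graph, sources, sinks)

crossing = sum(bool(set(p.nodes) & set(channel)) for p in paths)
print(f"paths computed: {len(paths)}; paths crossing the channel: {crossing}")

profile = pp.mediation_profile(paths, graph.n_nodes)
print("most-mediated residue(s):", profile.top_residues())
# the waist of the channel is a cut vertex, so it mediates every single
# source-to-sink route — exactly the signature used to call mediator
# residues in real allosteric networks

example = paths[0]
print(f"example path {example.source}->{example.sink}: {example.nodes} "
      f"(total weight {example.total_weight:.3f})")
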