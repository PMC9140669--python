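"""Build the Barabasi-Albert scale-free network that steers the search and
inspect its degree structure.

A few hub nodes accumulate most connections (power-law degree
distribution); the optimizer maps its current best solutions onto those
hubs so that ordinary solutions drift toward elite ones.
"""

from sfmoabc import build_ba_network, degree_distribution, max_degree_neighbor

net = build_ba_network(n_nodes=100, m0=3, n_links=2, seed=7)
print(f"BA(100, m0=3, links=2): {net.n_edges} edges (3 clique + 2*97 = 197)")
degs = net.degrees
hubs = sorted(degs, key=degs.get, reverse=True)[:5]
print("five highest-degree nodes:", {h: degs[h] for h in hubs})
print("hub ids (elite slots):", net.hub_ids)
print("max-degree neighbor of node 50:", max_degree_neighbor(net, 50))

pk, gamma = degree_distribution(build_ba_network(5000, 3, 2, seed=7))
print(f"BA(5000): fitted power-law tail exponent gamma_hat = {gamma:.2f} "
      "(scale-free networks typically show 2-3)")
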