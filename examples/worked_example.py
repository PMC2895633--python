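"""Decompose the built-in 10-node illustration network into subnets.

Builds the example network (roots a, b, d), prints each subnet's members and
hierarchical levels, and counts its single feed-forward-loop triad.  The
subnet of a root is everything topologically downstream of it, root included;
levels are maximal distances from the root.
"""

from subnetusage import enumerate_subnets, example_network, triad_census
from subnetusage.motifs import FFL_ID
from subnetusage.network import network_summary

net = example_network()
print("network:", network_summary(net))

for s in enumerate_subnets(net, min_size=1):
    print(f"subnet of {s.root}: members={sorted(s.members)} "
          f"size={s.size} max_level={s.max_level}")

census = triad_census(net)
print(f"connected triads: {census.total_connected_triples}, "
      f"feed-forward loops (id {FFL_ID}): {census.counts.get(FFL_ID, 0)}")
print("the single FFL is formed by nodes a, b, c")
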