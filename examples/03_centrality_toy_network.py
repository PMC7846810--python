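"""The three influence measures on a five-node toy network.

Follower->leader links: 1->4, 2->4, 3->4, 4->5, 5->1 (unit weights).
Individual 4 led three others; 5 led 4; 1 led 5; 2 and 3 never led.
"""

import networkx as nx

from leadfollow import (
    eigenvector_centrality,
    in_degree_centrality,
    rank,
    second_degree_centrality,
)

net = nx.DiGraph()
for follower, leader in [("1", "4"), ("2", "4"), ("3", "4"), ("4", "5"), ("5", "1")]:
    net.add_edge(follower, leader, weight=1)

indeg = in_degree_centrality(net)
eig = eigenvector_centrality(net)
second = second_degree_centrality(net, alpha=0.5)

print("node  in-degree  eigenvector  second-degree(alpha=0.5)")
for node in sorted(net.nodes):
    print(f"{node:>4}  {indeg[node]:>9.1f}  {eig[node]:>11.4f}  {second[node]:>12.2f}")

print("\nsecond-degree ranks:", rank(second).ranks)
# In-degree makes 4 the clear leader (score 3) with 1 and 5 tied at 1.
# Eigenvector zeroes 2 and 3 (no followers) and equalizes the 1-4-5 cycle.
# Second-degree keeps 4 on top (3 + 0.5*1 = 3.5) but now ranks 5 above 1
# (1 + 0.5*3 = 2.5): node 5's single follower is itself influential.
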