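"""Build the five-sensor body skeleton and inspect its partitioned adjacency.

Shows the hop-distance matrix of the default ankle-pocket-waist-neck-wrist
chain and the K normalized adjacency matrices each partition strategy
produces: K = 1 (uni-labeling), MD + 1 (distance) or 3 (spatial
configuration, root / centripetal / centrifugal).
"""

import numpy as np

import fallgcn as fg

graph = fg.build_default_graph()
print("nodes:", graph.node_names)
print("centre (gravity proxy):", graph.node_names[graph.center])
print("hop distances:\n", fg.hop_distances(graph))

for strategy in ("uni-labeling", "distance", "spatial-configuration"):
    config = fg.PartitionConfig(strategy, max_distance=1)
    stack = fg.build_adjacency_stack(graph, config)
    print(f"\n{strategy}: K = {stack.K} subsets {stack.subset_labels}")
    for label, subset in zip(stack.subset_labels, stack.subsets):
        print(f"  {label}: support rows\n{np.round(subset, 2)}")
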