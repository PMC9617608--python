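"""Minimum-spanning-tree pruning: recovering a branching backbone.

Cross-links create loops in the mesh.  Pruning with an inverse-length
MST preferentially removes short branches (putative cross-linkers),
leaving an acyclic tree; merging the rank-2 nodes that pruning leaves
behind then joins collinear branch pairs.
"""

import warnings

from spinemesh.loops import minimum_spanning_tree_prune, prune_stats
from spinemesh.synthetic import (
    SpinePhantomSpec,
    generate_spine_geometry,
    grow_network,
)

warnings.simplefilter("ignore")

spec = SpinePhantomSpec(head_radius=70, neck_length=80, neck_radius=32,
                        target_node_density=9e4, crosslink_rate=0.4,
                        min_branch_spacing=14.0)
mask = generate_spine_geometry(spec, seed=1)
net = grow_network(mask, spec, seed=2)

pruned = minimum_spanning_tree_prune(net)
stats = prune_stats(net, pruned, mask)

print(f"branches: {stats['branch_count_before']} -> {stats['branch_count_after']} "
      f"(-{stats['branch_reduction_percent']:.0f}%)")
print(f"nodes:    {stats['node_count_before']} -> {stats['node_count_after']} "
      f"(-{stats['node_reduction_percent']:.0f}%)")
print(f"mean branch length: {stats['mean_branch_length_before_nm']:.1f} -> "
      f"{stats['mean_branch_length_after_nm']:.1f} nm")
print(f"rank-1 (end) fraction: {stats['rank1_fraction_before']:.0%} -> "
      f"{stats['rank1_fraction_after']:.0%}")
print(f"volume fraction: {stats['volume_fraction_before']:.1%} -> "
      f"{stats['volume_fraction_after']:.1%}")
# Removing loops drops branch density and raises the mean branch length,
# as merged collinear pairs take the place of short cross-links.
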