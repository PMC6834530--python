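"""Trace a thin branch fragmented into beads.

Fixation can break thin dendrites into dark spheres ("beads") separated
by faint gaps.  Each bead is validated on its own and the broken chain
is reassembled by the distance-based connection heuristics.
"""

from dendrotrace import PipelineConfig, trace_stack
from dendrotrace.metrics import centerline_recall
from dendrotrace.scenarios import beaded_scene

config = PipelineConfig()
stack, truth = beaded_scene(seed=0)
tree = trace_stack(stack, config)

print(f"points: {len(tree)}  components: {len(tree.components())}")
print(f"cable recall: {centerline_recall(truth['tree'], tree):.3f}")
xs = sorted(round(p.x, 1) for p in tree.points)
print(f"traced bead positions along the branch (um): {xs}")

# one component over a fully beaded branch shows that point validation
# (finding each bead) and gap bridging (connect rules) work together
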