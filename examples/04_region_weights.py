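"""From selected edges to region weights and BrainNet Viewer files.

A region's weight is the number of selected edges touching it — a simple
proxy for how involved the region is in the group difference.
"""

from pathlib import Path

import numpy as np

import rnncluster as rnc
from rnncluster.edges import edge_to_index

atlas = rnc.synthetic_atlas(10)
selected = np.array([
    edge_to_index(0, 1, 10), edge_to_index(0, 2, 10), edge_to_index(0, 5, 10),
    edge_to_index(2, 5, 10), edge_to_index(3, 7, 10),
])
table = rnc.region_weights(selected, atlas)
print(table.to_frame().to_string(index=False))
print(f"sum of weights = {table.weights.sum()} = 2 x {selected.size} selected edges")

heavy = rnc.filter_regions(table, min_weight=1)
print("regions touched by more than one edge:", list(heavy.abbreviations))

out = Path("scratch_example_out")
out.mkdir(exist_ok=True)
rnc.export_brainnet(table, selected, atlas, out / "demo.node", out / "demo.edge")
print(f"-> wrote {out}/demo.node and {out}/demo.edge for BrainNet Viewer; "
      "node size/color encode the weight.")
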