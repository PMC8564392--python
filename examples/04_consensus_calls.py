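"""Per-group consensus gene calls from per-cell attractors.

A network is constructed around a planted fixed point; 100 synthetic cells
start at that state, every trajectory lands in the planted attractor, and
the 95%-of-cells consensus recovers the designed constant genes.
"""

from scboolnet import (PlantedNetworkSpec, consensus_genes, plant_fixed_point,
                       simulate_to_attractor)
from scboolnet.attractor_analysis import label_all_genes
from scboolnet.synthetic_data import sample_cells_near_state

planted = plant_fixed_point(PlantedNetworkSpec(n_genes=30, seed=5))
net = planted.network

cells = sample_cells_near_state(planted.target_state, 100, seed=1)
labels = {}
for i, bits in enumerate(cells):
    sim = simulate_to_attractor(net, net.state(bits))
    labels[f"cell{i}"] = label_all_genes(sim.attractor, net.symbols)

cons = consensus_genes(("patient1", "malignant"), labels,
                       min_cell_fraction=0.95)
n_true = sum(1 for lab in cons.labels.values() if lab == "True")
n_false = sum(1 for lab in cons.labels.values() if lab == "False")
recovered = sum(1 for g in planted.constant_genes
                if cons.labels[g] in ("True", "False"))

print(f"group: {cons.group}, cells in denominator: {cons.n_cells}")
print(f"consensus calls: {n_true} constantly expressed (True), "
      f"{n_false} constantly silent (False)")
print(f"designed constant genes recovered: "
      f"{recovered}/{len(planted.constant_genes)}")
# Every gene holds its planted value in the singleton attractor of every
# cell, so all 30 designed constant genes are called at the 95% threshold.
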