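"""Convert smFRET efficiencies to distances and compare with a model.

Förster theory maps efficiency E to donor–acceptor distance
d = R0·(1/E − 1)^(1/6) with R0 = 5.1 nm, minus a 1 nm fluorophore-linker
correction.  Model distances are residue-centroid distances over
trajectory frames.
"""

import numpy as np

from clampdyn.fret_model import build_comparison, fret_to_distance
from clampdyn.io_formats import Structure, Trajectory

for E in (0.2, 0.5, 0.9):
    d, physical = fret_to_distance(E)
    print(f"E = {E:.1f}  ->  d_exp = {d:.2f} nm"
          + ("" if physical else "  (non-physical after linker correction)"))

# a three-residue model: residue 2 fluctuates around the E = 0.5 distance
# from residue 1, residue 3 around the E = 0.3 distance
rng = np.random.default_rng(0)
frames = np.zeros((50, 3, 3))
frames[:, 1, 0] = 41.0 + rng.normal(0, 1.5, 50)                  # Å
frames[:, 2, 1] = 10 * fret_to_distance(0.3)[0] + rng.normal(0, 1.5, 50)
s = Structure(residue_index=np.array([1, 2, 3]),
              residue_name=np.array(["CYS", "CYS", "CYS"]),
              chain_id=np.array(["A", "B", "B"]),
              domain_label=np.array(["A", "B", "B"]),
              positions=frames[0])
traj = Trajectory(structure=s, frames=frames, dt=1.0)

comp = build_comparison([("pair1", [1], [2], 0.5),
                         ("pair2", [1], [3], 0.3)], traj)
print(comp.table.to_string(index=False))
print("d_exp comes from the efficiency; d_model from the coordinates —")
print("close agreement validates the structural model against smFRET.")
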