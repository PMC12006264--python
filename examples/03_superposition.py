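"""Confidence-gated structural comparison of two ortholog models.

A synthetic helix is copied, a 5-residue span displaced by 4 Å, and the
copy rigidly scrambled.  The iteratively pruned superposition recovers
the shared frame, reports per-residue CA deviations, and classes each
pair matched (< 2 Å) or different (>= 2 Å).
"""

import numpy as np
from scipy.spatial.transform import Rotation

from orthostruct.superpose import (
    classify_pairs, matchmaker_superpose,
)
from orthostruct.synthetic_data import make_backbone
from orthostruct.superpose import ResiduePairing

rng = np.random.default_rng(7)
a = make_backbone(80, "helix")
b = a.copy()
b[40:45] += np.array([0.0, 4.0, 0.0])          # planted displacement
rot = Rotation.random(rng=rng).as_matrix()      # hide it in a new frame
b = b @ rot.T + rng.uniform(-15, 15, size=3)

cols = np.arange(1, 81)
pairing = ResiduePairing("ref", "moved", cols, cols - 1, cols - 1, a, b)
result = classify_pairs(matchmaker_superpose(pairing))

print(f"converged in {result.n_iterations} iterations; "
      f"{int(result.retained.sum())}/80 pairs retained; "
      f"core RMSD {result.rmsd:.3f} A")
different = [int(c) for c, k in zip(cols, result.classes) if k == "different"]
print(f"pairs classed 'different': {different}")
print(f"their deviations: "
      f"{[round(float(result.deviations[i-1]), 2) for i in different]} A")
# exactly the planted span 41..45 comes back, at the planted 4 A magnitude.
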