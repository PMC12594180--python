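"""The two bespoke objectives: the OGT-anchored dual loss and Rank-N-Contrast.

The dual loss splits the predicted melting temperature into a species-level
component y_ogt, anchored to the species' mean train-set Tm (a proxy for
its optimal growth temperature), and a per-protein offset y_bias:
phi_tm = y_ogt + y_bias, loss = MSE(phi_tm, y_tm) + MSE(y_ogt, mu_tm).

Rank-N-Contrast orders representation-space similarities by label-space
rank: each sample j is contrasted against the set S_ij of samples at least
as far from the anchor i in Tm as j itself.
"""

import numpy as np

from tmelt.model import DualPrediction, combine_dual
from tmelt.objectives import ContrastiveBatch, SpeciesAnchor, dual_loss, rank_set, rnc_loss

# --- dual loss ---------------------------------------------------------
anchor = SpeciesAnchor({"T. thermophilus": 74.0})
pred = combine_dual(np.array([75.0, 3.0]))  # y_ogt = 75, y_bias = +3
print(f"phi_tm = {pred.y_ogt} + {pred.y_bias} = {pred.phi_tm} degC")
loss = dual_loss([pred], [80.0], ["T. thermophilus"], anchor)
print(f"dual loss vs y_tm=80, mu_tm=74: (78-80)^2 + (75-74)^2 = {loss}")

# --- rank set ----------------------------------------------------------
tms = [48.0, 50.0, 53.0, 68.0]
print(f"\nlabels {tms}, anchor idx 0, candidate idx 1 (|dTm| = 2)")
print(f"S_01 = {[int(k) for k in rank_set(0, 1, tms)]}  # everything at least 2 degC away")

# --- Rank-N-Contrast loss ---------------------------------------------
rng = np.random.default_rng(0)
labels = np.tile(np.array([45.0, 50.0, 55.0, 60.0]), 2)  # two-view batch, N=4
aligned = labels[:, None] * np.eye(3)[0]  # distances mirror |dTm|
shuffled = aligned[rng.permutation(8)]
print(f"\nRNC loss, label-aligned representations: {rnc_loss(ContrastiveBatch(aligned, labels)):.4f}")
print(f"RNC loss, same vectors shuffled:          {rnc_loss(ContrastiveBatch(shuffled, labels)):.4f}")
# The aligned geometry scores lower: the loss rewards representations whose
# pairwise distances increase with the melting-temperature gap.
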