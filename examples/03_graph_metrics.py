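"""Weighted graph metrics with random-surrogate normalization.

Compares a lattice-flavoured weighted network (strong neighbours, weak
long-range edges) against weight-permuted surrogates: clustering and path
length are reported raw and normalized, and their ratio is the
small-worldness index.
"""

import numpy as np

from eegnetrel import (characteristic_path_length, clustering_coefficient,
                       small_worldness, surrogate_normalize)

n = 16
idx = np.arange(n)
d = np.minimum(np.abs(idx[:, None] - idx[None, :]),
               n - np.abs(idx[:, None] - idx[None, :]))
W = np.where(d <= 2, 0.8, 0.08).astype(float)
np.fill_diagonal(W, 0.0)

Cw = clustering_coefficient(W)
Lw = characteristic_path_length(W)
Cn, Ln, C_rand, L_rand = surrogate_normalize(W, n_surrogates=200, seed=0)
print(f"Cw = {Cw:.4f}   (random reference {C_rand:.4f})")
print(f"Lw = {Lw:.4f}   (random reference {L_rand:.4f})")
print(f"normalized: Cw_nrm = {Cn:.4f}, Lw_nrm = {Ln:.4f}")
print(f"small-worldness index SWI = {small_worldness(Cn, Ln):.4f}")
# SWI compares clustering per unit path length against the
# weight-randomized null: this dense lattice pays in path length
# (Lw_nrm > 1) without excess weighted clustering, so its SWI is below 1;
# networks combining high clustering with short paths score above 1

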