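"""Simulate a two-session EEG cohort with known coupling ground truth.

Builds a small cohort in which one electrode pair is strongly coupled with
a quarter-cycle phase lag, then verifies that the phase lag index (PLI)
measured from the generated signals tracks the planted coupling.
"""

import numpy as np

from eegnetrel import (CohortSpec, connectivity_matrix, epoch_and_select,
                       generate_cohort)

base = np.zeros((6, 6))
base[0, 1] = base[1, 0] = 0.8          # one strong edge
spec = CohortSpec(n_subjects=2, n_channels=6, duration=60.0,
                  bands=(("alpha1", 6.0, 9.0),), coupling_base=base,
                  subject_sd=0.05, noise_sd=0.3, seed=42)
recordings, truth = generate_cohort(spec, with_truth=True)
print(f"{len(recordings)} recordings of shape {recordings[0].data.shape} "
      f"({spec.sampling_rate:.0f} Hz)")

rec = recordings[0]
eps = epoch_and_select(rec, epoch_length=5.0, n_select=12, seed=0,
                       band_name="alpha1")
m = connectivity_matrix(eps, method="pli")
planted = truth.query("subject=='sub000' and session==1 and "
                      "chan_i==0 and chan_j==1").weight.iloc[0]
print(f"planted coupling on edge (0,1): {planted:.2f}")
print(f"measured PLI on edge (0,1):     {m.values[0, 1]:.3f}")
print(f"median PLI on uncoupled edges:  "
      f"{np.median(m.values[2:, 2:][np.triu_indices(4, 1)]):.3f}")
# the coupled edge phase-locks strongly; uncoupled edges sit at the small
# positive bias floor of the PLI estimator
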