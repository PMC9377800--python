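"""Counting nuclei along a fiber from a DAPI-like intensity profile.

Plants a known number of nuclei (Gaussian bumps with an enforced minimum
gap) on a noisy background and counts them as local maxima above a
threshold, merging peaks closer than 5 µm.
"""

import numpy as np

from myoscale.morphometrics import count_nuclei
from myoscale.synthetic import gen_nuclei_profile

profile, true_centers, truth = gen_nuclei_profile(
    length_um=600.0, n_nuclei=15, nucleus_sd_um=3.0,
    amplitude=1.0, background=0.1, noise_sd=0.1, seed=0)

# threshold midway between background and peak; minimum separation at the
# ~10 µm nuclear diameter
result = count_nuclei(profile, threshold=0.7, min_separation_um=10.0)

print(f"fiber length:       600 um, planted nuclei: 15")
print(f"detected nuclei:    {result.count}")
match = np.abs(np.sort(result.peak_positions_um)[:, None]
               - np.sort(true_centers)[None, :]).min(axis=1)
print(f"position error:     median {np.median(match):.2f} um "
      "(detected maxima vs planted centers)")
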