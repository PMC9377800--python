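"""Nematic orientation analysis of a swirly fiber texture.

Renders a synthetic fiber-culture image from a known smooth angle field,
extracts the orientation grid with the structure tensor, and computes the
spatial correlation C(d), the nematic length eta_L (the x-intercept of the
initial linear decay of C) and the fraction of disordered windows (local
nematic order S < 0.5).
"""

import numpy as np

from myoscale.orientation import (
    compute_orientation_field,
    disorder_fraction,
    local_nematic_order,
    nematic_difference,
    nematic_length,
    spatial_correlation,
)
from myoscale.synthetic import gen_orientation_image

image, true_angles, truth = gen_orientation_image(
    shape=(512, 512), correlation_length_um=100.0, n_fibers=800, seed=0)

field = compute_orientation_field(image, sigma=8, grid_size=16, pixel_size=1.0)
curve = spatial_correlation(field)
eta = nematic_length(curve)
order = local_nematic_order(field, window_cells=4)
frac = disorder_fraction(order, threshold=0.5)

off, gs = int(field.origin_offset), int(field.grid_spacing)
nr, nc = field.angles.shape
ref = true_angles[off:off + nr * gs:gs, off:off + nc * gs:gs]
err = np.degrees(nematic_difference(field.angles, ref))[field.valid_mask]

print(f"valid grid cells:        {field.n_valid}/{field.angles.size}")
print(f"median angular error:    {np.median(err):.2f} deg "
      "(structure tensor vs the analytic field the strokes follow)")
print(f"nematic length eta_L:    {eta:.0f} um "
      "(size of aligned domains; grows as fibers co-align)")
print(f"disorder fraction:       {frac:.3f} "
      "(fraction of 4x4-cell windows with S < 0.5)")
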