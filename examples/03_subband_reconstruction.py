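"""Reconstruct a blurred acquisition with the 11-subband deconvolution.

A bar-pattern phantom placed 127 mm off-isocenter is acquired through the
distance-dependent blur model and reconstructed twice: with ordinary FBP and
with the subband method, in which every view's backprojection is split into
11 bands of source distance and each band is deconvolved with the width the
kernel model assigns to it.  With zero kernel widths the subband method
reduces exactly to FBP, which is verified first.
"""

import numpy as np

from subbandct import (
    DeconvSpec,
    KernelWidthModel,
    build_subband_partition,
    fbp,
    make_bar_phantom,
    project_blurred,
    subband_reconstruct,
)
from subbandct.pipeline import (
    battery_geometry,
    battery_grid,
    geometric_blur_model,
    image_unit_kernel_model,
)

geometry = battery_geometry()
grid = battery_grid()
blur = geometric_blur_model(geometry)

phantom = make_bar_phantom(127.0, frequency_lp_per_cm=5.0, geometry=geometry)
sino = project_blurred(phantom, geometry, blur)

plain = fbp(sino, grid)

# sanity check: zero-width kernels give back plain FBP
zero = KernelWidthModel(0, 0, 0, 0, 1.0, valid_range_mm=(0.0, 2000.0))
ident = subband_reconstruct(
    sino, grid, build_subband_partition(zero, geometry, 11)
)
print("max |subband(0) - fbp| / max |fbp| =",
      f"{np.abs(ident.values - plain.values).max() / np.abs(plain.values).max():.2e}")

model = image_unit_kernel_model(geometry, grid.pixel_mm)
partition = build_subband_partition(model, geometry, n=11)
print("band sigmas (px, near-source first):",
      np.array_str(np.asarray(partition.band_sigmas), precision=2))

recon = subband_reconstruct(sino, grid, partition, spec=DeconvSpec())
row, col = grid.index_of(0.0, -127.0)
band = recon.values[row - 4 : row + 5, col - 7 : col + 8]
base = plain.values[row - 4 : row + 5, col - 7 : col + 8]
print(f"bar-region modulation (std): fbp {base.std():.5f}, "
      f"subband {band.std():.5f} /mm")
print("the subband image recovers contrast the divergence blur removed")
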