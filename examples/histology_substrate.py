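"""From a synthetic histology raster to a meshed 3-D substrate.

Generates a reduced-size virtual section (sheetlet bands of polygonal
cells separated by shear layers), morphs it to a lower extra-cellular
fraction, polygonises and extrudes it into a watertight triangle mesh,
and prints the resulting geometry statistics.
"""

import numpy as np

from myowalk import (assemble_lattice, apply_sinusoid, ecv_area,
                     extrude_block, morph_to_ecv, polygonize,
                     synthesize_histology)

raster = synthesize_histology(target_ecs=0.38, roi_um=(200.0, 160.0),
                              n_sheetlets=4, seed=1)
print(f"raster: {raster.cell_ids.size} cells in "
      f"{len(set(raster.sheetlet_of.values()))} sheetlets, "
      f"ECS area fraction {ecv_area(raster):.3f}")

morphed = morph_to_ecv(raster, 0.25, seed=1)
print(f"after thickening morph: ECS area fraction "
      f"{ecv_area(morphed):.3f}")

footprints = polygonize(morphed)
verts = [fp.polygon.shape[0] for fp in footprints]
print(f"polygons: mean {np.mean(verts):.0f} vertices "
      f"(range {min(verts)}-{max(verts)})")

block = extrude_block(footprints, seed=2, axial_margin=5.0, side_segment=15.0,
                      extent_xy=(morphed.shape[1] * morphed.pixel_size,
                                 morphed.shape[0] * morphed.pixel_size))
lattice = assemble_lattice(apply_sinusoid(block, 5.0))
print(f"block: {block.triangles.shape[0]} triangles, "
      f"3-D ECV {block.ecv:.3f}")
print(f"lattice: rotation {lattice.rotation_per_layer_deg:.2f} deg/layer, "
      f"Monte Carlo intra fraction "
      f"{lattice.intra_fraction_mc(5000, seed=0):.3f} "
      f"(expect {1 - block.ecv:.3f})")
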