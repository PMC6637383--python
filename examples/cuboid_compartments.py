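"""Compartment-resolved tensors on the idealised cuboid substrate.

Builds the cuboid lattice at ECV = 25 %, runs PGSE and STEAM at
40 mT/m with D_IC = 1.5 and D_EC = 3.0 um^2/ms, and fits diffusion
tensors separately from intra- and extra-cellular particles.  The
short-diffusion-time spin echo nearly recovers the prescribed
diffusivities along the cell axis; the ~1 s mixing time of the
stimulated echo senses the intercalated-disc caps of the 120 um cells
and pushes the intra-cellular lambda1 far below D_IC.
"""

from myowalk import assemble_lattice, make_cuboid_block, simulate_tensors

block = make_cuboid_block(target_ecv=0.25)
lattice = assemble_lattice(block)
print(f"cuboid substrate: ECV = {lattice.ecv:.3f}, "
      f"pitch = {block.extent[0]:.2f} um, slot = {block.extent[2]:.2f} um")

for kind in ("PGSE", "STEAM"):
    t = simulate_tensors(lattice, kind, 40, d_ic=1.5, d_ec=3.0,
                         n_particles=10_000, seed=0,
                         compartments=("all", "intra", "extra"))
    print(f"{kind}: lambda1(EC) = {t['extra'].eigenvalues[0]:.3f}  "
          f"lambda1(IC) = {t['intra'].eigenvalues[0]:.3f}  "
          f"MD = {t['all'].md:.3f}  FA = {t['all'].fa:.3f}")
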