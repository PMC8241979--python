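"""Map mineral density to the per-voxel elastic material model.

Densities from 395 to 720 mg HA/cm^3 quantize onto a 14-level Young's
modulus ladder (4.045 to 12.170 GPa in 0.625 GPa steps); everything below
the threshold is soft tissue at 0.003 GPa, and the marrow cavity on the
loaded top slice is capped with a stiff 20 GPa plate.
"""

import numpy as np

import rtfe
from rtfe.material import ROLE_BONE, ROLE_CAP, ROLE_SOFT

model = rtfe.MaterialModel()
print("ladder (GPa):", np.array2string(model.ladder_gpa(), precision=3))
for rho in (100, 395, 420, 600, 720, 900):
    e_gpa, role = rtfe.density_to_modulus(rho, model)
    name = {0: "soft", 1: "bone"}[role]
    print(f"  {rho:4d} mg HA/cm^3 -> {e_gpa:7.3f} GPa ({name})")

res = rtfe.make_osteotomy_phantom(rtfe.PhantomSpec(seed=1))
matvol = rtfe.build_material_volume(rtfe.gaussian_filter(res.volume), model)
counts = {name: int((matvol.role == r).sum())
          for name, r in [("soft", ROLE_SOFT), ("bone", ROLE_BONE), ("cap", ROLE_CAP)]}
print("voxel roles:", counts)
print(f"bone volume: {matvol.bone_volume_mm3():.3f} mm^3 "
      "(bone voxel count x voxel volume)")
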