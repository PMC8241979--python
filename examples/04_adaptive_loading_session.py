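"""One full adaptive-loading session: match the load, screen fracture risk.

The session chain is: Gaussian filter -> material ladder -> micro-FE ->
bone mask -> KS matching (Nelder-Mead over the applied force, target
median 700 ue) -> fracture guard (while >= 50 bone voxels are at or above
10,000 ue, step the force down by 2 N). The phantom here has a single
thin strut, so the guard engages.

Runs two desk-scale FE solves; expect a couple of minutes on one CPU.
"""

import rtfe

res = rtfe.make_overloaded_strut_phantom()
check = res.volume.metadata["overload_check"]
print(f"phantom overloaded by construction: {check['over_threshold_count']} voxels "
      f">= 10,000 ue at {check['reference_load_n']:.0f} N")

matvol = rtfe.build_material_volume(rtfe.gaussian_filter(res.volume))
dist = rtfe.effective_strain_field(res.solution, rtfe.bone_mask(matvol))
target = rtfe.default_target()

plan = rtfe.match_load(dist, target)
print(f"matched force F* = {plan.matched_force_n:.2f} N "
      f"(KS statistic {plan.ks_at_match:.4f}, {plan.optimizer_evaluations} evaluations)")

plan = rtfe.fracture_guard(dist, plan)
for force, count in plan.guard_trace:
    print(f"  guard: {force:6.2f} N -> {count:3d} voxels >= 10,000 ue")
if plan.guard_failed:
    print("guard failed: do not load")
else:
    final = rtfe.scale_strains(dist, plan.final_force_n)
    print(f"recommended load {plan.final_force_n:.2f} N, "
          f"median strain {final.median_ue:.0f} ue, "
          f"final over-threshold count {plan.final_count}")

menu = rtfe.enumerate_loads(dist, target, [2, 4, 6, 8, 10, 12, 14])
print("\nactuator load menu (best first):")
print(menu.head(3).to_string(index=False))
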