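"""PCA of arm motion under stretch: variance fractions, projections,
tilt/twist angles.

Generates three rigid arms tilting to 80°/65°/68° maxima (the asymmetry
mimics one agonist-bound arm moving further than the other two), runs PCA
on the Cα coordinates, and measures per-arm tilt angles.
"""

import piezomd as pm
from piezomd.synthetic import ArmSpec, make_arm_tilt_trajectory

traj, truth = make_arm_tilt_trajectory(ArmSpec(seed=0, noise=0.2))
pca = pm.fit_pca(traj, "name CA", superpose=False)
print("variance fractions of the leading modes:",
      [f"{v:.1%}" for v in pca.variance_fractions[:3]])

proj = pm.project_onto_modes(traj, pca, modes=(1, 2), superpose=False)
print(f"mode-1 projection sweeps {proj.projections[0, 0]:.1f} → "
      f"{proj.projections[-1, 0]:.1f} Å of collective Cα displacement")

series = pm.tilt_twist_angles(traj, truth.arms)
for lb in "ABC":
    print(f"arm {lb}: max tilt {series[lb].tilt_deg.max():5.1f}° "
          f"(scheduled {max(truth.tilt_deg[lb]):.0f}°)")
print("mode 1 is the collective outward tilt; arm A (the 'bound' arm) "
      "tilts ~15° further than the other two.")
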