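"""Membrane dome-curvature radius from lipid headgroups.

Generates a curved bilayer whose mid-surface is a radial Gaussian of depth
zh = −30 Å and width σ = 70 Å (analytic peak curvature radius ≈ 81.7 Å,
i.e. ≈ 8.2 nm — the regime of the channel's inverted dome), then runs the
full pipeline: leaflet assignment, periodic tiling + gridding of headgroup
centers of mass, Gaussian surface fit, and the closed-form radius.
"""

import piezomd as pm
from piezomd.synthetic import DomeSpec, make_dome_membrane

spec = DomeSpec(seed=1, zh=-30.0, sigma=70.0, noise_sd=1.0, n_frames=6,
                flatten_to=-10.0)
traj, truth = make_dome_membrane(spec)
print(f"bilayer: {len(truth.labels)} lipids, analytic R at frame 0 = "
      f"{truth.R[0]:.1f} Å ({truth.R[0] / 10:.2f} nm)")

series = pm.curvature_timeseries(traj, truth.config, smooth_grid=False,
                                 span=None)
print(series.table.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print("R grows over time because the dome depth is ramped toward zero — "
      "the membrane flattens as it would under increasing tension.")
print(f"local-mean kernel for the published 52 × 50 grid: "
      f"{pm.kernel_size_rule(52, 50)} cells")
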