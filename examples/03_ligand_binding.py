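"""Find stably bound ligands by windowed RMSF and report their contacts.

Generates 20 ligands — 2 tethered in binding pockets, 18 diffusing in the
membrane, one of which enters from the lower (intracellular) leaflet at
frame 17 — then ranks them by windowed RMSF, reports the top binder's
contact residues, and classifies the scripted entry event.
"""

import piezomd as pm
from piezomd.synthetic import LigandSpec, make_ligand_ensemble

spec = LigandSpec(seed=5, n_bound=2, n_free=18, n_frames=400,
                  entry_side="lower", entry_frame=17)
traj, truth = make_ligand_ensemble(spec)
print(f"box concentration of 20 ligands: "
      f"{pm.ligand_concentration(spec.box, 20):.2f} mM")

sels = {lb: traj.topology.named_selections[lb]
        for lb in truth.bound_labels + truth.free_labels}
series = pm.ligand_rmsf_timecourse(traj, sels, window=20)
rank = pm.rank_ligand_stability(series)
print("most stable ligands (ascending mean RMSF over the tail):")
for lb in rank.order[:4]:
    print(f"  {lb}: {rank.mean_rmsf[lb]:6.2f} Å  "
          f"({'bound' if lb in truth.bound_labels else 'free'} in truth)")

best = rank.order[0]
report = pm.binding_contacts(traj, sels[best], (200, 400), cutoff=4.0)
print(f"{best} pocket residues (contact fraction ≥ 0.5): "
      f"{report.residues_above_threshold}")

entry = pm.classify_entry_leaflet(traj, sels[truth.entry_label],
                                  truth.upper_z, truth.lower_z)
print(f"{truth.entry_label} entered the membrane from the {entry.leaflet} "
      f"leaflet at t = {entry.entry_time_ns:.1f} ns (frame {entry.entry_frame}) "
      "— low RMSF marks a bound pose; the entry side mimics intracellular "
      "agonist access.")
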