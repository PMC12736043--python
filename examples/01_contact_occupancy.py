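"""Contact occupancy and the persistence histogram.

Generates a synthetic trajectory whose four protein-ligand interactions
switch on and off with programmed occupancies, detects them frame by frame
with the geometric criteria (H bond: proton-acceptor 1.9 +/- 0.5 A and angle
>= 120 deg; charged: 4.0 A; hydrophobic: 4.5 A), and keeps the contacts
populated at least 10% of the time.
"""
from ligdyn.contacts import build_timelines, persistence_histogram
from ligdyn.synthdata import TrajectorySpec, gen_trajectory, truth_interaction_defs

traj, truth = gen_trajectory(TrajectorySpec(seed=7))
timelines = build_timelines(traj, truth_interaction_defs(truth))

print(f"{traj.n_frames} frames, {traj.times_ns[-1]:.0f} ns")
for t in timelines:
    target = truth["target_occupancy"][t.interaction.label]
    print(f"  {t.interaction.label:<24s} kind={t.interaction.kind:<12s} "
          f"occupancy={t.occupancy:.4f} (programmed {target:.2f})")

hist = persistence_histogram(timelines, min_occupancy=0.10)
print("\npersistent contacts (>= 10% of frames):")
print(hist.to_string(index=False))
# The measured occupancy equals the generator's frame-exact truth; the rare
# (5%) contact is real but falls below the persistence threshold.
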