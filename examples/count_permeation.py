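"""Count single-file water crossings in a toy pore trajectory.

Builds a synthetic trajectory with 10 planted complete crossings, 5 waters
that enter and retreat, 3 waters that pass around the single-file region
at large radius, and 5 bulk decoys — then runs the cylinder counter and
the radial containment filter.
"""

from aquagate import (
    CylinderSpec,
    assign_compartments,
    detect_permeation_events,
    filter_spurious_events,
    simulate_toy_trajectory,
    transit_time_stats,
)

traj, truth = simulate_toy_trajectory(seed=1)
print(f"trajectory: {traj.n_atoms} waters x {traj.n_frames} frames "
      f"({traj.frame_period_ps} ps period)")

cylinder = CylinderSpec(center_mode="fixed")  # 2.2 nm x 1.5 nm at the origin
labels = assign_compartments(traj, cylinder, water_atom_ids=traj.atom_ids)
events = detect_permeation_events(labels)
kept, removed = filter_spurious_events(events)

mean_t, frac1, frac3 = transit_time_stats(kept)
print(f"planted crossings : {len(truth)}")
print(f"detected raw      : {len(events)}  (includes around-the-pore paths)")
print(f"kept after filter : {len(kept)}   removed: {len(removed)}")
print(f"mean transit      : {mean_t:.2f} ns "
      f"(<1 ns: {frac1:.0%}, <3 ns: {frac3:.0%})")
# The filtered count equals the planted ground truth; the removed events
# are exactly the waters that slipped around the single-file region.
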