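"""Side-chain dihedral time series and rotamer classification.

Builds a minimal four-atom trajectory in which the terminal atom swings
through the three staggered states of a chi1-like dihedral, computes the
signed angle per frame, and classifies each frame as gauche+ (~+60 deg),
trans (~180 deg) or gauche- (~-60 deg).
"""
import numpy as np

from ligdyn.geometry import classify_rotamer, dihedral_series
from ligdyn.structio import AtomRecord, SelectionSpec, TrajectoryFrames

# N-CA-CB-CG with CG rotating about the CA-CB bond (the x axis here)
names = ["N", "CA", "CB", "CG"]
atoms = [AtomRecord(i + 1, n, n[0], "ASP", 31, "A") for i, n in enumerate(names)]
angles = np.array([180.0, 175.0, 60.0, 65.0, -60.0, -170.0])  # programmed chi1
frames = []
for chi in np.radians(angles):
    cg = np.array([2.0, np.cos(chi), np.sin(chi)])
    frames.append(np.array([[0.0, 1, 0], [0, 0, 0], [1, 0, 0], *[cg + [0, 0, 0]]]))
traj = TrajectoryFrames(atoms, np.stack(frames), np.arange(len(angles), dtype=float))

series = dihedral_series(traj, *[SelectionSpec.make(atom_name=n) for n in names])
for t, val in zip(series.times_ns, series.values):
    print(f"  t={t:3.0f} ns  chi1={val:8.2f} deg  -> {classify_rotamer(val).value}")
# trans/gauche boundaries sit at +/-120 deg and 0 deg; a chi1 flip between
# trans and gauche+ is the kind of side-chain rearrangement that lets an
# acidic residue trade its ligand contact for a new partner.
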