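"""Central registry of the analysis defaults.

Every threshold that defines an analysis outcome lives here so a run can be
audited against one block.  Geometric criteria follow the conventions used to
annotate the study system: an H bond is called on the proton-acceptor
distance (heavy atom to proton, not heavy to heavy) falling in 1.9 +/- 0.5 A
with a donor-H...acceptor angle of at least 120 degrees; a contact is deemed
persistent when present in at least 10% of frames; an RMSD plateau tolerates
oscillations of +/- 0.2 nm about its mean.  Cutoffs the source conventions do
not fix numerically (charged-group and hydrophobic proximity, fingerprint
radius) are declared package choices, configurable at every call site.
"""

# H bond: proton-acceptor distance window (A), interpreted as the closed
# interval [1.9 - 0.5, 1.9 + 0.5], and minimum donor-H...acceptor angle (deg).
HBOND_DISTANCE_WINDOW_A = (1.4, 2.4)
HBOND_ANGLE_MIN_DEG = 120.0
# Sanity bound: a proton must sit within a covalent-bond length of its donor.
DONOR_PROTON_MAX_A = 1.3

# Heavy-atom cutoff for opposite-charge group contacts (A).  Ionic pairs that
# are also H-bonded sit near 2.9 A; 4.0 A separates charged contacts from
# long-range approaches.  Inclusive.
CHARGED_CUTOFF_A = 4.0

# Carbon-carbon cutoff for hydrophobic contacts (A); common convention.
HYDROPHOBIC_CUTOFF_A = 4.5

# Residues enter a ligand contact fingerprint when any heavy atom lies within
# this distance (A) of any ligand heavy atom.
FINGERPRINT_CUTOFF_A = 4.0

# A contact is "persistent" when occupied in at least this fraction of frames.
MIN_OCCUPANCY = 0.10

# Plateau criterion: every point within this band (nm) of the segment mean.
PLATEAU_TOLERANCE_NM = 0.2

# Single-linkage Jaccard similarity threshold for merging pose fingerprints
# into one binding location.
JACCARD_THRESHOLD = 0.5

# Triage-score defaults: residues at most segment_gap apart in sequence count
# as one segment; burial counts protein heavy atoms within burial_radius (A)
# of each ligand heavy atom.
TRIAGE_SEGMENT_GAP = 5
TRIAGE_BURIAL_RADIUS_A = 8.0

# Reference scales used to normalize triage components before weighting; the
# composite is a reporting convenience, not a validated score.
TRIAGE_NORMALIZERS = {
    "n_contact_residues": 10.0,
    "n_interactions": 10.0,
    "n_segments": 4.0,
    "triangulation_count": 5.0,
    "burial_index": 20.0,
}

# Residue names never treated as the ligand when flagging HETATM records.
WATER_RESNAMES = frozenset({"HOH", "WAT", "H2O", "TIP", "TIP3", "SOL"})
MONATOMIC_IONS = frozenset({
    "NA", "CL", "K", "MG", "CA", "ZN", "MN", "FE", "CU", "NI", "CO",
    "CD", "BR", "F", "I", "LI", "RB", "CS", "SR", "BA",
})
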