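# Methods

## Scope and data model

`ligdyn` analyzes three kinds of input, all plain text: multi-model PDB
files (trajectory snapshots or docked pose stacks; models become frames and
must share one atom table), TSV tables with a header row (per-frame energies:
`time_ns`, `energy_kcal`; pose scores: `pose_id`, `score_kcal`, optional
`source_bin`), and YAML for interaction definitions and run configuration.
Coordinates are stored in Å (PDB native); RMSD/RMSF are reported in nm
(conversion exactly ÷10) to match the usual presentation of trajectory
deviation plots; distances are reported in Å, dihedrals in degrees on
(−180°, 180°], energies in kcal/mol with more negative meaning more
favorable.

PDB parsing and writing delegate to gemmi. Alternate locations other than
blank or "A" are dropped (a deterministic rule; the analyses need one
conformer). HETATM residues are flagged as ligand unless they are water or a
monatomic ion; an explicit residue-name whitelist overrides this. A PDB
carries no time axis, so frame times come from a `dt_ns` argument (default
1 ns) or an explicit list; all analyses treat frame spacing as data-driven.
Input structures are taken as-is — chain repairs, missing residues and
protonation are upstream concerns.

## Superposition, RMSD, RMSF

Global translation and rotation of the protein are removed by a weighted
Kabsch fit (SVD with the reflection branch corrected, so the result is
always a proper rotation; fewer than 3 fit atoms or a collinear fit
configuration is an error). The default fit selection is the protein
backbone N, CA, C; whether a study's fit used backbone or Cα-only is often
unstated, so the selection is a config option. The default RMSD measure
selection is protein Cα plus every ligand atom including hydrogens; the
reference frame defaults to frame 0 of the supplied trajectory, on the
assumption that the first stored analysis frame is the end of equilibration.
RMSD at the reference frame is reported as exactly 0. RMSF uses the standard
definition about the time-averaged fitted position,
RMSF_i = sqrt(mean_t |r_i(t) − ⟨r_i⟩|²), per atom, optionally aggregated to
residues by averaging mean-square fluctuations before the root. Mass
weighting is not implemented; inputs are assumed pre-imaged (no periodic
wrapping).

Dihedrals use the standard atan2 formulation of the signed IUPAC torsion;
frames where three consecutive atoms are collinear yield NaN rather than an
error. Rotamer classes partition (−180°, 180°] into gauche+ (0°, 120°],
trans (120°, 180°] ∪ (−180°, −120°], gauche− (−120°, 0°], with boundary
values assigned to the interval they close — the standard three-state
convention consistent with the ~+60°/~180°/~−60° labels.

## Interaction detectors

* **H bond** — distance is measured from the proton to the acceptor heavy
  atom. Present iff that distance lies in the closed interval
  [1.4, 2.4] Å (i.e. 1.9 ± 0.5 Å) and the donor–H···acceptor angle at the
  proton is ≥ 120°. A proton more than 1.3 Å from its declared donor heavy
  atom is a topology error. Structures without hydrogens cannot support
  H-bond definitions; those definitions are skipped with a warning instead
  of failing the run.
* **Charged contact** — heavy atoms from oppositely tagged formal-charge
  groups within 4.0 Å inclusive. Ionic pairs that are simultaneously
  H-bonded sit near 2.9 Å; the 4.0 Å default is a declared package choice
  separating charged contacts from long-range approaches, not a literature
  constant, and is configurable.
* **Hydrophobic contact** — two carbons within 4.5 Å inclusive (common
  convention; configurable).

Which atoms are donors/acceptors and which groups carry formal charge is
data, not code: `ligdyn/data/chemistry.yaml` ships tables for the standard
residues plus the synthetic ligand, and any call site accepts a replacement.
Aromatic π-stacking and cation–π detection are out of scope; such proximity
shows up only as unclassified distance.

Occupancy is the mean of the per-frame presence flags; the persistence
histogram keeps contacts with occupancy ≥ 10% (inclusive) sorted descending.
Residue fingerprints collect protein residues with any heavy atom within
4.0 Å of any ligand heavy atom (hydrogens never count).

## Plateau segmentation

The stability criterion — every point within ± 0.2 nm (configurable) of the
segment's own mean — is operationalized as a greedy two-pointer scan: grow
the window while the running max/min stay within the band around the running
mean; on violation close the segment and restart at the violating frame.
Ties between overlapping candidates therefore resolve to the earlier start,
and the output is deterministic. Segments shorter than `min_length_ns`
(default 5% of the series span) are discarded; adjacent segments separated
by less than `merge_gap_ns` (default 0 = off) are merged when the union,
gap frames included, still satisfies the criterion. Reported means and
maximum deviations are recomputable from the raw series, and the criterion
holds exactly on every returned segment. This operationalizes what is often
done by visual inspection; exact reproduction of visually chosen windows is
not expected, only criterion satisfaction. Statistical change-point methods
(PELT etc.) are deliberately not used — the contract is the literal
criterion.

## Energy statistics and ISR

Window statistics use inclusive time bounds and require at least two frames:
mean μ, sample standard deviation σ (n−1 denominator — at thousands of
frames the choice is negligible but it is fixed for determinism), and the
most negative energy E_min. The intrinsic specificity ratio is
ISR = (μ − E_min)/σ, reported as a positive magnitude; it is invariant under
energy shift and positive scaling, undefined (error) when σ = 0, and by
default computed over the full series with any window supported. Every frame
in the window is used (no subsampling). The inverse relation
E_min = μ − ISR·σ is exposed (`implied_min_energy`) for consistency checks
of printed (μ, σ, ISR) triples against reported distribution extremes.
Histograms use fixed-width bins with the first bin centered on the window
minimum; counts sum to the frame count. Entropy-extended ISR variants are
not implemented.

## Pose deconvolution and triage

Poses are treated as rigid-receptor snapshots against the single supplied
protein structure. Grouping is single-linkage on fingerprint Jaccard
similarity with threshold 0.5 (configurable): single linkage because bins
sharing slightly different surrounding residues should merge into one
location, and there is no principled numeric rule for "slightly different" —
the threshold is a declared surrogate. Poses with empty fingerprints go to a
reserved *unassociated* group (id −1). Groups are identified and ordered by
their smallest member pose id, making the output invariant to input order;
raising the threshold can only split groups, never merge them. Each group
reports its most negative member score (the value a docking histogram would
plot) alongside the full sorted score list. A group's consensus fingerprint
is the set of residues present in a strict majority of member fingerprints.

Triage components operationalize qualitative pose-selection criteria, and
each is reported raw:

- `n_contact_residues` — fingerprint size;
- `n_interactions` by kind, enumerated from the chemistry tables (H bonds
  require protons in the structure);
- `n_segments` — maximal runs of contact-residue sequence numbers where
  consecutive members differ by ≤ 5 (tertiary-structure engagement: many
  segments means the fold, not one loop, grips the ligand);
- `triangulation_count` — ligand heavy atoms contacted by ≥ 2 distinct
  residues;
- `burial_index` — mean number of protein heavy atoms within 8 Å of each
  ligand heavy atom. This is a proximity surrogate for "recessed from the
  surface", not a solvent-accessibility measure, and must not be read as
  one.

The composite is Σ wᵢ·(componentᵢ/scaleᵢ) with default weights 1.0 and fixed
reference scales (10 residues, 10 interactions, 4 segments, 5 triangulated
atoms, 20 neighbors). Manual pose selection is a judgment call; the
composite is an explicitly arbitrary convenience ranking, which is why the
components are always reported individually.

## Synthetic data: what it emulates and what it does not

The generators exist so every analysis stage can be verified in a closed
loop against machine-readable truth.

* **Scaffold** — ten residues (Arg9, Phe10, Ala11, Pro12, Ser13, Glu45,
  Tyr172, Val176, Ile188, Arg190) placed 9 Å apart on a line with locally
  plausible backbone/side-chain geometry, plus a seven-atom ligand. The
  spacing makes every residue's neighborhood geometrically independent, so
  each programmed contact controls exactly one detector. It is deliberately
  not a folded protein: the detectors need local geometry only.
* **Trajectories** — each scheduled contact is independently on per frame
  with its target occupancy (i.i.d. Bernoulli by default; an optional Markov
  stay-probability adds frame-to-frame correlation for studying
  intermittent contacts, off by default for analyzability). On-frames place
  the controlled ligand atom at the bound detector distance (1.9 Å
  proton–acceptor for H bonds, 2.9 Å for charged, 3.8 Å for hydrophobic);
  off-frames at 6.5 Å, outside every window. An optional dissociation window
  forces all contacts off and displaces the ligand > 20 Å. Gaussian
  coordinate noise (default sd 0.03 Å) perturbs every atom — small enough
  (≳ 12 σ margins) that the truth on/off matrix is recovered exactly.
  Defaults: 2000 frames at 0.5 ns (a microsecond-scale run), occupancies
  {0.80, 0.35, 0.10, 0.05} spanning persistent, intermittent and rare
  contacts of all three kinds.
* **Energy series** — i.i.d. Gaussian draws per segment. Defaults are two
  segments, (μ = −18.25, σ = 12.26) then (μ = −29.00, σ = 4.49) kcal/mol
  over 0–500 and 500–1000 ns: a broad early distribution tightening late,
  the typical plateau structure of a binding simulation.
* **Pose sets** — locations anchored on disjoint residue pairs; each pose
  pins one ligand heavy atom 3 Å above each anchor's top side-chain heavy
  atom (inside the 4 Å fingerprint cutoff) and parks the rest away from the
  protein; scores come from per-location Gaussian mixtures. The default
  three locations include one bimodal site (3 poses near −6.5, 7 near
  −4.5 kcal/mol).

Identical (spec, seed) pairs produce byte-identical files. Because the
synthetic dynamics are uncorrelated switches on a rigid scaffold, passing
the closed-loop tests demonstrates that the bookkeeping (detection windows,
occupancy accounting, filtering, clustering, statistics) is correct — it
says nothing about force fields, sampling or the realism of any particular
system.

## Numerical choices and degenerate inputs

Inclusive boundaries throughout (detector cutoffs, the 10% persistence
threshold, window time bounds, the 1.4/2.4 Å H-bond window). RMSD at the
reference frame is set to exactly 0. Collinear dihedral frames yield NaN;
collinear superposition targets raise. σ = 0 makes ISR an error, not a
sentinel value. Histogram top edges are guarded against floating-point
shortfall so no frame is dropped. Single-linkage ties and group identities
are fixed by smallest pose id. The plateau scan's running mean makes
acceptance order-dependent in principle; the greedy earlier-start rule
resolves this deterministically.

## Problem sizes

The test suite and the acceptance script run on the generators' default
sizes — 2000-frame trajectories, 1000-point plateau series, 10⁴-sample
energy distributions, 1000-case geometry oracle sweeps, 20-pose sets —
chosen as the smallest sizes at which binomial/CLT bounds make the
closed-loop checks sharp. Everything completes in seconds on one CPU.

## Known limitations

No mass-weighted superposition or periodic-boundary handling; no π-system
interaction detection; no water-mediated bridges; no solvent-accessibility
burial measure; rigid-receptor fingerprints for poses; PDB-only structure
I/O (no XTC/TRR/DLG/mmCIF); the triage composite is an unvalidated
convenience. The synthetic generator's contacts are statistically
independent unless the Markov option is used, unlike real correlated
dynamics.
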