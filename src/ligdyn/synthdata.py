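"""Seeded generators of toy trajectories, energy series and pose sets.

Real inputs to this package are microsecond MD snapshots, MM/GBSA energy
tables and docking pose stacks.  The generators here emulate the *features*
of those inputs that the analyses consume -- contacts that switch on and off
with programmed occupancies, optional ligand dissociation, piecewise
mean/SD energy structure, pose clusters at distinct protein locations with
their own score distributions -- on a miniature synthetic scaffold, and emit
machine-readable ground truth alongside every artifact so each analysis
stage can be verified in a closed loop.

The scaffold is a deliberately artificial ~10-residue chain laid out on a
coarse grid with locally plausible bond geometry; the detectors only need
local geometry, not a folded protein.  Contact on/off draws are i.i.d.
Bernoulli per frame by default (an optional Markov ``persistence`` parameter
adds frame-to-frame correlation); real contacts are autocorrelated, so
passing occupancy-recovery tests here demonstrates correctness of the
bookkeeping, not realism of the dynamics.

Identical (spec, seed) pairs produce byte-identical outputs.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .contacts import InteractionDef
from .energetics import EnergySeries
from .poses import PoseRecord, PoseSet
from .structio import (AtomRecord, TrajectoryFrames, charge_group_of,
                       load_chemistry, write_multimodel_pdb, write_table)


class SynthError(ValueError):
    pass


# ---------------------------------------------------------------------------
# scaffold
# ---------------------------------------------------------------------------

# residue cast: (res_seq, res_name); 9 A spacing along x keeps every
# residue's neighborhood geometrically independent of the next.
SCAFFOLD_RESIDUES = (
    (9, "ARG"), (10, "PHE"), (11, "ALA"), (12, "PRO"), (13, "SER"),
    (45, "GLU"), (172, "TYR"), (176, "VAL"), (188, "ILE"), (190, "ARG"),
)
RESIDUE_SPACING_A = 9.0

# sidechain atoms per residue type: (atom_name, dy, dz); tips sit above the
# backbone so a ligand atom can be placed along +y at a controlled distance.
_SIDECHAINS = {
    "ARG": (("CB", 1.5, 0.0), ("NH1", 3.0, 0.0), ("HH11", 4.0, 0.0)),
    "PHE": (("CB", 1.5, 0.0), ("CZ", 3.0, 0.0)),
    "ALA": (("CB", 1.5, 0.0),),
    "PRO": (("CB", 1.5, 0.0),),
    "SER": (("CB", 1.5, 0.0), ("OG", 3.0, 0.0), ("HG", 4.0, 0.0)),
    "GLU": (("CB", 1.5, 0.0), ("OE1", 3.0, 0.0)),
    "TYR": (("CB", 1.5, 0.0), ("OH", 3.0, 0.0), ("HH", 4.0, 0.0)),
    "VAL": (("CB", 1.5, 0.0),),
    "ILE": (("CB", 1.5, 0.0),),
}

LIGAND_RESNAME = "LIG"
LIGAND_RES_SEQ = 900
LIGAND_CHAIN = "L"
# ligand atom table; home offsets (dx, dy, dz) relative to the ligand's home
# anchor point, used whenever a contact schedule does not control the atom.
LIGAND_ATOMS = (
    ("N1", 0.0, 0.0, 0.0), ("H1", 0.0, 1.0, 0.0),
    ("O1", 2.0, 0.0, 0.0), ("O2", 4.0, 0.0, 0.0), ("O3", 6.0, 0.0, 0.0),
    ("C1", 8.0, 0.0, 0.0), ("C2", 10.0, 0.0, 0.0),
)


def _element_of(name: str) -> str:
    return name[0]


@dataclass
class Scaffold:
    """Atom table + base coordinates of the synthetic protein-ligand system."""

    atoms: list[AtomRecord]
    base_coords: np.ndarray  # (n_atoms, 3)
    index: dict  # (res_seq, atom_name) -> atom index; ligand keyed by ("LIG", name)

    def idx(self, res_seq, atom_name: str) -> int:
        return self.index[(res_seq, atom_name)]

    def lig_idx(self, atom_name: str) -> int:
        return self.index[(LIGAND_RESNAME, atom_name)]

    def top_sidechain(self, res_seq: int) -> int:
        """Index of the residue's highest-y sidechain heavy atom."""
        best, besty = None, -np.inf
        for (rs, name), i in self.index.items():
            if rs == res_seq and name not in ("N", "CA", "C", "O"):
                a = self.atoms[i]
                if not a.is_hydrogen and self.base_coords[i, 1] > besty:
                    best, besty = i, self.base_coords[i, 1]
        if best is None:
            raise SynthError(f"residue {res_seq} has no sidechain heavy atom")
        return best


def build_scaffold(ligand_home_y: float = 14.0) -> Scaffold:
    """Construct the miniature scaffold with the ligand parked at its home spot."""
    chem = load_chemistry()
    atoms: list[AtomRecord] = []
    coords: list[list[float]] = []
    index: dict = {}
    serial = 0

    def add(name, res_name, res_seq, chain, lig, x, y, z):
        nonlocal serial
        serial += 1
        atoms.append(AtomRecord(
            serial=serial, atom_name=name, element=_element_of(name),
            res_name=res_name, res_seq=res_seq, chain_id=chain, is_ligand=lig,
            formal_charge_group=charge_group_of(res_name, name, chem)))
        coords.append([x, y, z])
        index[(LIGAND_RESNAME if lig else res_seq, name)] = len(atoms) - 1

    for k, (rs, rn) in enumerate(SCAFFOLD_RESIDUES):
        x = RESIDUE_SPACING_A * k
        add("N", rn, rs, "A", False, x - 1.2, -0.8, 0.0)
        add("CA", rn, rs, "A", False, x, 0.0, 0.0)
        add("C", rn, rs, "A", False, x + 1.2, -0.8, 0.0)
        add("O", rn, rs, "A", False, x + 1.2, -2.0, 0.0)
        for name, dy, dz in _SIDECHAINS.get(rn, ()):
            add(name, rn, rs, "A", False, x, dy, dz)

    cx = RESIDUE_SPACING_A * (len(SCAFFOLD_RESIDUES) - 1) / 2.0
    for name, dx, dy, dz in LIGAND_ATOMS:
        add(name, LIGAND_RESNAME, LIGAND_RES_SEQ, LIGAND_CHAIN, True,
            cx + dx, ligand_home_y + dy, dz)

    return Scaffold(atoms=atoms, base_coords=np.array(coords), index=index)


# ---------------------------------------------------------------------------
# trajectory generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactScheduleEntry:
    """One programmed interaction: which atoms, what occupancy, what geometry.

    ``kind``: hbond / charged / hydrophobic.  For hbond the donor side is
    inferred: a ligand N1 partner donates through H1; otherwise the protein
    residue's chemistry-table donor pair donates to the ligand atom.
    ``on_distance_A`` is the controlled detector distance in bound frames
    (proton-acceptor for hbond, heavy-heavy otherwise); ``off_distance_A``
    places the atom outside every detector window in unbound frames.
    """

    label: str
    kind: str
    res_seq: int
    protein_atom: str
    ligand_atom: str
    occupancy: float
    on_distance_A: float = None
    off_distance_A: float = 6.5
    protein_proton: str | None = None  # for protein-side donors

    def __post_init__(self):
        if not 0.0 <= self.occupancy <= 1.0:
            raise SynthError(f"{self.label}: occupancy must be in [0, 1]")
        if self.on_distance_A is None:
            object.__setattr__(self, "on_distance_A",
                               {"hbond": 1.9, "charged": 2.9, "hydrophobic": 3.8}[self.kind])


def default_contact_schedule() -> list[ContactScheduleEntry]:
    """The study-condition schedule: one persistent, one intermittent, one
    occasional and one rare contact, of three kinds."""
    return [
        ContactScheduleEntry("Ser13:OG-HG...LIG:O1", "hbond", 13, "OG", "O1",
                             occupancy=0.80, protein_proton="HG"),
        ContactScheduleEntry("LIG:N1-H1...Glu45:OE1", "hbond", 45, "OE1", "N1",
                             occupancy=0.35),
        ContactScheduleEntry("Arg9:NH1+...LIG:O2-", "charged", 9, "NH1", "O2",
                             occupancy=0.10),
        ContactScheduleEntry("Phe10:CZ...LIG:C1", "hydrophobic", 10, "CZ", "C1",
                             occupancy=0.05),
    ]


@dataclass
class TrajectorySpec:
    """Parameters of a synthetic trajectory."""

    n_frames: int = 2000
    dt_ns: float = 0.5
    contact_schedule: list[ContactScheduleEntry] = field(default_factory=default_contact_schedule)
    dissociation_window_ns: tuple[float, float] | None = None
    noise_sd_A: float = 0.03
    persistence: float | None = None  # optional Markov stay-probability
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise SynthError("n_frames must be >= 2")
        used = [e.ligand_atom for e in self.contact_schedule]
        if len(set(used)) != len(used):
            raise SynthError("each schedule entry must control a distinct ligand atom")
        if any(e.ligand_atom == "H1" for e in self.contact_schedule):
            raise SynthError("H1 is controlled implicitly by the N1 donor entry")


def _interaction_def_dict(e: ContactScheduleEntry) -> dict:
    if e.kind == "hbond":
        if e.ligand_atom == "N1":  # ligand donates
            return {"label": e.label, "kind": "hbond",
                    "donor_heavy": {"atom_name": "N1", "is_ligand": True},
                    "proton": {"atom_name": "H1", "is_ligand": True},
                    "acceptor_heavy": {"res_seq": e.res_seq, "atom_name": e.protein_atom,
                                       "is_ligand": False}}
        return {"label": e.label, "kind": "hbond",
                "donor_heavy": {"res_seq": e.res_seq, "atom_name": e.protein_atom,
                                "is_ligand": False},
                "proton": {"res_seq": e.res_seq, "atom_name": e.protein_proton,
                           "is_ligand": False},
                "acceptor_heavy": {"atom_name": e.ligand_atom, "is_ligand": True}}
    return {"label": e.label, "kind": e.kind,
            "protein_atom": {"res_seq": e.res_seq, "atom_name": e.protein_atom,
                             "is_ligand": False},
            "ligand_atom": {"atom_name": e.ligand_atom, "is_ligand": True}}


def truth_interaction_defs(truth: dict) -> list[InteractionDef]:
    """Rebuild the InteractionDef list recorded in a trajectory truth dict."""
    return [InteractionDef.from_dict(d) for d in truth["interactions"]]


UP = np.array([0.0, 1.0, 0.0])


def gen_trajectory(spec: TrajectorySpec) -> tuple[TrajectoryFrames, dict]:
    """Generate a trajectory with programmed contact occupancies.

    Per frame, each scheduled contact is independently on with its target
    occupancy (or follows a two-state Markov chain with that stationary
    occupancy when ``persistence`` is set).  On frames place the controlled
    ligand atom at the bound detector distance from its protein anchor; off
    frames place it ``off_distance_A`` away, outside every detector window.
    During the dissociation window every contact is forced off and the whole
    ligand is displaced > 20 A from the scaffold.  Gaussian coordinate noise
    (sd ``noise_sd_A``) is added to every atom.

    Returns the trajectory and a truth dict recording the interaction
    definitions, the frame-exact on/off matrix and exact occupancies.
    """
    rng = np.random.default_rng(spec.seed)
    scaffold = build_scaffold()
    n, m = spec.n_frames, len(spec.contact_schedule)
    times = np.arange(n, dtype=float) * spec.dt_ns

    for e in spec.contact_schedule:
        if (e.res_seq, e.protein_atom) not in scaffold.index:
            raise SynthError(f"{e.label}: atom {e.protein_atom} of residue "
                             f"{e.res_seq} absent from scaffold")
        if (LIGAND_RESNAME, e.ligand_atom) not in scaffold.index:
            raise SynthError(f"{e.label}: ligand atom {e.ligand_atom} absent")

    # frame-exact on/off draws
    on = np.zeros((m, n), dtype=bool)
    for k, e in enumerate(spec.contact_schedule):
        if spec.persistence is None:
            on[k] = rng.random(n) < e.occupancy
        else:
            p = spec.persistence
            state = rng.random() < e.occupancy
            for f in range(n):
                if rng.random() >= p:
                    state = rng.random() < e.occupancy
                on[k, f] = state

    dissoc = np.zeros(n, dtype=bool)
    if spec.dissociation_window_ns is not None:
        lo, hi = spec.dissociation_window_ns
        dissoc = (times >= lo) & (times <= hi)
        on[:, dissoc] = False

    coords = np.tile(scaffold.base_coords, (n, 1, 1))
    for k, e in enumerate(spec.contact_schedule):
        pa = scaffold.idx(e.res_seq, e.protein_atom)
        la = scaffold.lig_idx(e.ligand_atom)
        anchor = scaffold.base_coords[pa]
        if e.kind == "hbond" and e.ligand_atom == "N1":
            h1 = scaffold.lig_idx("H1")
            d_on, d_off = e.on_distance_A, e.off_distance_A
            coords[:, h1] = anchor + UP * np.where(on[k], d_on, d_off)[:, None]
            coords[:, la] = anchor + UP * np.where(on[k], d_on + 1.0, d_off + 1.0)[:, None]
        elif e.kind == "hbond":
            proton = scaffold.base_coords[scaffold.idx(e.res_seq, e.protein_proton)]
            u = (proton - anchor) / np.linalg.norm(proton - anchor)
            coords[:, la] = proton + u * np.where(on[k], e.on_distance_A,
                                                  e.off_distance_A)[:, None]
        else:
            coords[:, la] = anchor + UP * np.where(on[k], e.on_distance_A,
                                                   e.off_distance_A)[:, None]

    if dissoc.any():
        lig_idx = [i for i, a in enumerate(scaffold.atoms) if a.is_ligand]
        coords[np.ix_(np.nonzero(dissoc)[0], lig_idx)] += np.array([0.0, 50.0, 0.0])

    coords = coords + rng.normal(0.0, spec.noise_sd_A, size=coords.shape)
    traj = TrajectoryFrames(scaffold.atoms, coords, times)

    truth = {
        "seed": spec.seed,
        "n_frames": n,
        "dt_ns": spec.dt_ns,
        "noise_sd_A": spec.noise_sd_A,
        "interactions": [_interaction_def_dict(e) for e in spec.contact_schedule],
        "target_occupancy": {e.label: e.occupancy for e in spec.contact_schedule},
        "on_matrix": {e.label: on[k].astype(int).tolist()
                      for k, e in enumerate(spec.contact_schedule)},
        "occupancy_exact": {e.label: float(on[k].mean())
                            for k, e in enumerate(spec.contact_schedule)},
        "dissociation_window_ns": (list(spec.dissociation_window_ns)
                                   if spec.dissociation_window_ns else None),
    }
    return traj, truth


# ---------------------------------------------------------------------------
# energy generator
# ---------------------------------------------------------------------------

@dataclass
class EnergySpec:
    """Piecewise-Gaussian energy series: ordered, non-overlapping segments.

    Default segments mirror the broad-then-tight plateau structure typical of
    a binding simulation: a wide early distribution and a narrower late one.
    """

    segments: list[tuple[float, float, float, float]] = field(
        default_factory=lambda: [(0.0, 500.0, -18.25, 12.26),
                                 (500.0, 1000.0, -29.00, 4.49)])
    dt_ns: float = 0.5
    seed: int = 0

    def __post_init__(self):
        prev_end = None
        for (s, e, mu, sd) in self.segments:
            if e <= s:
                raise SynthError(f"segment ({s}, {e}) empty")
            if sd < 0:
                raise SynthError("sigma must be >= 0")
            if prev_end is not None and s < prev_end:
                raise SynthError("segments must be ordered and non-overlapping")
            prev_end = e


def gen_energy_series(spec: EnergySpec) -> tuple[EnergySeries, dict]:
    """i.i.d. Gaussian draws per segment; truth records programmed and realized stats."""
    rng = np.random.default_rng(spec.seed)
    times, energies, seg_truth = [], [], []
    t0 = spec.segments[0][0]
    t_end = spec.segments[-1][1]
    all_t = np.arange(t0, t_end, spec.dt_ns)
    for (s, e, mu, sd) in spec.segments:
        # frames in [s, e): each segment owns its left edge
        mask = (all_t >= s) & (all_t < e)
        t = all_t[mask]
        vals = rng.normal(mu, sd, size=t.size) if sd > 0 else np.full(t.size, mu)
        times.append(t)
        energies.append(vals)
        seg_truth.append({
            "start_ns": s, "end_ns": e, "mu": mu, "sigma": sd, "n": int(t.size),
            "realized_mu": float(np.mean(vals)),
            "realized_sigma": float(np.std(vals, ddof=1)) if t.size > 1 else 0.0,
            "realized_min": float(np.min(vals)),
        })
    series = EnergySeries(np.concatenate(times), np.concatenate(energies))
    truth = {"seed": spec.seed, "dt_ns": spec.dt_ns, "segments": seg_truth}
    return series, truth


# ---------------------------------------------------------------------------
# pose-set generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoseLocation:
    """One programmed binding location.

    ``anchor_res_seqs`` are two (or more) scaffold residues the poses will
    contact; ``score_components`` is a list of (mu, sigma, n) Gaussian score
    modes, together defining n_poses for the location.
    """

    name: str
    anchor_res_seqs: tuple[int, ...]
    score_components: tuple[tuple[float, float, int], ...]

    @property
    def n_poses(self) -> int:
        return sum(c[2] for c in self.score_components)


def default_pose_locations() -> list[PoseLocation]:
    """Three disjoint locations; the first carries a bimodal score profile
    (a few strong poses near -6.5 kcal/mol, more weak ones near -4.5)."""
    return [
        PoseLocation("crystal_site", (9, 10), ((-6.5, 0.1, 3), (-4.5, 0.1, 7))),
        PoseLocation("site_2", (13, 45), ((-5.0, 0.2, 6),)),
        PoseLocation("site_3", (176, 188), ((-3.8, 0.2, 4),)),
    ]


@dataclass
class PoseSpec:
    """Parameters of a synthetic docked pose set."""

    locations: list[PoseLocation] = field(default_factory=default_pose_locations)
    jitter_sd_A: float = 0.1
    max_poses: int = 200
    seed: int = 0

    def __post_init__(self):
        seen: set[int] = set()
        for loc in self.locations:
            if loc.n_poses < 1:
                raise SynthError(f"{loc.name}: needs at least one pose")
            overlap = seen & set(loc.anchor_res_seqs)
            if overlap:
                raise SynthError(f"anchor residues {sorted(overlap)} shared across locations")
            seen |= set(loc.anchor_res_seqs)
        if sum(l.n_poses for l in self.locations) > self.max_poses:
            raise SynthError("total poses exceed max_poses")


def gen_pose_set(spec: PoseSpec) -> tuple[TrajectoryFrames, PoseSet, pd.DataFrame, dict]:
    """Generate (protein structure, pose set, score table, truth).

    Each pose places one ligand heavy atom 3 A above the top sidechain heavy
    atom of each anchor residue (inside the fingerprint cutoff) and parks the
    remaining atoms well away from the protein; scores are drawn from the
    location's Gaussian mixture.  Truth maps pose_id -> location name.
    """
    rng = np.random.default_rng(spec.seed)
    scaffold = build_scaffold()
    prot_atoms = [a for a in scaffold.atoms if not a.is_ligand]
    prot_coords = scaffold.base_coords[[i for i, a in enumerate(scaffold.atoms)
                                        if not a.is_ligand]]
    protein = TrajectoryFrames(prot_atoms, prot_coords[None, :, :], [0.0])

    lig_atoms = [a for a in scaffold.atoms if a.is_ligand]
    lig_names = [a.atom_name for a in lig_atoms]
    heavy_names = [n for n in lig_names if not n.startswith("H")]

    poses: list[PoseRecord] = []
    rows = []
    truth_map = {}
    pid = 0
    for li, loc in enumerate(spec.locations):
        anchors = [scaffold.base_coords[scaffold.top_sidechain(rs)]
                   for rs in loc.anchor_res_seqs]
        scores = np.concatenate([rng.normal(mu, sd, size=cn)
                                 for (mu, sd, cn) in loc.score_components])
        for s in scores:
            pid += 1
            coords = np.zeros((len(lig_atoms), 3))
            # park everything far from the protein first
            center = np.mean(anchors, axis=0)
            for ai, name in enumerate(lig_names):
                coords[ai] = center + np.array([0.3 * ai, 9.0, 1.0 * (ai % 3)])
            # then pin one heavy atom 3 A above each anchor
            for k, apos in enumerate(anchors):
                coords[lig_names.index(heavy_names[k % len(heavy_names)])] = \
                    apos + np.array([0.0, 3.0, 0.0])
            coords += rng.normal(0.0, spec.jitter_sd_A, size=coords.shape)
            poses.append(PoseRecord(pose_id=pid, score_kcal=float(s),
                                    coords=coords, source_bin=li + 1))
            rows.append({"pose_id": pid, "score_kcal": float(s), "source_bin": li + 1})
            truth_map[str(pid)] = loc.name

    scores_df = pd.DataFrame(rows)
    pose_set = PoseSet(ligand_atoms=lig_atoms, poses=poses)
    truth = {
        "seed": spec.seed,
        "locations": [{"name": l.name, "anchors": list(l.anchor_res_seqs),
                       "n_poses": l.n_poses} for l in spec.locations],
        "pose_location": truth_map,
        "scores": {str(p.pose_id): p.score_kcal for p in poses},
    }
    return protein, pose_set, scores_df, truth


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def _dump_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def write_trajectory_files(spec: TrajectorySpec, outdir: str | Path,
                           prefix: str = "traj") -> dict:
    """Generate and write <prefix>.pdb + <prefix>_truth.json; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traj, truth = gen_trajectory(spec)
    pdb = outdir / f"{prefix}.pdb"
    tj = outdir / f"{prefix}_truth.json"
    write_multimodel_pdb(traj, pdb)
    _dump_json(truth, tj)
    return {"pdb": str(pdb), "truth": str(tj)}


def write_energy_files(spec: EnergySpec, outdir: str | Path,
                       prefix: str = "energy") -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    series, truth = gen_energy_series(spec)
    tsv = outdir / f"{prefix}.tsv"
    tj = outdir / f"{prefix}_truth.json"
    series.to_tsv(tsv)
    _dump_json(truth, tj)
    return {"tsv": str(tsv), "truth": str(tj)}


def write_pose_files(spec: PoseSpec, outdir: str | Path,
                     prefix: str = "poses") -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    protein, pose_set, scores_df, truth = gen_pose_set(spec)
    ppdb = outdir / f"{prefix}_protein.pdb"
    qpdb = outdir / f"{prefix}.pdb"
    tsv = outdir / f"{prefix}_scores.tsv"
    tj = outdir / f"{prefix}_truth.json"
    write_multimodel_pdb(protein, ppdb)
    n = len(pose_set.poses)
    pose_traj = TrajectoryFrames(pose_set.ligand_atoms,
                                 np.stack([p.coords for p in pose_set.poses]),
                                 np.arange(n, dtype=float))
    write_multimodel_pdb(pose_traj, qpdb)
    write_table(scores_df, tsv)
    _dump_json(truth, tj)
    return {"protein_pdb": str(ppdb), "poses_pdb": str(qpdb),
            "scores": str(tsv), "truth": str(tj)}
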