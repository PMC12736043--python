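"""Per-frame protein-ligand interaction detection and occupancy timelines.

Three geometric detectors classify an interaction in a single frame:

* **H bond** -- distance measured from the *proton* to the acceptor heavy
  atom (not heavy atom to heavy atom), true when it lies in the closed window
  1.9 +/- 0.5 A and the donor-H...acceptor angle at the proton is >= 120 deg.
* **Charged contact** -- heavy atoms from oppositely tagged formal-charge
  groups within 4.0 A (inclusive); ionic pairs that are simultaneously
  H-bonded sit near 2.9 A.
* **Hydrophobic contact** -- two carbons within 4.5 A (inclusive).

Running a detector over every frame of a trajectory gives a
:class:`ContactTimeline` whose *occupancy* is the fraction of frames in which
the interaction is present; timelines with occupancy of at least 10% make up
the persistence histogram.  A per-frame residue *fingerprint* (protein
residues with any heavy atom within a cutoff of any ligand heavy atom) is the
basis for regrouping docked poses into binding locations.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import defaults
from .structio import (AtomRecord, EmptySelectionError, SelectionSpec,
                       TrajectoryFrames, resolve_selection)

logger = logging.getLogger(__name__)

INTERACTION_KINDS = ("hbond", "charged", "hydrophobic")


class ContactError(ValueError):
    """Invalid interaction definition or atom chemistry."""


@dataclass(frozen=True)
class InteractionDef:
    """A labelled interaction to monitor along a trajectory.

    For ``kind="hbond"`` supply the donor heavy atom, its covalently bound
    proton, and the acceptor heavy atom (each a single-atom selection); the
    donor may belong to either partner.  For ``charged`` and ``hydrophobic``
    supply one protein atom and one ligand atom.
    """

    label: str
    kind: str
    protein_atom: SelectionSpec | None = None
    ligand_atom: SelectionSpec | None = None
    donor_heavy: SelectionSpec | None = None
    proton: SelectionSpec | None = None
    acceptor_heavy: SelectionSpec | None = None

    def __post_init__(self):
        if self.kind not in INTERACTION_KINDS:
            raise ContactError(f"unknown interaction kind {self.kind!r}")
        if self.kind == "hbond":
            if not (self.donor_heavy and self.proton and self.acceptor_heavy):
                raise ContactError(
                    f"{self.label}: hbond needs donor_heavy, proton and acceptor_heavy")
        else:
            if not (self.protein_atom and self.ligand_atom):
                raise ContactError(
                    f"{self.label}: {self.kind} needs protein_atom and ligand_atom")

    @classmethod
    def from_dict(cls, d: dict) -> "InteractionDef":
        d = dict(d)
        for key in ("protein_atom", "ligand_atom", "donor_heavy", "proton", "acceptor_heavy"):
            if key in d and d[key] is not None:
                d[key] = SelectionSpec.from_dict(d[key])
        return cls(**d)


@dataclass
class ContactTimeline:
    """Per-frame presence and distance of one interaction."""

    interaction: InteractionDef
    times_ns: np.ndarray
    distances_A: np.ndarray
    present: np.ndarray

    @property
    def occupancy(self) -> float:
        return float(np.mean(self.present))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_ns": self.times_ns,
            "distance_A": self.distances_A,
            "present": self.present.astype(int),
        })


# ---------------------------------------------------------------------------
# single-frame detectors
# ---------------------------------------------------------------------------

def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def detect_hbond(frame: np.ndarray, donor_heavy: int, proton: int, acceptor_heavy: int,
                 distance_window_A: tuple[float, float] = defaults.HBOND_DISTANCE_WINDOW_A,
                 angle_min_deg: float = defaults.HBOND_ANGLE_MIN_DEG) -> tuple[bool, float]:
    """Classify one putative H bond in one frame.

    Returns ``(present, proton-acceptor distance in A)``.  Present iff the
    proton-acceptor distance lies in the closed window and the
    donor-H...acceptor angle measured at the proton is >= the threshold.
    Raises :class:`ContactError` if the proton is not within a covalent-bond
    length of its donor heavy atom.
    """
    D, H, A = frame[donor_heavy], frame[proton], frame[acceptor_heavy]
    if np.linalg.norm(H - D) >= defaults.DONOR_PROTON_MAX_A:
        raise ContactError(
            f"proton {proton} is {np.linalg.norm(H - D):.2f} A from donor {donor_heavy}; "
            "not a covalent donor-H pair")
    d_ha = float(np.linalg.norm(A - H))
    ang = _angle_deg(D - H, A - H)
    ok = (distance_window_A[0] <= d_ha <= distance_window_A[1]) and ang >= angle_min_deg
    return bool(ok), d_ha


def detect_charged(frame: np.ndarray, atom_cationic: int, atom_anionic: int,
                   atoms: Sequence[AtomRecord],
                   cutoff_A: float = defaults.CHARGED_CUTOFF_A) -> tuple[bool, float]:
    """Opposite-charge heavy-atom contact within ``cutoff_A`` (inclusive)."""
    gc = atoms[atom_cationic].formal_charge_group
    ga = atoms[atom_anionic].formal_charge_group
    if {gc, ga} != {"cationic", "anionic"}:
        raise ContactError(
            f"charged contact needs opposite formal charge groups, got {gc!r}/{ga!r}")
    d = float(np.linalg.norm(frame[atom_cationic] - frame[atom_anionic]))
    return bool(d <= cutoff_A), d


def detect_hydrophobic(frame: np.ndarray, carbon_a: int, carbon_b: int,
                       atoms: Sequence[AtomRecord],
                       cutoff_A: float = defaults.HYDROPHOBIC_CUTOFF_A) -> tuple[bool, float]:
    """Carbon-carbon contact within ``cutoff_A`` (inclusive)."""
    for i in (carbon_a, carbon_b):
        if atoms[i].element.upper() != "C":
            raise ContactError(f"hydrophobic contact atom {i} is not carbon "
                               f"({atoms[i].element})")
    d = float(np.linalg.norm(frame[carbon_a] - frame[carbon_b]))
    return bool(d <= cutoff_A), d


# ---------------------------------------------------------------------------
# timelines over a trajectory
# ---------------------------------------------------------------------------

def _resolve_one(traj: TrajectoryFrames, sel: SelectionSpec, what: str) -> int:
    idx = resolve_selection(traj, sel)
    if idx.size != 1:
        raise ContactError(f"{what} must resolve to exactly 1 atom, got {idx.size}")
    return int(idx[0])


def build_timelines(traj: TrajectoryFrames, defs: Iterable[InteractionDef],
                    hbond_distance_window_A=defaults.HBOND_DISTANCE_WINDOW_A,
                    hbond_angle_min_deg=defaults.HBOND_ANGLE_MIN_DEG,
                    charged_cutoff_A=defaults.CHARGED_CUTOFF_A,
                    hydrophobic_cutoff_A=defaults.HYDROPHOBIC_CUTOFF_A,
                    ) -> list[ContactTimeline]:
    """Evaluate each interaction in every frame.

    Distances are recorded for every frame whether or not the interaction is
    present.  H-bond definitions whose proton cannot be resolved (e.g. a
    structure stored without hydrogens) are skipped with a warning rather than
    failing the run.
    """
    out: list[ContactTimeline] = []
    n = traj.n_frames
    for d in defs:
        if d.kind == "hbond":
            try:
                di = _resolve_one(traj, d.donor_heavy, f"{d.label}: donor_heavy")
                hi = _resolve_one(traj, d.proton, f"{d.label}: proton")
                ai = _resolve_one(traj, d.acceptor_heavy, f"{d.label}: acceptor_heavy")
            except EmptySelectionError:
                logger.warning("skipping hbond %r: proton/donor/acceptor not present "
                               "in structure (missing hydrogens?)", d.label)
                continue
            pres = np.zeros(n, dtype=bool)
            dist = np.zeros(n)
            for f in range(n):
                pres[f], dist[f] = detect_hbond(
                    traj.coords[f], di, hi, ai,
                    distance_window_A=hbond_distance_window_A,
                    angle_min_deg=hbond_angle_min_deg)
        else:
            pi = _resolve_one(traj, d.protein_atom, f"{d.label}: protein_atom")
            li = _resolve_one(traj, d.ligand_atom, f"{d.label}: ligand_atom")
            vec = traj.coords[:, pi, :] - traj.coords[:, li, :]
            dist = np.linalg.norm(vec, axis=1)
            if d.kind == "charged":
                # validate tags once via the single-frame detector
                detect_charged(traj.coords[0], pi, li, traj.atoms,
                               cutoff_A=charged_cutoff_A)
                pres = dist <= charged_cutoff_A
            else:
                detect_hydrophobic(traj.coords[0], pi, li, traj.atoms,
                                   cutoff_A=hydrophobic_cutoff_A)
                pres = dist <= hydrophobic_cutoff_A
        out.append(ContactTimeline(interaction=d, times_ns=traj.times_ns.copy(),
                                   distances_A=np.asarray(dist, dtype=float),
                                   present=np.asarray(pres, dtype=bool)))
    return out


def persistence_histogram(timelines: Sequence[ContactTimeline],
                          min_occupancy: float = defaults.MIN_OCCUPANCY) -> pd.DataFrame:
    """Contacts populated at least ``min_occupancy`` of the time (inclusive).

    Returns a table (label, kind, occupancy) sorted by descending occupancy;
    ties keep input order.  May be empty.
    """
    rows = [(t.interaction.label, t.interaction.kind, t.occupancy)
            for t in timelines if t.occupancy >= min_occupancy]
    df = pd.DataFrame(rows, columns=["label", "kind", "occupancy"])
    return df.sort_values("occupancy", ascending=False, kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# residue fingerprints
# ---------------------------------------------------------------------------

def residue_fingerprint(frame: np.ndarray, atoms: Sequence[AtomRecord],
                        heavy_cutoff_A: float = defaults.FINGERPRINT_CUTOFF_A,
                        ) -> frozenset[tuple[str, int, str]]:
    """Protein residues with any heavy atom within cutoff of any ligand heavy atom.

    Returns a frozenset of ``(chain_id, res_seq, res_name)``; empty for a
    dissociated ligand.
    """
    prot = [i for i, a in enumerate(atoms) if not a.is_ligand and not a.is_hydrogen]
    lig = [i for i, a in enumerate(atoms) if a.is_ligand and not a.is_hydrogen]
    if not lig or not prot:
        return frozenset()
    dm = cdist(frame[prot], frame[lig])
    near = np.any(dm <= heavy_cutoff_A, axis=1)
    return frozenset(atoms[prot[i]].residue_key for i in np.nonzero(near)[0])
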