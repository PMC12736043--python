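"""Docked-pose deconvolution and triage.

Docking programs return a stack of ligand poses with scores, grouped into
score *bins* that are plotted at the most negative member score.  Score bins
are not binding locations: poses from different bins can occupy the same
patch of protein, and one bin can straddle patches.  This module regroups
poses into *location groups* -- sets of poses whose contact-residue
fingerprints agree -- via single-linkage clustering on Jaccard similarity,
reconstructs the per-bin score profile (min score plus the full within-group
score distribution), and computes per-pose triage components that
operationalize the qualitative criteria used to prioritize poses for
simulation: interaction count and diversity, engagement of sequence-distant
chain segments, triangulation of the ligand by multiple residues, and a
burial surrogate.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import defaults
from .contacts import residue_fingerprint
from .structio import (AtomRecord, StructIOError, TrajectoryFrames, load_chemistry,
                       read_multimodel_pdb, read_table)


class PoseError(ValueError):
    pass


@dataclass
class PoseRecord:
    """One docked ligand pose: coordinates, score and (optional) provenance bin."""

    pose_id: int
    score_kcal: float
    coords: np.ndarray  # (n_ligand_atoms, 3) A
    source_bin: int | None = None
    fingerprint: frozenset | None = None


@dataclass
class PoseSet:
    """A pose stack sharing one ligand atom table."""

    ligand_atoms: list[AtomRecord]
    poses: list[PoseRecord]


@dataclass
class LocationGroup:
    """Poses sharing a binding location (similar residue fingerprints)."""

    group_id: int
    pose_ids: list[int]
    consensus_fingerprint: frozenset
    bin_energy: float
    score_list: list[float]
    unassociated: bool = False

    @property
    def n_members(self) -> int:
        return len(self.pose_ids)


def read_pose_set(structure_pdb: str | Path, scores_tsv: str | Path,
                  ligand_resnames: Sequence[str] | None = None) -> PoseSet:
    """Read a multi-model PDB of ligand poses joined to a score table.

    The PDB contains one model per pose (ligand atoms only); the TSV needs
    columns ``pose_id`` (1-based model number) and ``score_kcal``, optionally
    ``source_bin``.  Model count and row count must match; duplicate pose ids
    are rejected.
    """
    traj = read_multimodel_pdb(structure_pdb, ligand_resnames=ligand_resnames)
    df = read_table(scores_tsv, {"pose_id": int, "score_kcal": float})
    if len(df) != traj.n_frames:
        raise PoseError(f"{traj.n_frames} pose models but {len(df)} score rows")
    if df["pose_id"].duplicated().any():
        raise PoseError("duplicate pose_id in score table")
    by_id = df.set_index("pose_id")
    poses = []
    for m in range(traj.n_frames):
        pid = m + 1
        if pid not in by_id.index:
            raise PoseError(f"score table has no row for pose_id {pid}")
        row = by_id.loc[pid]
        sb = int(row["source_bin"]) if "source_bin" in by_id.columns and pd.notna(row.get("source_bin")) else None
        poses.append(PoseRecord(pose_id=pid, score_kcal=float(row["score_kcal"]),
                                coords=traj.coords[m].copy(), source_bin=sb))
    return PoseSet(ligand_atoms=list(traj.atoms), poses=poses)


def _pose_frame(protein: TrajectoryFrames, pose_set: PoseSet,
                pose: PoseRecord) -> tuple[np.ndarray, list[AtomRecord]]:
    """Combined protein(frame 0) + pose coordinates and atom table."""
    atoms = list(protein.atoms) + list(pose_set.ligand_atoms)
    frame = np.vstack([protein.coords[0], pose.coords])
    return frame, atoms


def compute_fingerprints(pose_set: PoseSet, protein: TrajectoryFrames,
                         contact_cutoff_A: float = defaults.FINGERPRINT_CUTOFF_A) -> None:
    """Fill each pose's contact-residue fingerprint in place."""
    for p in pose_set.poses:
        frame, atoms = _pose_frame(protein, pose_set, p)
        p.fingerprint = residue_fingerprint(frame, atoms, heavy_cutoff_A=contact_cutoff_A)


def jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def rebin_by_location(pose_set: PoseSet, protein: TrajectoryFrames,
                      contact_cutoff_A: float = defaults.FINGERPRINT_CUTOFF_A,
                      jaccard_threshold: float = defaults.JACCARD_THRESHOLD,
                      ) -> list[LocationGroup]:
    """Regroup poses into binding locations by fingerprint similarity.

    Single-linkage clustering: poses join one group whenever some chain of
    pairwise Jaccard similarities >= threshold connects them.  Poses with an
    empty fingerprint (dissociated) collect in a reserved *unassociated*
    group.  Groups are ordered and identified by their smallest pose id, so
    the output is invariant to input order.
    """
    if not pose_set.poses:
        raise PoseError("empty pose set")
    if not (0 < jaccard_threshold <= 1):
        raise PoseError("jaccard_threshold must be in (0, 1]")
    compute_fingerprints(pose_set, protein, contact_cutoff_A)

    poses = sorted(pose_set.poses, key=lambda p: p.pose_id)
    assoc = [p for p in poses if p.fingerprint]
    loose = [p for p in poses if not p.fingerprint]

    parent = list(range(len(assoc)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(assoc)):
        for j in range(i + 1, len(assoc)):
            if jaccard(assoc[i].fingerprint, assoc[j].fingerprint) >= jaccard_threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    clusters: dict[int, list[PoseRecord]] = {}
    for i, p in enumerate(assoc):
        clusters.setdefault(find(i), []).append(p)

    groups = []
    for members in clusters.values():
        ids = [p.pose_id for p in members]
        scores = [p.score_kcal for p in members]
        counts: dict = {}
        for p in members:
            for r in p.fingerprint:
                counts[r] = counts.get(r, 0) + 1
        consensus = frozenset(r for r, c in counts.items() if c > len(members) / 2)
        groups.append(LocationGroup(group_id=min(ids), pose_ids=sorted(ids),
                                    consensus_fingerprint=consensus,
                                    bin_energy=min(scores),
                                    score_list=sorted(scores)))
    groups.sort(key=lambda g: g.group_id)
    if loose:
        ids = [p.pose_id for p in loose]
        scores = [p.score_kcal for p in loose]
        groups.append(LocationGroup(group_id=-1, pose_ids=sorted(ids),
                                    consensus_fingerprint=frozenset(),
                                    bin_energy=min(scores), score_list=sorted(scores),
                                    unassociated=True))
    return groups


def groups_from_source_bins(pose_set: PoseSet) -> list[LocationGroup]:
    """Group poses by the docking program's own bin ids (passthrough)."""
    by_bin: dict[int, list[PoseRecord]] = {}
    for p in pose_set.poses:
        if p.source_bin is None:
            raise PoseError(f"pose {p.pose_id} has no source_bin")
        by_bin.setdefault(p.source_bin, []).append(p)
    out = []
    for b in sorted(by_bin):
        members = by_bin[b]
        out.append(LocationGroup(
            group_id=b, pose_ids=sorted(p.pose_id for p in members),
            consensus_fingerprint=frozenset(),
            bin_energy=min(p.score_kcal for p in members),
            score_list=sorted(p.score_kcal for p in members)))
    return out


def bin_score_profile(groups: Sequence[LocationGroup]) -> pd.DataFrame:
    """Per-group score profile: the bin's plotted (minimum) score plus all members.

    One row per group: (group_id, bin_energy, n_members, scores) where
    ``scores`` is the sorted within-group score list -- the data behind a
    bin-vs-individual-pose scatter.
    """
    if not groups:
        raise PoseError("no groups")
    return pd.DataFrame({
        "group_id": [g.group_id for g in groups],
        "bin_energy": [g.bin_energy for g in groups],
        "n_members": [g.n_members for g in groups],
        "scores": [list(g.score_list) for g in groups],
    })


# ---------------------------------------------------------------------------
# triage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TriageScore:
    """Quantitative surrogates for the qualitative pose-selection criteria.

    All components are reported individually; the composite is an arbitrary
    weighted convenience ranking, not a validated score.
    """

    n_contact_residues: int
    n_interactions: Mapping[str, int]
    n_segments: int
    triangulation_count: int
    burial_index: float
    composite: float

    def as_dict(self) -> dict:
        return {
            "n_contact_residues": self.n_contact_residues,
            "n_interactions": dict(self.n_interactions),
            "n_segments": self.n_segments,
            "triangulation_count": self.triangulation_count,
            "burial_index": self.burial_index,
            "composite": self.composite,
        }


def count_segments(res_seqs: Sequence[int], segment_gap: int = defaults.TRIAGE_SEGMENT_GAP) -> int:
    """Number of distinct sequence segments among contact residues.

    Sorted residue numbers are split wherever consecutive members differ by
    more than ``segment_gap``; the count of maximal runs is returned.  A pose
    gripped by many segments engages the protein's tertiary structure rather
    than a single loop.
    """
    rs = sorted(set(int(r) for r in res_seqs))
    if not rs:
        return 0
    return 1 + sum(1 for a, b in zip(rs, rs[1:]) if b - a > segment_gap)


def _count_interactions(frame: np.ndarray, atoms: Sequence[AtomRecord],
                        chemistry: Mapping) -> dict[str, int]:
    """Count detector-positive protein-ligand atom pairs by kind.

    H bonds are enumerated from the chemistry table's donor/acceptor lists in
    both directions (requires protons in the structure); charged pairs from
    opposite formal-charge tags; hydrophobic from carbon-carbon proximity.
    """
    from .contacts import detect_hbond, ContactError

    prot = [i for i, a in enumerate(atoms) if not a.is_ligand]
    lig = [i for i, a in enumerate(atoms) if a.is_ligand]
    counts = {"hbond": 0, "charged": 0, "hydrophobic": 0}

    def donors_of(indices):
        out = []
        for i in indices:
            a = atoms[i]
            proton_name = chemistry["donors"].get(a.res_name, {}).get(a.atom_name)
            if proton_name is None:
                continue
            for j in indices:
                b = atoms[j]
                if (b.atom_name == proton_name and b.residue_key == a.residue_key):
                    out.append((i, j))
        return out

    def acceptors_of(indices):
        return [i for i in indices
                if atoms[i].atom_name in chemistry["acceptors"].get(atoms[i].res_name, ())]

    for donor_side, acceptor_side in ((prot, lig), (lig, prot)):
        for dh, h in donors_of(donor_side):
            for acc in acceptors_of(acceptor_side):
                try:
                    ok, _ = detect_hbond(frame, dh, h, acc)
                except ContactError:
                    continue
                if ok:
                    counts["hbond"] += 1

    for i in prot:
        for j in lig:
            gi, gj = atoms[i].formal_charge_group, atoms[j].formal_charge_group
            d = float(np.linalg.norm(frame[i] - frame[j]))
            if {gi, gj} == {"cationic", "anionic"} and d <= defaults.CHARGED_CUTOFF_A:
                counts["charged"] += 1
            elif (atoms[i].element.upper() == "C" and atoms[j].element.upper() == "C"
                  and d <= defaults.HYDROPHOBIC_CUTOFF_A):
                counts["hydrophobic"] += 1
    return counts


def triage_score(pose: PoseRecord, pose_set: PoseSet, protein: TrajectoryFrames,
                 weights: Mapping[str, float] | None = None,
                 segment_gap: int = defaults.TRIAGE_SEGMENT_GAP,
                 burial_radius_A: float = defaults.TRIAGE_BURIAL_RADIUS_A,
                 contact_cutoff_A: float = defaults.FINGERPRINT_CUTOFF_A,
                 chemistry: Mapping | None = None) -> TriageScore:
    """Score one pose against the manual prioritization criteria.

    Components: number of contact residues; interactions by kind; number of
    sequence segments among contact residues (difference > ``segment_gap``
    starts a new segment); triangulation (ligand heavy atoms contacted by >= 2
    distinct residues); burial index (mean number of protein heavy atoms
    within ``burial_radius_A`` of each ligand heavy atom -- a surrogate for
    "recessed from the surface", not a solvent-accessibility measure).  A
    dissociated pose scores zero on every component.
    """
    chemistry = chemistry if chemistry is not None else load_chemistry()
    frame, atoms = _pose_frame(protein, pose_set, pose)
    fp = residue_fingerprint(frame, atoms, heavy_cutoff_A=contact_cutoff_A)

    prot_heavy = [i for i, a in enumerate(atoms) if not a.is_ligand and not a.is_hydrogen]
    lig_heavy = [i for i, a in enumerate(atoms) if a.is_ligand and not a.is_hydrogen]

    if not fp:
        return TriageScore(0, {"hbond": 0, "charged": 0, "hydrophobic": 0}, 0, 0, 0.0, 0.0)

    n_inter = _count_interactions(frame, atoms, chemistry)
    n_seg = count_segments([r[1] for r in fp], segment_gap)

    dm = cdist(frame[lig_heavy], frame[prot_heavy])
    tri = 0
    for k in range(len(lig_heavy)):
        near = dm[k] <= contact_cutoff_A
        residues = {atoms[prot_heavy[m]].residue_key for m in np.nonzero(near)[0]}
        if len(residues) >= 2:
            tri += 1
    burial = float(np.mean(np.sum(dm <= burial_radius_A, axis=1)))

    comps = {
        "n_contact_residues": len(fp),
        "n_interactions": sum(n_inter.values()),
        "n_segments": n_seg,
        "triangulation_count": tri,
        "burial_index": burial,
    }
    w = dict.fromkeys(comps, 1.0)
    if weights:
        w.update(weights)
    composite = sum(w[k] * comps[k] / defaults.TRIAGE_NORMALIZERS[k] for k in comps)
    return TriageScore(n_contact_residues=len(fp), n_interactions=n_inter,
                       n_segments=n_seg, triangulation_count=tri,
                       burial_index=burial, composite=composite)
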