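"""Rigid-body superposition and geometric time series.

The trajectory analyses all reduce to a small geometric core: a weighted
Kabsch superposition used to remove the protein's global translation and
rotation before any deviation is measured, RMSD of a measured selection
against a reference frame (reported in nm), per-atom RMSF about the
time-averaged fitted position, inter-atomic distances (A), and signed IUPAC
dihedral angles (degrees) with the three-state rotamer classification used
for side-chain chi1 analysis.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structio import SelectionSpec, TrajectoryFrames, resolve_selection

A_PER_NM = 10.0


class GeometryError(ValueError):
    """Degenerate geometry or invalid geometric arguments."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` (rotation 3x3, translation in A)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise GeometryError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise GeometryError("rotation matrix not orthonormal")
        if np.linalg.det(R) < 0:
            raise GeometryError("improper rotation (reflection)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass
class SeriesResult:
    """A per-frame (or per-atom, for RMSF) series with tagged units."""

    times_ns: np.ndarray
    values: np.ndarray
    units: str
    labels: list | None = None

    def summary(self) -> dict:
        v = self.values[np.isfinite(self.values)]
        return {
            "units": self.units,
            "n": int(self.values.size),
            "mean": float(np.mean(v)) if v.size else float("nan"),
            "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
            "min": float(np.min(v)) if v.size else float("nan"),
            "max": float(np.max(v)) if v.size else float("nan"),
        }


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray,
               weights: np.ndarray | None = None) -> RigidTransform:
    """Least-squares proper rigid motion mapping ``mobile`` onto ``reference``.

    Classic SVD solution with the reflection branch corrected so the result is
    always a proper rotation (det = +1).  Requires at least three
    non-collinear fit points.
    """
    X = np.asarray(mobile, dtype=float)
    Y = np.asarray(reference, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise GeometryError(f"coordinate shapes differ or are not (n, 3): {X.shape} vs {Y.shape}")
    n = X.shape[0]
    if n < 3:
        raise GeometryError("superposition needs at least 3 atoms")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise GeometryError("weights must be non-negative with positive sum")
    w = w / w.sum()
    cx = w @ X
    cy = w @ Y
    X0 = X - cx
    Y0 = Y - cy
    # collinearity: centered mobile cloud must span at least a plane
    sv = np.linalg.svd(X0 * np.sqrt(w)[:, None], compute_uv=False)
    if sv[1] <= 1e-10 * max(sv[0], 1.0):
        raise GeometryError("degenerate (collinear) fit configuration")
    H = (X0 * w[:, None]).T @ Y0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    R = Vt.T @ D @ U.T
    t = cy - R @ cx
    return RigidTransform(R, t)


def _fit_frames(traj: TrajectoryFrames, fit_idx: np.ndarray,
                reference_frame: int) -> np.ndarray:
    """Superpose every frame's fit selection onto the reference frame.

    Returns the full coordinate array with each frame's transform applied.
    """
    if not 0 <= reference_frame < traj.n_frames:
        raise GeometryError(f"reference frame {reference_frame} out of range")
    ref = traj.coords[reference_frame][fit_idx]
    out = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        tr = kabsch_fit(traj.coords[f][fit_idx], ref)
        out[f] = tr.apply(traj.coords[f])
    return out


def default_fit_selection() -> SelectionSpec:
    """Protein backbone N, CA, C -- the default superposition selection."""
    return SelectionSpec.make(atom_name=("N", "CA", "C"), is_ligand=False)


def default_measure_selection() -> SelectionSpec:
    """Protein alpha carbons plus every ligand atom including hydrogens.

    Matches the reporting convention of combined protein-fold + ligand RMSD.
    Resolution is the union of the two parts, so this returns a list of specs.
    """
    return [SelectionSpec.make(atom_name="CA", is_ligand=False),
            SelectionSpec.make(is_ligand=True)]


def _resolve_union(traj: TrajectoryFrames, sel) -> np.ndarray:
    if isinstance(sel, SelectionSpec):
        return resolve_selection(traj, sel)
    idx = np.unique(np.concatenate([resolve_selection(traj, s) for s in sel]))
    return idx


def rmsd_series(traj: TrajectoryFrames,
                fit_sel: SelectionSpec | None = None,
                measure_sel=None,
                reference_frame: int = 0) -> SeriesResult:
    """RMSD (nm) of the measured selection vs. a reference frame.

    Each frame is first superposed onto the reference over ``fit_sel``
    (default: protein backbone N, CA, C), then the RMSD is taken over
    ``measure_sel`` (default: protein CA plus all ligand atoms, hydrogens
    included).  The value at the reference frame is exactly zero.
    """
    fit_sel = fit_sel if fit_sel is not None else default_fit_selection()
    measure_sel = measure_sel if measure_sel is not None else default_measure_selection()
    fit_idx = _resolve_union(traj, fit_sel)
    meas_idx = _resolve_union(traj, measure_sel)
    fitted = _fit_frames(traj, fit_idx, reference_frame)
    ref = fitted[reference_frame][meas_idx]
    diffs = fitted[:, meas_idx, :] - ref
    vals = np.sqrt(np.mean(np.sum(diffs**2, axis=2), axis=1)) / A_PER_NM
    vals[reference_frame] = 0.0
    return SeriesResult(times_ns=traj.times_ns.copy(), values=vals, units="nm")


def rmsf(traj: TrajectoryFrames,
         fit_sel: SelectionSpec | None = None,
         measure_sel=None,
         reference_frame: int = 0,
         per_residue: bool = False) -> SeriesResult:
    """Per-atom RMSF (nm) about the time-averaged fitted position.

    ``RMSF_i = sqrt(mean_t |r_i(t) - <r_i>|^2)`` after superposing every frame
    onto the reference over ``fit_sel``.  With ``per_residue`` the per-atom
    mean-square fluctuations are averaged within each residue before the root.
    """
    if traj.n_frames < 2:
        raise GeometryError("RMSF needs at least 2 frames")
    fit_sel = fit_sel if fit_sel is not None else default_fit_selection()
    measure_sel = measure_sel if measure_sel is not None else SelectionSpec.make(
        atom_name="CA", is_ligand=False)
    fit_idx = _resolve_union(traj, fit_sel)
    meas_idx = _resolve_union(traj, measure_sel)
    fitted = _fit_frames(traj, fit_idx, reference_frame)[:, meas_idx, :]
    mean_pos = fitted.mean(axis=0)
    msf = np.mean(np.sum((fitted - mean_pos) ** 2, axis=2), axis=0)
    atoms = [traj.atoms[i] for i in meas_idx]
    if per_residue:
        keys, values = [], []
        by_res: dict[tuple, list[float]] = {}
        for a, m in zip(atoms, msf):
            by_res.setdefault(a.residue_key, []).append(m)
        for k in sorted(by_res, key=lambda k: (k[0], k[1])):
            keys.append(k)
            values.append(np.sqrt(np.mean(by_res[k])))
        return SeriesResult(times_ns=np.array([]), values=np.array(values) / A_PER_NM,
                            units="nm", labels=keys)
    return SeriesResult(times_ns=np.array([]), values=np.sqrt(msf) / A_PER_NM,
                        units="nm", labels=[a.residue_key + (a.atom_name,) for a in atoms])


def _single_atom(traj: TrajectoryFrames, sel: SelectionSpec, what: str) -> int:
    idx = resolve_selection(traj, sel)
    if idx.size != 1:
        raise GeometryError(f"{what} must resolve to exactly 1 atom, got {idx.size}")
    return int(idx[0])


def distance_series(traj: TrajectoryFrames, atom_a: SelectionSpec,
                    atom_b: SelectionSpec) -> SeriesResult:
    """Euclidean distance (A) between two single-atom selections, per frame."""
    ia = _single_atom(traj, atom_a, "atom_a")
    ib = _single_atom(traj, atom_b, "atom_b")
    d = np.linalg.norm(traj.coords[:, ia, :] - traj.coords[:, ib, :], axis=1)
    return SeriesResult(times_ns=traj.times_ns.copy(), values=d, units="A")


def dihedral_from_coords(p: np.ndarray) -> np.ndarray:
    """Signed dihedral (degrees, (-180, 180]) for points of shape (..., 4, 3).

    Standard atan2 formulation; frames where either bond plane degenerates
    (three consecutive atoms collinear) yield NaN.
    """
    p = np.asarray(p, dtype=float)
    b0 = p[..., 1, :] - p[..., 0, :]
    b1 = p[..., 2, :] - p[..., 1, :]
    b2 = p[..., 3, :] - p[..., 2, :]
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1n = np.linalg.norm(b1, axis=-1)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b1, axis=-1) / np.where(b1n == 0, np.nan, b1n)
    deg = np.degrees(np.arctan2(y, x))
    bad = (np.linalg.norm(n1, axis=-1) < 1e-9) | (np.linalg.norm(n2, axis=-1) < 1e-9)
    deg = np.where(bad, np.nan, deg)
    # map -180 into the (-180, 180] convention
    return np.where(deg <= -180.0, deg + 360.0, deg)


def dihedral_series(traj: TrajectoryFrames, a1: SelectionSpec, a2: SelectionSpec,
                    a3: SelectionSpec, a4: SelectionSpec) -> SeriesResult:
    """Signed IUPAC dihedral (degrees) over four single-atom selections."""
    idx = [_single_atom(traj, s, f"a{k+1}") for k, s in enumerate((a1, a2, a3, a4))]
    if len(set(idx)) != 4:
        raise GeometryError("dihedral atoms must be distinct")
    pts = traj.coords[:, idx, :]
    return SeriesResult(times_ns=traj.times_ns.copy(),
                        values=dihedral_from_coords(pts), units="deg")


class RotamerState(str, enum.Enum):
    GAUCHE_PLUS = "gauche_plus"
    TRANS = "trans"
    GAUCHE_MINUS = "gauche_minus"


def classify_rotamer(angle_deg: float) -> RotamerState:
    """Three-state rotamer class of a chi-type dihedral.

    gauche+ on (0, 120], trans on (120, 180] and (-180, -120], gauche- on
    (-120, 0]; boundaries belong to the interval they close, so 120 is
    gauche+, 0 is gauche-, -120 is trans, and 180 or -170 are trans.
    """
    a = float(angle_deg)
    if not (-180.0 < a <= 180.0) or not np.isfinite(a):
        raise GeometryError(f"angle {a} outside (-180, 180]")
    if 0.0 < a <= 120.0:
        return RotamerState.GAUCHE_PLUS
    if a > 120.0 or a <= -120.0:
        return RotamerState.TRANS
    return RotamerState.GAUCHE_MINUS
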