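"""Independently coded reference implementations used only to check results.

Each oracle deliberately uses a different algorithm from the library code it
validates: superposition via Horn's closed-form quaternion method instead of
SVD, dihedrals via arccos of plane normals with an explicit sign instead of
the atan2 form, detectors as literal one-line translations of their stated
criteria, and brute-force loops instead of vectorized kernels.
"""
from __future__ import annotations

import numpy as np


def horn_quaternion_fit(mobile: np.ndarray, reference: np.ndarray):
    """Closed-form quaternion superposition (Horn 1987): returns (R, t)."""
    X = np.asarray(mobile, float)
    Y = np.asarray(reference, float)
    cx, cy = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - cx, Y - cy
    S = X0.T @ Y0
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    vals, vecs = np.linalg.eigh(K)
    w, x, y, z = vecs[:, np.argmax(vals)]
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = cy - R @ cx
    return R, t


def postfit_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """RMSD after quaternion superposition (A)."""
    R, t = horn_quaternion_fit(mobile, reference)
    moved = mobile @ R.T + t
    return float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))


def dihedral_acos(p: np.ndarray) -> float:
    """Signed dihedral (deg) via arccos of plane normals + explicit sign."""
    p = np.asarray(p, float)
    b1 = p[1] - p[0]
    b2 = p[2] - p[1]
    b3 = p[3] - p[2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    c = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def hbond_literal(distance_ha: float, angle_deg: float) -> bool:
    """Literal translation of the stated criterion: within 1.9 +/- 0.5 A and
    angle >= 120 deg."""
    return (1.9 - 0.5) <= distance_ha <= (1.9 + 0.5) and angle_deg >= 120.0


def brute_fingerprint(frame: np.ndarray, atoms, cutoff: float) -> frozenset:
    """All-pairs loop version of the residue fingerprint."""
    out = set()
    for i, a in enumerate(atoms):
        if a.is_ligand or a.is_hydrogen:
            continue
        for j, b in enumerate(atoms):
            if not b.is_ligand or b.is_hydrogen:
                continue
            if np.linalg.norm(frame[i] - frame[j]) <= cutoff:
                out.add((a.chain_id, a.res_seq, a.res_name))
                break
    return frozenset(out)


def brute_rmsd_series_nm(traj, fit_idx, meas_idx, ref_frame):
    """Per-frame quaternion fit + RMSD, for checking the library series."""
    vals = []
    ref_fit = traj.coords[ref_frame][fit_idx]
    ref_meas = None
    # fit the reference frame onto itself first, mirroring the library
    R0, t0 = horn_quaternion_fit(traj.coords[ref_frame][fit_idx], ref_fit)
    ref_meas = traj.coords[ref_frame][meas_idx] @ R0.T + t0
    for f in range(traj.n_frames):
        R, t = horn_quaternion_fit(traj.coords[f][fit_idx], ref_fit)
        moved = traj.coords[f][meas_idx] @ R.T + t
        vals.append(np.sqrt(np.mean(np.sum((moved - ref_meas) ** 2, axis=1))) / 10.0)
    return np.array(vals)
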