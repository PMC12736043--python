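"""Structure, trajectory and table I/O.

Trajectory snapshots and docked pose sets travel as multi-model PDB files; a
file is read into a :class:`TrajectoryFrames` -- a fixed atom table plus a
``(n_frames, n_atoms, 3)`` coordinate array in Angstrom and per-frame times in
nanoseconds.  PDB parsing and writing delegate to :mod:`gemmi`; this module
adds the invariants the analyses rely on (identical atom table in every
model, altloc filtering, ligand flagging, formal-charge tagging) and the
selection mini-language used by every geometric operation.

Tabular inputs and outputs (energy series, pose scores, timelines) are TSV
with a header row, handled by pandas behind :func:`read_table` /
:func:`write_table` with light schema checking.
"""
from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
import yaml

from . import defaults


class StructIOError(ValueError):
    """Raised for malformed structures, tables, or selections."""


class EmptySelectionError(StructIOError):
    """A selection resolved to no atoms where atoms were required."""


CHARGE_GROUPS = ("none", "cationic", "anionic")


@dataclass(frozen=True)
class AtomRecord:
    """One row of the fixed atom table shared by all frames."""

    serial: int
    atom_name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    is_ligand: bool = False
    formal_charge_group: str = "none"

    def __post_init__(self) -> None:
        if not self.element:
            raise StructIOError(f"atom {self.serial} {self.atom_name}: empty element")
        if self.formal_charge_group not in CHARGE_GROUPS:
            raise StructIOError(
                f"unknown charge group {self.formal_charge_group!r}"
            )

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.res_name)


class TrajectoryFrames:
    """Fixed atom table + per-frame coordinates (A) + frame times (ns).

    Parameters
    ----------
    atoms
        Ordered atom table; identical for every frame.
    coords
        Array of shape ``(n_frames, n_atoms, 3)`` in Angstrom.
    times_ns
        Strictly increasing frame times in nanoseconds.
    """

    def __init__(self, atoms: Sequence[AtomRecord], coords: np.ndarray,
                 times_ns: Sequence[float]):
        self.atoms = list(atoms)
        self.coords = np.asarray(coords, dtype=float)
        self.times_ns = np.asarray(times_ns, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructIOError(f"coords must be (n_frames, n_atoms, 3), got {self.coords.shape}")
        if self.coords.shape[1] != len(self.atoms):
            raise StructIOError(
                f"{len(self.atoms)} atoms but {self.coords.shape[1]} coordinate triples per frame"
            )
        if self.times_ns.shape != (self.coords.shape[0],):
            raise StructIOError("times_ns length must equal frame count")
        if len(self.times_ns) > 1 and not np.all(np.diff(self.times_ns) > 0):
            raise StructIOError("times_ns must be strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise StructIOError("non-finite coordinates")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise StructIOError("duplicate atom serials")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def heavy_mask(self) -> np.ndarray:
        return np.array([not a.is_hydrogen for a in self.atoms], dtype=bool)

    def ligand_mask(self) -> np.ndarray:
        return np.array([a.is_ligand for a in self.atoms], dtype=bool)


@dataclass(frozen=True)
class SelectionSpec:
    """Conjunctive atom selection over the fixed atom table.

    Every non-None field is a constraint; an atom is selected when it matches
    all of them.  ``res_seq`` accepts ints and ``(lo, hi)`` inclusive ranges.
    Resolution is deterministic: indices come back in atom-table order.
    """

    atom_name: frozenset[str] | None = None
    res_name: frozenset[str] | None = None
    res_seq: tuple = None
    chain_id: frozenset[str] | None = None
    is_ligand: bool | None = None
    allow_empty: bool = False

    _FIELDS = ("atom_name", "res_name", "res_seq", "chain_id", "is_ligand", "allow_empty")

    @classmethod
    def make(cls, atom_name=None, res_name=None, res_seq=None, chain_id=None,
             is_ligand=None, allow_empty=False) -> "SelectionSpec":
        def to_set(v):
            if v is None:
                return None
            if isinstance(v, str):
                return frozenset([v])
            return frozenset(v)
        if res_seq is not None:
            if isinstance(res_seq, int):
                res_seq = (res_seq,)
            else:
                res_seq = tuple(tuple(x) if isinstance(x, (list, tuple)) else int(x)
                                for x in res_seq)
        return cls(atom_name=to_set(atom_name), res_name=to_set(res_name),
                   res_seq=res_seq, chain_id=to_set(chain_id),
                   is_ligand=is_ligand, allow_empty=allow_empty)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SelectionSpec":
        unknown = set(d) - set(cls._FIELDS)
        if unknown:
            raise StructIOError(f"unknown selection field(s): {sorted(unknown)}")
        return cls.make(**dict(d))

    def _res_seq_match(self, rs: int) -> bool:
        for item in self.res_seq:
            if isinstance(item, tuple):
                lo, hi = item
                if lo <= rs <= hi:
                    return True
            elif rs == item:
                return True
        return False

    def matches(self, a: AtomRecord) -> bool:
        if self.atom_name is not None and a.atom_name not in self.atom_name:
            return False
        if self.res_name is not None and a.res_name not in self.res_name:
            return False
        if self.res_seq is not None and not self._res_seq_match(a.res_seq):
            return False
        if self.chain_id is not None and a.chain_id not in self.chain_id:
            return False
        if self.is_ligand is not None and a.is_ligand != self.is_ligand:
            return False
        return True


def resolve_selection(traj: TrajectoryFrames, sel: SelectionSpec) -> np.ndarray:
    """Resolve a selection to sorted atom indices (atom-table order).

    Raises :class:`EmptySelectionError` on an empty result unless the
    selection sets ``allow_empty``.
    """
    idx = np.array([i for i, a in enumerate(traj.atoms) if sel.matches(a)], dtype=int)
    if idx.size == 0 and not sel.allow_empty:
        raise EmptySelectionError(f"selection matched no atoms: {sel}")
    return idx


# ---------------------------------------------------------------------------
# chemistry table: donors/acceptors and formal charge groups per residue
# ---------------------------------------------------------------------------

def load_chemistry(path: str | Path | None = None) -> dict:
    """Load the donor/acceptor/charge-group table (editable YAML).

    Returns a dict with keys ``cationic``, ``anionic`` (each mapping res_name
    to a list of atom names), ``donors`` (res_name to {heavy: proton}) and
    ``acceptors`` (res_name to atom-name list).
    """
    if path is None:
        ref = importlib.resources.files("ligdyn").joinpath("data/chemistry.yaml")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    table = yaml.safe_load(text)
    for key in ("cationic", "anionic", "donors", "acceptors"):
        table.setdefault(key, {})
    return table


def charge_group_of(res_name: str, atom_name: str, chemistry: Mapping) -> str:
    if atom_name in chemistry["cationic"].get(res_name, ()):
        return "cationic"
    if atom_name in chemistry["anionic"].get(res_name, ()):
        return "anionic"
    return "none"


# ---------------------------------------------------------------------------
# multi-model PDB
# ---------------------------------------------------------------------------

def _is_ligand_residue(res_name: str, het: bool,
                       ligand_resnames: Iterable[str] | None) -> bool:
    if ligand_resnames is not None:
        return res_name in set(ligand_resnames)
    if not het:
        return False
    if res_name in defaults.WATER_RESNAMES or res_name in defaults.MONATOMIC_IONS:
        return False
    return True


def read_multimodel_pdb(path: str | Path,
                        ligand_resnames: Iterable[str] | None = None,
                        chemistry: Mapping | None = None,
                        dt_ns: float = 1.0,
                        times_ns: Sequence[float] | None = None) -> TrajectoryFrames:
    """Read a multi-model PDB into a :class:`TrajectoryFrames`.

    Models become frames.  The atom table must be identical across models by
    (atom name, res_seq, chain, res_name); otherwise an "inconsistent atom
    table" error is raised.  Alternate locations other than blank or "A" are
    dropped.  HETATM residues are flagged ``is_ligand`` unless they are water
    or a monatomic ion; pass ``ligand_resnames`` to whitelist explicitly.

    PDB carries no time axis: frame times default to ``dt_ns`` spacing
    starting at 0, or pass ``times_ns`` explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise StructIOError(f"no such file: {path}")
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise StructIOError(f"empty structure: {path}")

    chemistry = chemistry if chemistry is not None else load_chemistry()
    atoms: list[AtomRecord] = []
    keys: list[tuple] = []
    frames: list[np.ndarray] = []
    for mi, model in enumerate(st):
        xyz = []
        mkeys = []
        serial = 0
        for chain in model:
            for res in chain:
                het = res.het_flag == "H"
                lig = _is_ligand_residue(res.name, het, ligand_resnames)
                for at in res:
                    if at.altloc not in ("", "A", "\x00"):
                        continue
                    serial += 1
                    key = (at.name, res.seqid.num, chain.name, res.name)
                    mkeys.append(key)
                    xyz.append([at.pos.x, at.pos.y, at.pos.z])
                    if mi == 0:
                        atoms.append(AtomRecord(
                            serial=at.serial if at.serial else serial,
                            atom_name=at.name,
                            element=at.element.name or at.name[0],
                            res_name=res.name,
                            res_seq=res.seqid.num,
                            chain_id=chain.name,
                            is_ligand=lig,
                            formal_charge_group=charge_group_of(res.name, at.name, chemistry),
                        ))
        if mi == 0:
            keys = mkeys
            if not keys:
                raise StructIOError(f"no atoms in first model of {path}")
        elif mkeys != keys:
            raise StructIOError(
                f"inconsistent atom table: model {mi + 1} differs from model 1"
            )
        frames.append(np.array(xyz, dtype=float))

    # serials may collide across chains in pathological files; renumber then
    serials = [a.serial for a in atoms]
    if len(set(serials)) != len(serials):
        atoms = [dataclasses.replace(a, serial=i + 1) for i, a in enumerate(atoms)]

    coords = np.stack(frames)
    if times_ns is None:
        times_ns = np.arange(len(frames), dtype=float) * float(dt_ns)
    return TrajectoryFrames(atoms, coords, times_ns)


def write_multimodel_pdb(traj: TrajectoryFrames, path: str | Path) -> None:
    """Write a :class:`TrajectoryFrames` as a multi-model PDB (3-decimal coords).

    Atoms must be grouped contiguously by chain and residue (true of every
    structure this package reads or generates); otherwise re-reading would
    reorder the atom table.
    """
    # group atom indices: chain -> [(residue key, [atom indices])]
    chains: list[tuple[str, list[tuple[tuple, list[int]]]]] = []
    for ai, a in enumerate(traj.atoms):
        rkey = (a.res_seq, a.res_name, a.is_ligand)
        if not chains or chains[-1][0] != a.chain_id:
            chains.append((a.chain_id, [(rkey, [ai])]))
        elif chains[-1][1][-1][0] != rkey:
            chains[-1][1].append((rkey, [ai]))
        else:
            chains[-1][1][-1][1].append(ai)

    st = gemmi.Structure()
    st.name = "ligdyn"
    for fi in range(traj.n_frames):
        model = gemmi.Model(str(fi + 1))
        for chain_id, residues in chains:
            ch = gemmi.Chain(chain_id)
            for (res_seq, res_name, is_lig), idxs in residues:
                res = gemmi.Residue()
                res.name = res_name
                res.seqid = gemmi.SeqId(res_seq, " ")
                res.het_flag = "H" if is_lig else "A"
                for ai in idxs:
                    a = traj.atoms[ai]
                    at = gemmi.Atom()
                    at.name = a.atom_name
                    at.element = gemmi.Element(a.element)
                    at.serial = a.serial
                    x, y, z = traj.coords[fi, ai]
                    at.pos = gemmi.Position(float(x), float(y), float(z))
                    res.add_atom(at)
                ch.add_residue(res)
            model.add_chain(ch)
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_table(path: str | Path, schema: Mapping[str, type]) -> pd.DataFrame:
    """Read a header-bearing TSV, enforcing required columns and dtypes.

    ``schema`` maps required column names to types (float, int, str).  Extra
    columns are kept as-is; row order is preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = set(schema) - set(df.columns)
    if missing:
        raise StructIOError(f"{path}: missing required column(s) {sorted(missing)}")
    for col, typ in schema.items():
        if typ in (float, int):
            try:
                df[col] = df[col].astype(float if typ is float else int)
            except (ValueError, TypeError) as exc:
                raise StructIOError(f"{path}: non-numeric value in column {col!r}") from exc
        else:
            df[col] = df[col].astype(str)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as TSV, floats at full round-trip precision."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
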