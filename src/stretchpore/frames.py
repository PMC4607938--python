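"""Core containers: single bilayer configurations and ordered frame series.

Coordinates are right-handed Cartesian in nanometres with z the bilayer
normal; the box is orthorhombic with origin at (0, 0, 0) and positions are
stored wrapped into [0, l_i).  Residue types are ``DPPC``, ``CHOL`` and
``WATER``; the atom names the analysis relies on are the DPPC phosphorus
``P``, the sn-2 chain carbons ``C1``..``C14``, the cholesterol ring anchors
``C5``/``C21`` and the water oxygen ``OW``.
"""

from __future__ import annotations

import io
import json
import os
import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np

RESIDUE_TYPES = ("DPPC", "CHOL", "WATER")
#: residue names used on disk (GRO/PDB); WATER is written as SOL
GRO_RESNAMES = {"DPPC": "DPPC", "CHOL": "CHOL", "WATER": "SOL"}
RESNAME_TO_TYPE = {"DPPC": "DPPC", "CHOL": "CHOL", "SOL": "WATER", "WAT": "WATER",
                   "HOH": "WATER", "TIP3": "WATER", "SPC": "WATER", "WATER": "WATER"}

N_SN2_CARBONS = 14
SN2_NAMES = tuple(f"C{i}" for i in range(1, N_SN2_CARBONS + 1))


class FrameError(ValueError):
    """Raised for malformed or inconsistent frame data."""


@dataclass
class Frame:
    """One configuration of the bilayer system.

    Parameters
    ----------
    positions : (n, 3) float array, nm, wrapped into the box
    atom_names : (n,) str array
    residue_types : (n,) str array, entries from ``RESIDUE_TYPES``
    residue_indices : (n,) int array grouping atoms into molecules
    box : (3,) float array, box lengths (l_x, l_y, l_z) in nm
    time : float, ps
    """

    positions: np.ndarray
    atom_names: np.ndarray
    residue_types: np.ndarray
    residue_indices: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.residue_types = np.asarray(self.residue_types, dtype=object)
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.box = np.asarray(self.box, dtype=float)

    # -- basic queries -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def mask(self, residue_type: str | None = None, atom_name: str | None = None) -> np.ndarray:
        m = np.ones(self.n_atoms, dtype=bool)
        if residue_type is not None:
            m &= self.residue_types == residue_type
        if atom_name is not None:
            m &= self.atom_names == atom_name
        return m

    def residue_count(self, residue_type: str) -> int:
        m = self.mask(residue_type=residue_type)
        return len(np.unique(self.residue_indices[m]))

    def wrapped(self) -> "Frame":
        """Return a copy with positions wrapped into [0, l_i)."""
        pos = np.mod(self.positions, self.box[None, :])
        # guard against positions exactly equal to the box length after fp mod
        pos = np.where(pos >= self.box[None, :], 0.0, pos)
        return Frame(pos, self.atom_names.copy(), self.residue_types.copy(),
                     self.residue_indices.copy(), self.box.copy(), self.time)

    def copy(self) -> "Frame":
        return Frame(self.positions.copy(), self.atom_names.copy(),
                     self.residue_types.copy(), self.residue_indices.copy(),
                     self.box.copy(), self.time)

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        """Check the structural invariants; raise :class:`FrameError` if violated."""
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise FrameError("positions must be (n, 3)")
        n = self.n_atoms
        for name, arr in (("atom_names", self.atom_names),
                          ("residue_types", self.residue_types),
                          ("residue_indices", self.residue_indices)):
            if len(arr) != n:
                raise FrameError(f"{name} length {len(arr)} != n_atoms {n}")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise FrameError("box lengths must be three strictly positive values")
        unknown = set(np.unique(self.residue_types)) - set(RESIDUE_TYPES)
        if unknown:
            raise FrameError(f"unknown residue types: {sorted(unknown)}")
        wrapped = self.positions
        if np.any(wrapped < 0) or np.any(wrapped >= self.box[None, :]):
            raise FrameError("positions must be wrapped into [0, l_i)")
        self._check_naming()

    def _check_naming(self) -> None:
        for rtype, required in (("DPPC", ("P",) + SN2_NAMES),
                                ("CHOL", ("C5", "C21")),
                                ("WATER", ("OW",))):
            m = self.mask(residue_type=rtype)
            if not m.any():
                continue
            for ridx in np.unique(self.residue_indices[m]):
                names = self.atom_names[m & (self.residue_indices == ridx)]
                for req in required:
                    cnt = int(np.sum(names == req))
                    if cnt != 1:
                        raise FrameError(
                            f"{rtype} residue {ridx} has {cnt} atoms named '{req}' "
                            f"(expected exactly 1); the analysis requires the naming "
                            f"convention P/C1..C14 (DPPC), C5/C21 (CHOL), OW (WATER)")


@dataclass
class Trajectory:
    """Ordered frame series plus run metadata.

    ``meta`` keys used downstream: ``l_x0_nm`` (reference lateral box length),
    ``c_m_per_s`` (stretching speed), ``mode`` (US/QS), ``frame_interval_ps``,
    ``seed`` and ``composition`` (label).
    """

    frames: list[Frame]
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def l_x0(self) -> float:
        try:
            return float(self.meta["l_x0_nm"])
        except KeyError as exc:
            raise FrameError("trajectory metadata lacks 'l_x0_nm'") from exc

    def strains(self) -> np.ndarray:
        """Areal strain per frame, (l_x / l_x0)^2 - 1."""
        lx0 = self.l_x0
        return np.array([(f.box[0] / lx0) ** 2 - 1.0 for f in self.frames])

    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


# ---------------------------------------------------------------------------
# GRO / PDB reading and writing (MDAnalysis-backed)
# ---------------------------------------------------------------------------

def _mda_universe(frame: Frame):
    """Build an in-memory MDAnalysis Universe mirroring ``frame`` (Å units)."""
    import MDAnalysis as mda

    ridx = frame.residue_indices
    uniq, inverse = np.unique(ridx, return_index=False, return_inverse=True)
    n_res = len(uniq)
    u = mda.Universe.empty(frame.n_atoms, n_residues=n_res,
                           atom_resindex=inverse,
                           residue_segindex=np.zeros(n_res, dtype=int),
                           trajectory=True)
    u.add_TopologyAttr("names", [str(x) for x in frame.atom_names])
    res_types = []
    for r in uniq:
        rt = frame.residue_types[np.argmax(ridx == r)]
        res_types.append(GRO_RESNAMES[rt])
    u.add_TopologyAttr("resnames", res_types)
    u.add_TopologyAttr("resids", (np.arange(n_res) % 99999) + 1)
    u.atoms.positions = frame.positions * 10.0  # nm -> Å
    u.dimensions = [frame.box[0] * 10, frame.box[1] * 10, frame.box[2] * 10, 90, 90, 90]
    u.trajectory.ts.time = frame.time
    return u


def _frame_from_atomgroup(atoms, box_A, time_ps: float) -> Frame:
    names = np.array([str(n) for n in atoms.names], dtype=object)
    rtypes = []
    for rn in atoms.resnames:
        if rn not in RESNAME_TO_TYPE:
            raise FrameError(f"unknown residue name {rn!r} (expected DPPC/CHOL/SOL)")
        rtypes.append(RESNAME_TO_TYPE[rn])
    fr = Frame(atoms.positions / 10.0,
               names,
               np.array(rtypes, dtype=object),
               np.asarray(atoms.resindices, dtype=int),
               np.asarray(box_A[:3], dtype=float) / 10.0,
               time=float(time_ps))
    fr = fr.wrapped()
    fr.validate()
    return fr


@contextmanager
def _quiet_mda():
    """Silence MDAnalysis chatter about optional PDB attributes."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="MDAnalysis")
        warnings.filterwarnings("ignore", message=".*Reader has no dt.*")
        yield


def write_frames(traj: Trajectory, path: str, fmt: str | None = None) -> None:
    """Write a trajectory as multi-frame GRO (concatenated blocks) or PDB.

    A JSON metadata sidecar ``<path>.meta.json`` carries the trajectory
    metadata (stretching speed, reference box length, seed, ...).
    """
    import MDAnalysis as mda

    fmt = _infer_format(path, fmt)
    if not traj.frames:
        raise FrameError("cannot write an empty trajectory")
    if fmt == "GRO":
        chunks = []
        for fr in traj.frames:
            u = _mda_universe(fr)
            buf = mda.lib.util.NamedStream(io.StringIO(), "frame.gro")
            with _quiet_mda(), mda.coordinates.GRO.GROWriter(buf, n_atoms=fr.n_atoms) as w:
                w.write(u.atoms)
            body = buf.getvalue().split("\n", 1)[1]
            chunks.append(f"stretchpore frame t= {fr.time:.4f} ps\n" + body)
        with open(path, "w") as fh:
            fh.write("".join(chunks))
    elif fmt == "PDB":
        with _quiet_mda(), mda.coordinates.PDB.PDBWriter(path, multiframe=True) as w:
            for fr in traj.frames:
                w.write(_mda_universe(fr).atoms)
    else:  # pragma: no cover
        raise FrameError(f"unsupported format {fmt!r}")
    sidecar = dict(traj.meta)
    sidecar["_times_ps"] = [float(fr.time) for fr in traj.frames]
    with open(path + ".meta.json", "w") as fh:
        json.dump(sidecar, fh, indent=1, default=float)


def read_frames(path: str, fmt: str | None = None) -> Trajectory:
    """Read a single- or multi-frame GRO/PDB file written by :func:`write_frames`.

    Positions round-trip to the file precision (GRO: 0.001 nm, PDB: 0.0001 nm).
    """
    import MDAnalysis as mda

    fmt = _infer_format(path, fmt)
    frames: list[Frame] = []
    if fmt == "GRO":
        with open(path) as fh:
            text = fh.read()
        for k, block in enumerate(_split_gro_blocks(text)):
            stream = mda.lib.util.NamedStream(io.StringIO(block), f"frame{k}.gro")
            with _quiet_mda():
                u = mda.Universe(stream, format="GRO")
            t = _gro_block_time(block)
            frames.append(_frame_from_atomgroup(u.atoms, u.dimensions, t))
    elif fmt == "PDB":
        cryst = _pdb_cryst1(path)
        with _quiet_mda():
            u = mda.Universe(path, format="PDB")
            for ts in u.trajectory:
                box = ts.dimensions if ts.dimensions is not None else cryst
                if box is None:
                    raise FrameError("PDB file lacks a CRYST1 box record")
                frames.append(_frame_from_atomgroup(u.atoms, box, ts.time))
    else:  # pragma: no cover
        raise FrameError(f"unsupported format {fmt!r}")
    if not frames:
        raise FrameError(f"no frames parsed from {path}")
    meta = {}
    if os.path.exists(path + ".meta.json"):
        with open(path + ".meta.json") as fh:
            meta = json.load(fh)
    times = meta.pop("_times_ps", None)
    if times is not None and len(times) == len(frames):
        for fr, t in zip(frames, times):
            fr.time = float(t)
    return Trajectory(frames, meta)


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.upper()
    ext = os.path.splitext(path)[1].lower()
    if ext == ".gro":
        return "GRO"
    if ext == ".pdb":
        return "PDB"
    raise FrameError(f"cannot infer format from {path!r}; pass fmt='GRO' or 'PDB'")


def _split_gro_blocks(text: str) -> list[str]:
    """Split concatenated GRO frames (title, natoms, atoms..., box) into blocks."""
    lines = text.splitlines()
    blocks, i = [], 0
    while i < len(lines):
        if not lines[i].strip() and i == len(lines) - 1:
            break
        if i + 1 >= len(lines):
            raise FrameError("truncated GRO file: missing atom-count line")
        try:
            natoms = int(lines[i + 1].strip())
        except ValueError as exc:
            raise FrameError(f"bad GRO atom-count line: {lines[i + 1]!r}") from exc
        end = i + 2 + natoms + 1
        if end > len(lines):
            raise FrameError("truncated GRO file: fewer atom lines than declared")
        blocks.append("\n".join(lines[i:end]) + "\n")
        i = end
    if not blocks:
        raise FrameError("empty GRO file")
    return blocks


def _pdb_cryst1(path: str):
    """First CRYST1 cell (a, b, c in Å) of a PDB file, or None."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                return np.array([float(line[6:15]), float(line[15:24]),
                                 float(line[24:33])])
    return None


def _gro_block_time(block: str) -> float:
    title = block.splitlines()[0]
    if "t=" in title:
        try:
            return float(title.split("t=")[1].split()[0])
        except (ValueError, IndexError):
            return 0.0
    return 0.0
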