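"""Trans-bilayer water-chain and pore detection; critical areal strain.

The first step of rupture is a chain of water molecules penetrating the
bilayer.  Waters are connected when their oxygen-oxygen minimum-image
distance is within a cutoff (default 0.35 nm, the first hydration shell);
a connected component "spans" when it reaches both bulk sides of the
membrane.  The areal strain of the first spanning frame is the critical
areal strain eps_c.  Spanning components restricted to the hydrophobic core
are clustered in-plane to count simultaneous pores (single vs multi-pore).

Periodicity: the water graph itself is periodic in x, y and z.  Spanning
detection, however, recentres the bilayer midplane to l_z/2 and drops the
z-periodic images — under z-periodicity the two bulk slabs of any solvated
bilayer are one component through the box boundary, which would make every
intact frame "spanning".
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .frames import Frame, FrameError, Trajectory
from .observables import _p_planes

DEFAULT_CUTOFF = 0.35  # nm, O-O connectivity (first hydration shell)
DEFAULT_MARGIN = 0.3   # nm, inset of the P planes toward the midplane
DEFAULT_WINDOW = 5     # frames inspected after first detection
MIN_CLUSTER_WATERS = 3  # core clusters below this are noise

#: head-group atom set for the lining-hydrophilicity measure
HYDROPHILIC_ATOMS = {("DPPC", "P"), ("CHOL", "C5")}


class PoreError(ValueError):
    pass


def _component_labels(points: np.ndarray, cutoff: float,
                      boxsize) -> np.ndarray:
    """Connected-component labels of the distance-cutoff graph (cKDTree)."""
    n = len(points)
    tree = cKDTree(points, boxsize=boxsize)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    data = np.ones(len(pairs))
    adj = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    return labels


def water_graph(frame: Frame, cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Component label per water oxygen under full xyz periodic boundaries.

    Returns an array aligned with the frame's OW atoms (see
    :func:`water_indices`).
    """
    if cutoff <= 0:
        raise PoreError("cutoff must be > 0")
    idx = water_indices(frame)
    if len(idx) == 0:
        raise PoreError("frame has no water oxygens")
    pos = np.mod(frame.positions[idx], frame.box[None, :])
    pos = np.where(pos >= frame.box[None, :], 0.0, pos)
    return _component_labels(pos, cutoff, boxsize=frame.box)


def water_indices(frame: Frame) -> np.ndarray:
    """Atom indices of the water oxygens, in frame order."""
    return np.nonzero(frame.mask(residue_type="WATER", atom_name="OW"))[0]


def _recentred_water_z(frame: Frame) -> tuple[np.ndarray, float, float, float]:
    """Water xyz with the P midplane shifted to l_z/2, plus plane positions."""
    z_up, z_lo = _p_planes(frame)
    mid = 0.5 * (z_up + z_lo)
    shift = frame.box[2] / 2.0 - mid
    idx = water_indices(frame)
    if len(idx) == 0:
        raise PoreError("frame has no water oxygens")
    pos = frame.positions[idx].copy()
    pos[:, 2] = np.mod(pos[:, 2] + shift, frame.box[2])
    pos[:, :2] = np.mod(pos[:, :2], frame.box[None, :2])
    pos = np.where(pos >= frame.box[None, :], 0.0, pos)
    return pos, z_up + shift, z_lo + shift, frame.box[2] / 2.0


def detect_spanning(frame: Frame, cutoff: float = DEFAULT_CUTOFF,
                    margin: float = DEFAULT_MARGIN):
    """Does any water component cross the bilayer core?

    A component spans when it contains waters above the upper and below the
    lower phosphorus plane, the planes inset by ``margin`` toward the
    midplane.  Returns ``(spanning, spanning_labels, labels)`` with labels
    aligned to :func:`water_indices` (xy-periodic connectivity, see module
    docstring).
    """
    pos, z_up, z_lo, _ = _recentred_water_z(frame)
    labels = _component_labels(pos, cutoff,
                               boxsize=[frame.box[0], frame.box[1], 0.0])
    hi = pos[:, 2] > z_up - margin
    lo = pos[:, 2] < z_lo + margin
    span_labels = sorted(set(labels[hi]) & set(labels[lo]))
    return len(span_labels) > 0, span_labels, labels


def count_pores(frame: Frame, cutoff: float = DEFAULT_CUTOFF,
                margin: float = DEFAULT_MARGIN,
                min_cluster: int = MIN_CLUSTER_WATERS):
    """Number of simultaneous pores and their in-plane centres.

    Waters of spanning components restricted to the core slab
    (|z - midplane| < l_t/2 - margin) are re-clustered with the same cutoff
    (xy periodic); clusters with fewer than ``min_cluster`` waters are
    ignored as noise.  Centres are circular means in x and y.
    """
    spanning, span_labels, labels = detect_spanning(frame, cutoff, margin)
    if not spanning:
        return 0, np.empty((0, 2))
    pos, z_up, z_lo, z_mid = _recentred_water_z(frame)
    half_core = (z_up - z_lo) / 2.0 - margin
    in_span = np.isin(labels, span_labels)
    core = in_span & (np.abs(pos[:, 2] - z_mid) < half_core)
    if not core.any():
        return 0, np.empty((0, 2))
    core_pos = pos[core]
    core_labels = _component_labels(core_pos, cutoff,
                                    boxsize=[frame.box[0], frame.box[1], 0.0])
    centers = []
    n_pores = 0
    for lab in np.unique(core_labels):
        members = core_pos[core_labels == lab]
        if len(members) < min_cluster:
            continue
        n_pores += 1
        centers.append([_circular_mean(members[:, 0], frame.box[0]),
                        _circular_mean(members[:, 1], frame.box[1])])
    return n_pores, np.asarray(centers).reshape(-1, 2)


def _circular_mean(x: np.ndarray, period: float) -> float:
    ang = x * (2.0 * np.pi / period)
    mean_ang = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    return float(np.mod(mean_ang, 2.0 * np.pi) * period / (2.0 * np.pi))


@dataclass
class PoreReport:
    """Outcome of scanning one trajectory for pore formation."""

    first_spanning_frame: int | None
    epsilon_c: float | None
    pores_per_frame: list[int]
    classification: str  # none | single | multi
    lining_hydrophilic_fraction: float | None = None
    cutoff: float = DEFAULT_CUTOFF
    margin: float = DEFAULT_MARGIN

    def __post_init__(self) -> None:
        if (self.epsilon_c is None) != (self.first_spanning_frame is None):
            raise PoreError("epsilon_c and first_spanning_frame must be set together")

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "first_spanning_frame": self.first_spanning_frame,
            "epsilon_c": self.epsilon_c,
            "pores_per_frame": list(map(int, self.pores_per_frame)),
            "classification": self.classification,
            "lining_hydrophilic_fraction": self.lining_hydrophilic_fraction,
            "cutoff": self.cutoff,
            "margin": self.margin,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def critical_strain(traj: Trajectory, cutoff: float = DEFAULT_CUTOFF,
                    margin: float = DEFAULT_MARGIN,
                    window: int = DEFAULT_WINDOW) -> PoreReport:
    """Scan frames in time order for the first trans-bilayer water chain.

    eps_c is the areal strain of the first spanning frame; the single/multi
    classification uses the maximum simultaneous pore count over the
    ``window`` frames following (and including) first detection — multi-pore
    events are transient, so a single frame would under-count them.
    """
    if len(traj) == 0:
        raise PoreError("empty trajectory")
    strains = traj.strains()
    first = None
    counts: list[int] = []
    for i, fr in enumerate(traj):
        spanning, _, _ = detect_spanning(fr, cutoff, margin)
        if spanning:
            first = i
            break
        counts.append(0)
    if first is None:
        return PoreReport(None, None, counts, "none", None, cutoff, margin)
    max_pores = 0
    for j in range(first, min(first + window, len(traj))):
        n, _ = count_pores(traj[j], cutoff, margin)
        counts.append(n)
        max_pores = max(max_pores, n)
    classification = "multi" if max_pores >= 2 else "single"
    return PoreReport(first, float(strains[first]), counts, classification,
                      None, cutoff, margin)


def multipore_rate(flags: list[str]) -> float:
    """Fraction of 'multi' outcomes among replicate classifications."""
    if not flags:
        raise PoreError("no outcomes")
    bad = set(flags) - {"single", "multi"}
    if bad:
        raise PoreError(f"unknown classifications: {sorted(bad)}")
    return sum(f == "multi" for f in flags) / len(flags)


@dataclass
class QsBracket:
    """Bracket of the quasistatic critical strain.

    The QS strains are discretized, so eps_c is bracketed by the largest
    pore-free strain and the smallest pore-bearing strain.
    """

    max_strain_no_pore: float | None
    min_strain_with_pore: float | None


def qs_bracket(observations: list[tuple[float, bool]]) -> QsBracket:
    """Bracket eps_c from (strain, pore-formed?) quasistatic outcomes."""
    if not observations:
        raise PoreError("no QS observations")
    no_pore = [s for s, p in observations if not p]
    pore = [s for s, p in observations if p]
    lo = max(no_pore) if no_pore else None
    hi = min(pore) if pore else None
    if lo is not None and hi is not None and hi <= lo:
        warnings.warn(
            f"inconsistent QS outcomes: pore at strain {hi:g} but none at {lo:g}; "
            "reporting the extrema anyway", stacklevel=2)
    return QsBracket(lo, hi)


def pore_lining(frame: Frame, cutoff: float = DEFAULT_CUTOFF,
                margin: float = DEFAULT_MARGIN, shell: float = 0.5,
                hydrophilic=HYDROPHILIC_ATOMS) -> float | None:
    """Hydrophilic fraction of the atoms lining the pore walls.

    Among non-water atoms within ``shell`` nm of any core-slab water of a
    spanning component, the fraction belonging to the head-group set
    (default: DPPC P and the hydroxyl-bearing cholesterol C5).  Returns None
    when the frame has no spanning component or the shell is empty.
    """
    if shell <= 0:
        raise PoreError("shell must be > 0")
    spanning, span_labels, labels = detect_spanning(frame, cutoff, margin)
    if not spanning:
        return None
    pos, z_up, z_lo, z_mid = _recentred_water_z(frame)
    half_core = (z_up - z_lo) / 2.0 - margin
    core = np.isin(labels, span_labels) & (np.abs(pos[:, 2] - z_mid) < half_core)
    if not core.any():
        return None
    # recentre the non-water atoms identically
    shift = z_mid - 0.5 * sum(_p_planes(frame))
    non_water = frame.residue_types != "WATER"
    other = frame.positions[non_water].copy()
    other[:, 2] = np.mod(other[:, 2] + shift, frame.box[2])
    other[:, :2] = np.mod(other[:, :2], frame.box[None, :2])
    other = np.where(other >= frame.box[None, :], 0.0, other)
    tree = cKDTree(other, boxsize=[frame.box[0], frame.box[1], 0.0])
    near = set()
    for hits in tree.query_ball_point(pos[core], shell):
        near.update(hits)
    if not near:
        return None
    near = np.fromiter(near, dtype=int)
    names = frame.atom_names[non_water][near]
    rtypes = frame.residue_types[non_water][near]
    is_head = np.array([(rt, nm) in hydrophilic for rt, nm in zip(rtypes, names)])
    return float(is_head.mean())
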