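"""Per-frame structural observables of the stretched bilayer.

Implements the quantities the analysis tracks against areal strain: bilayer
thickness l_t (distance between the mean phosphorus planes of the two
leaflets), the averaged instantaneous sn-2 chain order parameter
S = (1/N_c) * sum_i (3 cos^2 Theta_i - 1)/2 with N_c = 14, the cholesterol
tilt angle theta_c (C5->C21 ring axis vs the bilayer normal, folded to
[0, 90] degrees), the tail overlap length (leaflet interdigitation), and the
interdigitated-gel transition index R_Li.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .frames import Frame, FrameError, N_SN2_CARBONS, SN2_NAMES, Trajectory


def areal_strain(l_x: float, l_x0: float) -> float:
    """Areal strain eps_A = (l_x / l_x0)^2 - 1 of the equibiaxially stretched box."""
    if l_x <= 0 or l_x0 <= 0:
        raise FrameError("box lengths must be > 0")
    return (l_x / l_x0) ** 2 - 1.0


def assign_leaflets(frame: Frame) -> dict[int, str]:
    """Label each lipid residue 'upper' or 'lower' by its anchor z vs the midplane.

    The midplane is the mean z of all DPPC phosphorus atoms; the anchor is P
    for DPPC and C5 for cholesterol.  Invariant under rigid translation.
    """
    p_mask = frame.mask(residue_type="DPPC", atom_name="P")
    if not p_mask.any():
        raise FrameError("no DPPC phosphorus atoms: cannot define the midplane")
    mid = frame.positions[p_mask, 2].mean()
    labels: dict[int, str] = {}
    for rtype, anchor in (("DPPC", "P"), ("CHOL", "C5")):
        m = frame.mask(residue_type=rtype, atom_name=anchor)
        for ridx, z in zip(frame.residue_indices[m], frame.positions[m, 2]):
            labels[int(ridx)] = "upper" if z > mid else "lower"
    return labels


def _p_planes(frame: Frame) -> tuple[float, float]:
    """(upper, lower) mean phosphorus-plane z; raises if a leaflet is empty."""
    p_mask = frame.mask(residue_type="DPPC", atom_name="P")
    if not p_mask.any():
        raise FrameError("no DPPC phosphorus atoms")
    z = frame.positions[p_mask, 2]
    mid = z.mean()
    upper, lower = z[z > mid], z[z <= mid]
    if len(upper) == 0 or len(lower) == 0:
        raise FrameError("a leaflet has no DPPC: thickness undefined")
    return float(upper.mean()), float(lower.mean())


def bilayer_thickness(frame: Frame) -> float:
    """l_t: distance between the upper and lower mean phosphorus planes, nm."""
    z_up, z_lo = _p_planes(frame)
    return z_up - z_lo


@dataclass
class OrderResult:
    """Chain order parameter with per-molecule detail."""

    s_tail: float
    per_molecule: np.ndarray
    theta_deg: np.ndarray  # per-segment angles, all molecules flattened
    n_carbons: int = N_SN2_CARBONS

    @property
    def s_sd(self) -> float:
        """Molecule-level standard deviation (NaN for a single molecule)."""
        if len(self.per_molecule) < 2:
            return float("nan")
        return float(np.std(self.per_molecule, ddof=1))


def chain_order_parameter(frame: Frame) -> OrderResult:
    """Averaged instantaneous order parameter over the DPPC sn-2 chains.

    The molecular axis at carbon i is the vector from carbon i-1 to i+1
    (chain ends use their single neighbour); Theta_i is its angle to z.
    """
    m = frame.mask(residue_type="DPPC")
    if not m.any():
        raise FrameError("no DPPC residues")
    per_mol, thetas = [], []
    missing = []
    for ridx in np.unique(frame.residue_indices[m]):
        rm = m & (frame.residue_indices == ridx)
        names = frame.atom_names[rm]
        pos = frame.positions[rm]
        try:
            chain = np.array([pos[np.nonzero(names == nm)[0][0]] for nm in SN2_NAMES])
        except IndexError:
            missing.append(int(ridx))
            continue
        axes = np.empty_like(chain)
        axes[0] = chain[1] - chain[0]
        axes[-1] = chain[-1] - chain[-2]
        axes[1:-1] = chain[2:] - chain[:-2]
        norm = np.linalg.norm(axes, axis=1)
        cos2 = (axes[:, 2] / norm) ** 2
        s_mol = np.mean((3.0 * cos2 - 1.0) / 2.0)
        per_mol.append(s_mol)
        thetas.append(np.degrees(np.arccos(np.clip(np.abs(axes[:, 2]) / norm, 0, 1))))
    if missing:
        raise FrameError(f"DPPC residues missing sn-2 carbons: {missing}")
    return OrderResult(float(np.mean(per_mol)), np.asarray(per_mol),
                       np.concatenate(thetas))


def cholesterol_tilt(frame: Frame) -> tuple[float, float, np.ndarray]:
    """Cholesterol tilt: (mean, SD, per-molecule) angles in degrees.

    theta_c = arccos(|v_z| / |v|) with v = r(C21) - r(C5), folded to
    [0, 90] degrees so leaflet orientation does not flip the angle.
    """
    m = frame.mask(residue_type="CHOL")
    if not m.any():
        raise FrameError("no cholesterol residues")
    angles = []
    for ridx in np.unique(frame.residue_indices[m]):
        rm = m & (frame.residue_indices == ridx)
        names = frame.atom_names[rm]
        pos = frame.positions[rm]
        v = pos[names == "C21"][0] - pos[names == "C5"][0]
        nv = np.linalg.norm(v)
        if nv == 0:
            raise FrameError(f"CHOL residue {ridx}: C5 and C21 coincide")
        angles.append(np.degrees(np.arccos(np.clip(abs(v[2]) / nv, 0, 1))))
    angles = np.asarray(angles)
    sd = float(np.std(angles, ddof=1)) if len(angles) > 1 else float("nan")
    return float(angles.mean()), sd, angles


def tail_overlap_length(frame: Frame) -> float:
    """Interdigitation measure: crossing distance of the mean terminal planes.

    L_ov = max(0, <z of lower-leaflet C14> - <z of upper-leaflet C14>);
    positive iff the terminal sn-2 carbons of the two leaflets have crossed.
    """
    labels = assign_leaflets(frame)
    m = frame.mask(residue_type="DPPC", atom_name=f"C{N_SN2_CARBONS}")
    if not m.any():
        raise FrameError("no terminal sn-2 carbons")
    z = frame.positions[m, 2]
    ridx = frame.residue_indices[m]
    up = np.array([labels[int(r)] == "upper" for r in ridx])
    if not up.any() or up.all():
        raise FrameError("a leaflet has no DPPC: overlap undefined")
    return float(max(0.0, z[~up].mean() - z[up].mean()))


# ---------------------------------------------------------------------------
# trajectory-level series
# ---------------------------------------------------------------------------

@dataclass
class ObservableSeries:
    """Tidy per-frame observables plus metadata (one row per frame).

    Columns: time_ps, areal_strain, thickness_nm, s_tail, s_tail_sd,
    chol_tilt_deg, chol_tilt_sd_deg, overlap_nm (tilt columns are NaN for a
    cholesterol-free system).
    """

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    def __getattr__(self, name):
        tab = object.__getattribute__(self, "table")
        if name in tab.columns:
            return tab[name].to_numpy()
        raise AttributeError(name)

    def to_csv(self, path: str) -> None:
        """Write the table as CSV with a JSON metadata sidecar."""
        self.table.to_csv(path, index=False)
        with open(path + ".meta.json", "w") as fh:
            json.dump(self.meta, fh, indent=1, default=float)

    @classmethod
    def from_csv(cls, path: str) -> "ObservableSeries":
        import os
        meta = {}
        if os.path.exists(path + ".meta.json"):
            with open(path + ".meta.json") as fh:
                meta = json.load(fh)
        return cls(pd.read_csv(path), meta)

    def time_averages(self) -> pd.Series:
        """Mean of each column over frames (used for QS runs)."""
        return self.table.drop(columns=["time_ps"]).mean()


def compute_series(traj: Trajectory) -> ObservableSeries:
    """All observables per frame; requires ``l_x0_nm`` in the metadata."""
    if len(traj) == 0:
        raise FrameError("empty trajectory")
    lx0 = traj.l_x0
    rows = []
    for i, fr in enumerate(traj):
        try:
            has_chol = bool(fr.mask(residue_type="CHOL").any())
            order = chain_order_parameter(fr)
            if has_chol:
                tilt_mean, tilt_sd, _ = cholesterol_tilt(fr)
            else:
                tilt_mean, tilt_sd = float("nan"), float("nan")
            rows.append({
                "time_ps": fr.time,
                "areal_strain": areal_strain(fr.box[0], lx0),
                "thickness_nm": bilayer_thickness(fr),
                "s_tail": order.s_tail,
                "s_tail_sd": order.s_sd,
                "chol_tilt_deg": tilt_mean,
                "chol_tilt_sd_deg": tilt_sd,
                "overlap_nm": tail_overlap_length(fr),
            })
        except FrameError as exc:
            raise FrameError(f"frame {i}: {exc}") from exc
    meta = dict(traj.meta)
    meta.setdefault("l_x0_nm", lx0)
    return ObservableSeries(pd.DataFrame(rows), meta)


def match_thickness(series: ObservableSeries, target_l_t: float) -> int:
    """Frame index minimizing |l_t - target|; ties resolve to the earlier frame."""
    if len(series) == 0:
        raise FrameError("empty series")
    lt = series.table["thickness_nm"].to_numpy()
    return int(np.argmin(np.abs(lt - target_l_t)))  # argmin takes the first minimum


@dataclass
class RLiResult:
    """Interdigitated-gel transition index and its ingredients."""

    r_li: float
    s_ref_dc: float
    s_ref_pd: float
    matched_frame: int | None = None
    target_thickness: float | None = None


def r_li(s_at_matched: float, s_ref_dc: float, s_ref_pd: float,
         matched_frame: int | None = None,
         target_thickness: float | None = None) -> RLiResult:
    """R_Li = (S - S_ref_PD) / (S_ref_DC - S_ref_PD), reported unclipped.

    ~1 for an interdigitated gel-like structure, ~0 for a bilayer that does
    not form one (the pure-DPPC reference).  Undefined for equal references.
    """
    if s_ref_dc == s_ref_pd:
        raise FrameError("R_Li undefined: reference order parameters are equal")
    val = (s_at_matched - s_ref_pd) / (s_ref_dc - s_ref_pd)
    return RLiResult(float(val), s_ref_dc, s_ref_pd, matched_frame, target_thickness)


def _s_at_thickness(series: ObservableSeries, target_lt: float,
                    tol: float) -> tuple[float, int]:
    """Mean S over frames whose thickness is within ``tol`` of the target.

    Falls back to the single closest frame when none are within tolerance;
    averaging over the matched window suppresses molecule-sampling noise in
    finite systems.
    """
    lt = series.table["thickness_nm"].to_numpy()
    s = series.table["s_tail"].to_numpy()
    close = np.abs(lt - target_lt) <= tol
    i_best = match_thickness(series, target_lt)
    if not close.any():
        return float(s[i_best]), i_best
    return float(s[close].mean()), i_best


def transition_index(series: ObservableSeries, chol_ref: ObservableSeries,
                     pure_ref: ObservableSeries, eps_ref: float = 1.0,
                     tol_nm: float = 0.08) -> RLiResult:
    """R_Li of ``series`` against the two reference runs at matched thickness.

    The target thickness is that of the cholesterol reference at areal strain
    ``eps_ref`` (default 1.0, where the interdigitated-gel transition of the
    40 mol% system completes); S is averaged over each run's frames whose
    thickness lies within ``tol_nm`` of that target.
    """
    eps = chol_ref.table["areal_strain"].to_numpy()
    ref_frame = int(np.argmin(np.abs(eps - eps_ref)))
    target_lt = float(chol_ref.table["thickness_nm"].iloc[ref_frame])
    s_ref_dc, _ = _s_at_thickness(chol_ref, target_lt, tol_nm)
    s_ref_pd, _ = _s_at_thickness(pure_ref, target_lt, tol_nm)
    s_self, i_self = _s_at_thickness(series, target_lt, tol_nm)
    return r_li(s_self, s_ref_dc, s_ref_pd, matched_frame=i_self,
                target_thickness=target_lt)
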