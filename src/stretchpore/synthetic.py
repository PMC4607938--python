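"""Seeded pseudo-atomistic bilayer generator with known ground truth.

Builds planar two-leaflet DPPC(/cholesterol) configurations whose structural
observables — thickness, sn-2 chain order, cholesterol tilt, leaflet
interdigitation, trans-bilayer water defects — are set by construction, so
the downstream analysis can be tested for exact parameter recovery without
running molecular dynamics.  No energetics or solvent structure is claimed.

Pseudo-molecule geometry: DPPC is one head bead ("P") plus 14 colinear sn-2
carbons at 0.125 nm spacing; cholesterol is a rigid rod from "C5" (head end,
hydroxyl-bearing) to "C21" (tail end), 0.9 nm long; water is a single "OW"
bead.  Chain/rod axes are drawn from a "Gaussian cap" around the bilayer
normal: polar angle Theta = |N(0, tilt_sd)|, azimuth uniform, which gives the
exact closed form E[S] = (1 + 3 exp(-2 sigma^2)) / 4 for the chain order
parameter S = <(3 cos^2 Theta - 1)/2>.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .deform import StretchSchedule
from .frames import Frame, FrameError, N_SN2_CARBONS, SN2_NAMES, Trajectory

CHAIN_SPACING = 0.125  # nm between consecutive sn-2 carbons
CHAIN_LENGTH = (N_SN2_CARBONS - 1) * CHAIN_SPACING  # 1.625 nm, C1 -> C14
CHOL_ROD_LENGTH = 0.9  # nm, C5 -> C21
WATER_NUMBER_DENSITY = 33.0  # beads / nm^3 (simple-cubic lattice)
WATER_JITTER_FRACTION = 0.10
CORE_WATER_PAD = 0.20  # nm kept water-free beyond each P plane


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# composition and response models
# ---------------------------------------------------------------------------

@dataclass
class CompositionSpec:
    """Molecule counts for one system; label 'chol40' asserts ~40 mol% cholesterol."""

    n_dppc: int
    n_chol: int = 0
    n_water: int = 0
    label: str = "custom"

    def __post_init__(self) -> None:
        if min(self.n_dppc, self.n_chol, self.n_water) < 0:
            raise SyntheticError("molecule counts must be non-negative")
        if self.label == "chol40":
            frac = self.n_chol / max(self.n_chol + self.n_dppc, 1)
            if abs(frac - 0.40) > 0.02:
                raise SyntheticError(
                    f"label 'chol40' requires a cholesterol mole fraction of "
                    f"0.40 +/- 0.02, got {frac:.3f}")


def study_composition(label: str) -> CompositionSpec:
    """The two study compositions: pure DPPC and DPPC + 40 mol% cholesterol."""
    if label == "pure":
        return CompositionSpec(n_dppc=128, n_chol=0, n_water=16483, label="pure")
    if label == "chol40":
        return CompositionSpec(n_dppc=128, n_chol=86, n_water=13842, label="chol40")
    raise SyntheticError(f"unknown composition label {label!r}")


def expected_order_parameter(tilt_sd_deg: float) -> float:
    """Closed-form E[S] under the Gaussian-cap tilt distribution."""
    sigma = np.deg2rad(tilt_sd_deg)
    return (1.0 + 3.0 * np.exp(-2.0 * sigma ** 2)) / 4.0


def tilt_sd_for_order(s_target: float) -> float:
    """Invert :func:`expected_order_parameter`; s_target must lie in (0.25, 1]."""
    s = float(np.clip(s_target, 0.2501, 1.0))
    arg = (4.0 * s - 1.0) / 3.0
    return float(np.rad2deg(np.sqrt(-np.log(arg) / 2.0)))


def _recovery_profile() -> Callable[[float], float]:
    # dips, recovers slowly then sharply, peaks at eps_A = 1.0, decays again
    eps = np.array([0.0, 0.30, 0.55, 0.80, 1.00, 1.20, 1.60, 3.00])
    s = np.array([0.75, 0.46, 0.45, 0.52, 0.68, 0.60, 0.48, 0.36])
    interp = PchipInterpolator(eps, s, extrapolate=False)

    def profile(e: float) -> float:
        return float(interp(np.clip(e, 0.0, 3.0)))

    return profile


ORDER_PROFILES: dict[str, Callable[[float], float]] = {
    "monotone_decrease": lambda e: float(max(0.31, 0.75 - 0.28 * e)),
    "recovery": _recovery_profile(),
}


@dataclass
class ResponseModel:
    """Prescribed structural response of the pseudo-bilayer to areal strain.

    thickness_rule maps eps_A -> l_t in nm (default: volume-conserving
    l_t0 / (1 + eps_A)); order_profile maps eps_A -> target S_tail (named
    preset or callable); pore_strain, if set, is the strain at and beyond
    which ``n_channels`` trans-bilayer water channels are present;
    replicate_noise holds standard deviations for per-replicate jitter
    (keys: ``pore_strain_sd``, ``order_sd``).
    """

    l_t0: float = 4.0
    thickness_rule: Callable[[float], float] | None = None
    order_profile: str | Callable[[float], float] = "monotone_decrease"
    interdigitation_profile: Callable[[float], float] | None = None
    pore_strain: float | None = None
    n_channels: int = 1
    replicate_noise: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pore_strain is not None and self.pore_strain < 0:
            raise SyntheticError("pore_strain must be >= 0")
        if self.l_t0 <= 0:
            raise SyntheticError("l_t0 must be > 0")
        probe = np.linspace(0.0, 3.0, 31)
        lt = np.array([self.thickness_at(e) for e in probe])
        if np.any(lt <= 0) or np.any(np.diff(lt) > 1e-9):
            raise SyntheticError("thickness_rule must be positive and non-increasing")

    def thickness_at(self, eps_a: float) -> float:
        if self.thickness_rule is not None:
            return float(self.thickness_rule(eps_a))
        return self.l_t0 / (1.0 + eps_a)

    def order_at(self, eps_a: float) -> float:
        if callable(self.order_profile):
            return float(self.order_profile(eps_a))
        try:
            return ORDER_PROFILES[self.order_profile](eps_a)
        except KeyError as exc:
            raise SyntheticError(
                f"unknown order profile {self.order_profile!r}; "
                f"presets: {sorted(ORDER_PROFILES)}") from exc

    def tilt_sd_at(self, eps_a: float) -> float:
        return tilt_sd_for_order(self.order_at(eps_a))

    def interdigitation_at(self, eps_a: float) -> float:
        if self.interdigitation_profile is None:
            return 0.0
        return float(self.interdigitation_profile(eps_a))


# ---------------------------------------------------------------------------
# frame construction
# ---------------------------------------------------------------------------

def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _draw_axes(rng: np.random.Generator, n: int, tilt_sd_deg: float,
               downward: bool) -> np.ndarray:
    """Unit axes from the Gaussian cap around +z (downward=False) or -z."""
    theta = np.abs(rng.normal(0.0, np.deg2rad(tilt_sd_deg), size=n)) if tilt_sd_deg > 0 \
        else np.zeros(n)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    axes = np.column_stack([np.sin(theta) * np.cos(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(theta)])
    if downward:
        axes[:, 2] *= -1.0
    return axes


def default_box(comp: CompositionSpec, l_x: float = 6.47, thickness: float = 4.0,
                headroom: float = 1.4) -> tuple[float, float, float]:
    """Box sized so the water slabs hold ``comp.n_water`` at ~33 beads/nm^3."""
    slab = comp.n_water / (WATER_NUMBER_DENSITY * l_x * l_x) * headroom
    l_z = thickness + 2.0 * CORE_WATER_PAD + slab + 0.6
    return (l_x, l_x, l_z)


def build_frame(comp: CompositionSpec, box: Sequence[float], thickness: float,
                tilt_sd: float = 10.0, interdigitation_depth: float = 0.0,
                seed=0, z_jitter: float = 0.02, time: float = 0.0,
                layout_seed=None) -> Frame:
    """Build one pseudo-bilayer frame with the requested ground truth.

    Lipids sit on a jittered square lattice, half per leaflet; DPPC phosphorus
    planes are separated by ``thickness``; chain/rod axes are drawn around
    +/-z with spread ``tilt_sd`` (degrees); sn-2 terminal carbons of each
    leaflet extend ``interdigitation_depth`` nm past the midplane; water
    fills the remaining slab.  Deterministic for a fixed seed.

    ``layout_seed``, when given, fixes which lattice site carries which
    molecule kind independently of ``seed``, so the frames of one trajectory
    share a topology (atom/residue ordering) while positions resample.
    """
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise SyntheticError("box lengths must be > 0")
    if comp.n_dppc + comp.n_chol == 0:
        raise SyntheticError("at least one lipid is required")
    if not 0 <= thickness < box[2]:
        raise SyntheticError("need 0 <= thickness < l_z (no room for water)")
    if tilt_sd < 0:
        raise SyntheticError("tilt_sd must be >= 0")

    rng = _rng(seed)
    layout_rng = _rng(layout_seed) if layout_seed is not None else rng
    l_x, l_y, l_z = box
    mid = l_z / 2.0

    pos, names, rtypes, ridx = [], [], [], []
    res_counter = 0

    # split molecules over leaflets (upper gets the remainder)
    n_dppc_lower = comp.n_dppc // 2
    n_chol_lower = comp.n_chol // 2
    for leaflet, n_dppc_leaf, n_chol_leaf in (
            ("upper", comp.n_dppc - n_dppc_lower, comp.n_chol - n_chol_lower),
            ("lower", n_dppc_lower, n_chol_lower)):
        n_lip = n_dppc_leaf + n_chol_leaf
        if n_lip == 0:
            continue
        sign = 1.0 if leaflet == "upper" else -1.0
        n_side = int(np.ceil(np.sqrt(n_lip)))
        sx, sy = l_x / n_side, l_y / n_side
        gx, gy = np.meshgrid(np.arange(n_side), np.arange(n_side), indexing="ij")
        sites = np.column_stack([(gx.ravel() + 0.5) * sx, (gy.ravel() + 0.5) * sy])
        sites = sites[:n_lip]
        sites += rng.uniform(-0.1, 0.1, size=sites.shape) * np.array([sx, sy])
        kinds = np.array(["DPPC"] * n_dppc_leaf + ["CHOL"] * n_chol_leaf)
        layout_rng.shuffle(kinds)
        axes = _draw_axes(rng, n_lip, tilt_sd, downward=(leaflet == "upper"))
        head_z = mid + sign * thickness / 2.0
        term_z = mid - sign * interdigitation_depth
        jz = rng.normal(0.0, z_jitter, size=n_lip) if z_jitter > 0 else np.zeros(n_lip)
        for i in range(n_lip):
            res_counter += 1
            x, y = sites[i]
            a = axes[i]  # points from head side toward the midplane
            if kinds[i] == "DPPC":
                pos.append([x, y, head_z + jz[i]])
                names.append("P")
                rtypes.append("DPPC")
                ridx.append(res_counter)
                # colinear chain ending exactly at the target terminal plane
                c14 = np.array([x, y, term_z])
                for k in range(1, N_SN2_CARBONS + 1):
                    p = c14 - a * CHAIN_SPACING * (N_SN2_CARBONS - k)
                    pos.append(p)
                    names.append(SN2_NAMES[k - 1])
                    rtypes.append("DPPC")
                    ridx.append(res_counter)
            else:
                c5 = np.array([x, y, head_z + jz[i]])
                c21 = c5 + a * CHOL_ROD_LENGTH
                pos.append(c5)
                names.append("C5")
                rtypes.append("CHOL")
                ridx.append(res_counter)
                pos.append(c21)
                names.append("C21")
                rtypes.append("CHOL")
                ridx.append(res_counter)

    # water slabs above and below the bilayer
    if comp.n_water > 0:
        a = (1.0 / WATER_NUMBER_DENSITY) ** (1.0 / 3.0)
        z_lo = mid - thickness / 2.0 - CORE_WATER_PAD
        z_hi = mid + thickness / 2.0 + CORE_WATER_PAD
        xs = np.arange(a / 2, l_x, a)
        ys = np.arange(a / 2, l_y, a)
        zs = np.arange(a / 2, l_z, a)
        zs = zs[(zs < z_lo) | (zs > z_hi)]
        if len(zs) == 0:
            raise SyntheticError("no room for water outside the bilayer core")
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        lattice = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        if len(lattice) < comp.n_water:
            raise SyntheticError(
                f"water slab holds only {len(lattice)} lattice sites; "
                f"{comp.n_water} requested — enlarge the box")
        pick = rng.choice(len(lattice), size=comp.n_water, replace=False)
        waters = lattice[np.sort(pick)]
        waters = waters + rng.uniform(-WATER_JITTER_FRACTION * a,
                                      WATER_JITTER_FRACTION * a, size=waters.shape)
        for w in waters:
            res_counter += 1
            pos.append(w)
            names.append("OW")
            rtypes.append("WATER")
            ridx.append(res_counter)

    frame = Frame(np.asarray(pos, dtype=float), np.array(names, dtype=object),
                  np.array(rtypes, dtype=object), np.asarray(ridx, dtype=int),
                  box, time=time).wrapped()
    frame.validate()
    return frame


# ---------------------------------------------------------------------------
# trans-bilayer water channels
# ---------------------------------------------------------------------------

def insert_transbilayer_water(frame: Frame, centers: Sequence[Sequence[float]],
                              radius: float = 0.2, spacing: float = 0.25,
                              seed=0, overshoot: float = 0.2) -> Frame:
    """Add columns of water beads connecting the two bulk slabs through the core.

    Each column is a solid cylinder of beads (pitch <= ``spacing`` axially and
    laterally, lateral extent ``radius``) running from ``overshoot`` nm below
    the lower phosphorus plane to ``overshoot`` nm above the upper one.
    Pre-existing atoms are never moved.
    """
    if radius <= 0:
        raise SyntheticError("channel radius must be > 0")
    if spacing <= 0:
        raise SyntheticError("bead spacing must be > 0")
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    l_x, l_y, _ = frame.box
    if np.any(centers < 0) or np.any(centers[:, 0] >= l_x) or np.any(centers[:, 1] >= l_y):
        raise SyntheticError("channel centers must lie inside the box")

    p_mask = frame.mask(residue_type="DPPC", atom_name="P")
    if not p_mask.any():
        raise SyntheticError("frame has no DPPC phosphorus atoms")
    pz = frame.positions[p_mask, 2]
    mid = pz.mean()
    z_up = pz[pz > mid].mean()
    z_lo = pz[pz <= mid].mean()

    rng = _rng(seed)
    zs = np.arange(z_lo - overshoot, z_up + overshoot + spacing / 2, spacing)
    ring_pitch = spacing * 0.9
    new = []
    for cx, cy in centers:
        offsets = [(0.0, 0.0)]
        r = ring_pitch
        while r <= radius + 1e-9:
            n_arc = max(int(np.ceil(2 * np.pi * r / ring_pitch)), 3)
            ang = np.linspace(0, 2 * np.pi, n_arc, endpoint=False)
            offsets.extend(zip(r * np.cos(ang), r * np.sin(ang)))
            r += ring_pitch
        for z in zs:
            for ox, oy in offsets:
                jit = rng.uniform(-0.03, 0.03, size=3) * spacing
                new.append([cx + ox + jit[0], cy + oy + jit[1], z + jit[2]])
    new = np.asarray(new, dtype=float)

    n_new = len(new)
    start = int(frame.residue_indices.max()) + 1
    out = Frame(np.vstack([frame.positions, new]),
                np.concatenate([frame.atom_names, np.array(["OW"] * n_new, dtype=object)]),
                np.concatenate([frame.residue_types,
                                np.array(["WATER"] * n_new, dtype=object)]),
                np.concatenate([frame.residue_indices,
                                start + np.arange(n_new)]),
                frame.box.copy(), frame.time).wrapped()
    out.validate()
    return out


# ---------------------------------------------------------------------------
# trajectory generation
# ---------------------------------------------------------------------------

def generate_trajectory(comp: CompositionSpec, schedule: StretchSchedule,
                        response: ResponseModel, seed: int = 0) -> Trajectory:
    """Frame series following the schedule with the prescribed response.

    Thickness follows ``response.thickness_rule``; per-frame chain axes are
    resampled so the measured S_tail tracks ``response.order_profile``;
    channels are present in every frame with eps_A >= ``response.pore_strain``.
    Frame k uses the seed substream (seed, k) so any frame is reproducible
    in isolation.
    """
    if len(schedule) == 0:
        raise SyntheticError("schedule has no frames")
    table = schedule.table
    lx0 = schedule.l_x0
    center_rng = _rng((seed, 1_000_003))
    frac_centers = None
    if response.pore_strain is not None and response.n_channels > 0:
        # same fractional centers at every frame: channels persist and move
        # affinely with the box
        frac_centers = _spread_fractional(center_rng, response.n_channels)

    frames = []
    for row in table.itertuples(index=False):
        k = int(row.frame)
        eps = float(row.strain)
        thickness = response.thickness_at(eps)
        tilt_sd = response.tilt_sd_at(eps)
        interdig = response.interdigitation_at(eps)
        fr = build_frame(comp, (row.l_x, row.l_y, row.l_z), thickness,
                         tilt_sd=tilt_sd, interdigitation_depth=interdig,
                         seed=(seed, k), time=float(row.time_ps),
                         layout_seed=(seed, 999_983))
        if (response.pore_strain is not None and response.n_channels > 0
                and eps >= response.pore_strain - 1e-12):
            centers = frac_centers * np.array([row.l_x, row.l_y])
            fr = insert_transbilayer_water(fr, centers, seed=(seed, k, 7))
        frames.append(fr)

    meta = {"mode": schedule.mode, "c_m_per_s": schedule.c,
            "l_x0_nm": lx0, "frame_interval_ps": schedule.frame_interval,
            "seed": seed, "composition": comp.label,
            "n_dppc": comp.n_dppc, "n_chol": comp.n_chol, "n_water": comp.n_water}
    if response.pore_strain is not None:
        meta["true_pore_strain"] = response.pore_strain
        meta["true_n_channels"] = response.n_channels
    return Trajectory(frames, meta)


def _spread_fractional(rng: np.random.Generator, n: int,
                       min_frac_sep: float = 0.30) -> np.ndarray:
    """n fractional (x, y) centers pairwise at least min_frac_sep apart."""
    for _ in range(500):
        cand = rng.uniform(0.12, 0.88, size=(n, 2))
        ok = True
        for i in range(n):
            for j in range(i + 1, n):
                if np.hypot(*(cand[i] - cand[j])) < min_frac_sep:
                    ok = False
        if ok:
            return cand
    raise SyntheticError("could not spread channel centers")
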