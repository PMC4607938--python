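"""Stretching-schedule mathematics for unsteady (US) and quasistatic (QS) runs.

Unsteady stretching scales box lengths and atom positions affinely per time
step: laterally by the same factor mu in x and y (equibiaxial stretching),
and in z by the Berendsen weak-coupling factor that drives the normal
pressure toward its reference value.  Units follow the project convention
1 m/s = 1 nm/ns = 1e-3 nm/ps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .frames import Frame

#: stretching-speed unit conversion, m/s -> nm/ps
M_PER_S_TO_NM_PER_PS = 1e-3


class DeformError(ValueError):
    pass


@dataclass
class DeformParams:
    """Coupling parameters of the deformation protocol.

    c : stretching speed, m/s; dt : MD time step, ps; tau_p : pressure
    coupling constant, ps; beta : isothermal compressibility, bar^-1;
    P0 : reference normal pressure, bar.
    """

    c: float = 0.0
    dt: float = 0.002
    tau_p: float = 0.5
    beta: float = 4.5e-5
    P0: float = 1.0

    def __post_init__(self) -> None:
        if self.c < 0:
            raise DeformError("stretching speed c must be >= 0")
        if self.dt <= 0 or self.tau_p <= 0 or self.beta <= 0:
            raise DeformError("dt, tau_p and beta must be > 0")


def lateral_scale_factor(l: float, c: float, dt: float) -> float:
    """Per-step lateral scale factor mu = (l + c*dt)/l.

    Realizes a constant box-edge growth speed c, i.e. l(t) = l0 + c*t when
    the factor is recomputed at the current length every step.
    """
    if l <= 0 or dt <= 0:
        raise DeformError("l and dt must be > 0")
    if c < 0:
        raise DeformError("c must be >= 0")
    return (l + c * M_PER_S_TO_NM_PER_PS * dt) / l


def berendsen_z_factor(P_z: float, params: DeformParams) -> float:
    """Berendsen scaling factor mu_z = [1 - (dt/tau_p) * beta * (P0 - P_z)]^(1/3)."""
    bracket = 1.0 - (params.dt / params.tau_p) * params.beta * (params.P0 - P_z)
    if bracket <= 0:
        raise DeformError(
            f"Berendsen bracket {bracket:g} <= 0: inputs outside the weak-coupling "
            "validity range")
    return bracket ** (1.0 / 3.0)


def apply_scaling(frame: Frame, mu_x: float, mu_y: float, mu_z: float) -> Frame:
    """Scale positions and box componentwise (affine deformation)."""
    mu = np.array([mu_x, mu_y, mu_z], dtype=float)
    if np.any(mu <= 0):
        raise DeformError("scale factors must be > 0")
    out = frame.copy()
    out.positions = frame.positions * mu[None, :]
    out.box = frame.box * mu
    return out


def strain_at_time(l_x0: float, c: float, t_ns: float) -> float:
    """Areal strain after stretching for t_ns at speed c: ((l0 + c t)/l0)^2 - 1."""
    if l_x0 <= 0:
        raise DeformError("l_x0 must be > 0")
    return ((l_x0 + c * t_ns) / l_x0) ** 2 - 1.0


def time_to_strain(l_x0: float, c: float, eps_a: float) -> float:
    """Inverse of :func:`strain_at_time`: time (ns) to reach areal strain eps_a."""
    if l_x0 <= 0 or c <= 0:
        raise DeformError("l_x0 and c must be > 0 for the inverse")
    if eps_a < 0:
        raise DeformError("target areal strain must be >= 0")
    return l_x0 * (np.sqrt(1.0 + eps_a) - 1.0) / c


@dataclass
class StretchSchedule:
    """A discretized stretching schedule with per-frame box lengths.

    ``table`` columns: frame, time_ps, l_x, l_y, l_z, strain.
    mode US: box grows until the stop strain; mode QS: constant box at
    ``target_strain``.  ``growth`` selects the lateral rule: "linear"
    (constant edge speed, default) or "exponential" (fixed per-step factor).
    """

    mode: str
    l_x0: float
    target_strain: float
    frame_interval: float  # ps
    c: float = 0.0  # m/s, US only
    l_z: float = 15.0  # nm, constant (P_z = P0 in synthetic pipelines)
    growth: str = "linear"
    n_frames_qs: int = 11
    table: pd.DataFrame = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.mode not in ("US", "QS"):
            raise DeformError("mode must be 'US' or 'QS'")
        if self.frame_interval <= 0:
            raise DeformError("frame_interval must be > 0")
        if self.target_strain < 0:
            raise DeformError("target_strain must be >= 0")
        if self.mode == "US" and self.c <= 0:
            raise DeformError("US mode requires c > 0")
        if self.growth not in ("linear", "exponential"):
            raise DeformError("growth must be 'linear' or 'exponential'")
        if self.table is None:
            self.table = self._build_table()

    def _build_table(self) -> pd.DataFrame:
        lx0 = self.l_x0
        if self.mode == "QS":
            lx = lx0 * np.sqrt(1.0 + self.target_strain)
            times = np.arange(self.n_frames_qs) * self.frame_interval
            lxs = np.full_like(times, lx, dtype=float)
        else:
            t_stop_ps = time_to_strain(lx0, self.c, self.target_strain) * 1e3
            n = int(np.ceil(t_stop_ps / self.frame_interval)) + 1
            times = np.arange(n) * self.frame_interval
            if self.growth == "linear":
                lxs = lx0 + self.c * M_PER_S_TO_NM_PER_PS * times
            else:
                # fixed per-step factor evaluated at l_x0, dt = frame_interval
                mu0 = 1.0 + self.c * M_PER_S_TO_NM_PER_PS * self.frame_interval / lx0
                lxs = lx0 * mu0 ** np.arange(n)
        strain = (lxs / lx0) ** 2 - 1.0
        return pd.DataFrame({
            "frame": np.arange(len(times), dtype=int),
            "time_ps": times.astype(float),
            "l_x": lxs,
            "l_y": lxs,
            "l_z": np.full(len(times), self.l_z, dtype=float),
            "strain": strain,
        })

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str, mode: str, l_x0: float, target_strain: float,
                 frame_interval: float, c: float = 0.0) -> "StretchSchedule":
        table = pd.read_csv(path)
        sched = cls(mode=mode, l_x0=l_x0, target_strain=target_strain,
                    frame_interval=frame_interval, c=max(c, 1e-12) if mode == "US" else c,
                    table=table)
        return sched


def build_schedule(mode: str, c: float, frame_interval: float, target_strain: float,
                   l_x0: float, l_z: float = 15.0, growth: str = "linear",
                   n_frames_qs: int = 11) -> StretchSchedule:
    """Construct a :class:`StretchSchedule` (see class docstring)."""
    return StretchSchedule(mode=mode, c=c, frame_interval=frame_interval,
                           target_strain=target_strain, l_x0=l_x0, l_z=l_z,
                           growth=growth, n_frames_qs=n_frames_qs)
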