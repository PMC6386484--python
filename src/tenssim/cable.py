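"""Grouped-node Hodgkin-Huxley cable model of a myelinated fibre.

The fibre is a chain of N active compartments coupled by the axial
(axoplasmic) conductance G_a.  With V the reduced membrane potential,
V_e the extracellular potential at the nodes and G the tridiagonal cable
coupling matrix, the membrane obeys

    C_m dV/dt = -I_i(V, m, n, h) + G (V + V_e(t)),

jointly with first-order kinetics for the gating variables m, n, h.  The
extracellular drive factorises as profile x pulse(t) because conduction in
the tissue is purely resistive.  The system is stiff (membrane time
constants of tens of microseconds against a 30 ms horizon) and is integrated
piecewise around the square-pulse discontinuities with a variable-step
stiff solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .fibers import FiberGeometry
from .kinetics import GatingModel, HHParams

__all__ = [
    "CableState",
    "CableSimResult",
    "axial_conductance",
    "cable_matrix",
    "membrane_conductances",
    "ionic_current",
    "resting_state",
    "integrate_fiber",
]


@dataclass
class CableState:
    """Instantaneous state of the fibre: V (volts, reduced) and gates m, n, h."""

    v: np.ndarray
    m: np.ndarray
    n: np.ndarray
    h: np.ndarray

    def __post_init__(self) -> None:
        for name in ("v", "m", "n", "h"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")
        for name in ("m", "n", "h"):
            arr = getattr(self, name)
            if np.any(arr < -1e-9) or np.any(arr > 1 + 1e-9):
                raise ValueError(f"gating variable {name} outside [0, 1]")
            setattr(self, name, np.clip(arr, 0.0, 1.0))

    def pack(self) -> np.ndarray:
        """Interleave to (4N,) solver layout [V0, m0, n0, h0, V1, ...]."""
        return np.column_stack([self.v, self.m, self.n, self.h]).ravel()

    @classmethod
    def unpack(cls, y: np.ndarray) -> "CableState":
        u = y.reshape(-1, 4)
        return cls(v=u[:, 0], m=np.clip(u[:, 1], 0, 1),
                   n=np.clip(u[:, 2], 0, 1), h=np.clip(u[:, 3], 0, 1))


@dataclass
class CableSimResult:
    """Time-resolved membrane response of one fibre to one stimulus.

    ``v`` is (n_times, n_nodes) in volts (reduced potential); gating
    trajectories are optional.  ``stimulus`` is a free-form description of
    the drive; ``diagnostics`` carries solver statistics.
    """

    t: np.ndarray
    v: np.ndarray
    arc_length: np.ndarray
    stimulus: dict = field(default_factory=dict)
    gates: dict | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.v.shape != (len(self.t), len(self.arc_length)):
            raise ValueError("v must be (n_times, n_nodes)")

    @property
    def n_nodes(self) -> int:
        return self.v.shape[1]

    def snapshot(self, t: float) -> np.ndarray:
        """Linear-in-time interpolated V(node) at time ``t`` (s)."""
        if not (self.t[0] <= t <= self.t[-1]):
            raise ValueError(f"snapshot time {t} outside simulated range")
        i = np.searchsorted(self.t, t)
        if i == 0:
            return self.v[0].copy()
        w = (t - self.t[i - 1]) / (self.t[i] - self.t[i - 1])
        return (1 - w) * self.v[i - 1] + w * self.v[i]

    def last_node_trace(self) -> np.ndarray:
        return self.v[:, -1]

    def to_frame(self):
        """Long-format DataFrame (time s, node, arc-length mm, V mV)."""
        import pandas as pd

        nt, nn = self.v.shape
        return pd.DataFrame(
            {
                "time_s": np.repeat(self.t, nn),
                "node": np.tile(np.arange(nn), nt),
                "arc_length_mm": np.tile(self.arc_length * 1e3, nt),
                "v_mV": self.v.ravel() * 1e3,
            }
        )


def axial_conductance(fiber: FiberGeometry | None = None,
                      params: HHParams | None = None) -> float:
    """Axial internodal conductance G_a = pi d^2 / (4 rho_i dx_eff), in S.

    ``rho_i`` is the axoplasmic resistivity at the operating temperature
    (Q10-corrected unless disabled on ``params``).
    """
    fiber = fiber or FiberGeometry()
    params = params or HHParams()
    return math.pi * fiber.diameter**2 / (4.0 * params.rho_i_at_t * fiber.dx_eff)


def cable_matrix(n_nodes: int, g_a: float) -> np.ndarray:
    """Tridiagonal axial coupling matrix (S): sealed ends, zero row sums."""
    if n_nodes < 2:
        raise ValueError("cable needs at least two nodes")
    g = np.zeros((n_nodes, n_nodes))
    idx = np.arange(n_nodes - 1)
    g[idx, idx + 1] = g_a
    g[idx + 1, idx] = g_a
    g[idx, idx] -= g_a
    g[idx + 1, idx + 1] -= g_a
    return g


def _apply_cable(w: np.ndarray, g_a: float) -> np.ndarray:
    """G @ w for the tridiagonal cable matrix, without forming G."""
    out = np.empty_like(w)
    out[0] = g_a * (w[1] - w[0])
    out[-1] = g_a * (w[-2] - w[-1])
    out[1:-1] = g_a * (w[2:] - 2.0 * w[1:-1] + w[:-2])
    return out


def membrane_conductances(state: CableState, params: HHParams | None = None,
                          fiber: FiberGeometry | None = None):
    """Per-node sodium, potassium and leak conductances (S).

    G_Na = m^3 h G_Na,max, G_K = n^4 G_K,max, G_L = G_L,max, with
    G_ion,max = pi d L g_ion from the temperature-corrected per-area values
    and the lumped nodal membrane length L.
    """
    params = params or HHParams()
    fiber = fiber or FiberGeometry()
    area = fiber.membrane_area
    g_na = state.m**3 * state.h * (params.g_na_at_t * area)
    g_k = state.n**4 * (params.g_k_at_t * area)
    g_l = np.full_like(g_na, params.g_l_at_t * area)
    return g_na, g_k, g_l


def ionic_current(state: CableState, params: HHParams | None = None,
                  fiber: FiberGeometry | None = None) -> np.ndarray:
    """Total per-node ionic current I_i (A), positive outward."""
    params = params or HHParams()
    fiber = fiber or FiberGeometry()
    g_na, g_k, g_l = membrane_conductances(state, params, fiber)
    return (
        g_na * (state.v - params.v_na_max)
        + g_k * (state.v - params.v_k_max)
        + g_l * (state.v - params.v_l_max)
    )


def resting_state(n_nodes: int, params: HHParams | None = None) -> CableState:
    """Initial condition: V = 0 with gates at their V = 0 steady state.

    The printed parameter set is treated as approximately (not exactly)
    equilibrated at rest; residual drift is monitored by the resting
    stability tests rather than forced to zero.
    """
    params = params or HHParams()
    gm = GatingModel(params.gating, params.temperature, params.rate_cap)
    m, n, h = gm.steady_state(0.0)
    ones = np.ones(n_nodes)
    return CableState(v=np.zeros(n_nodes), m=m * ones, n=n * ones, h=h * ones)


def integrate_fiber(
    profile,
    pulse,
    params: HHParams | None = None,
    fiber: FiberGeometry | None = None,
    t_end: float = 0.03,
    rtol: float = 1e-6,
    atol_v: float = 1e-8,
    atol_gate: float = 1e-9,
    sample_dt: float = 5e-5,
    initial_state: CableState | None = None,
    t_start: float = 0.0,
    keep_gates: bool = False,
    method: str = "LSODA",
) -> CableSimResult:
    """Integrate the cable + HH system for one fibre and one stimulus.

    Parameters
    ----------
    profile : ExtracellularProfile or array
        Extracellular potential at each model node for the pattern's unit
        drive (volts); the time course is ``profile * pulse(t)``.
    pulse : StimulusPulse
        Monophasic square pulse (scaling function with onset and width).
    t_end : simulation horizon (s); must cover the pulse and the propagation
        time to the CNS-ward end.
    sample_dt : output sampling interval (s); 0.05 ms resolves AP shape.
    initial_state, t_start : optionally resume from a pre-relaxed state
        (e.g. the common resting history shared by all patterns in a screen).

    Returns
    -------
    CableSimResult with V sampled on a uniform grid plus segment boundaries.
    """
    from .volume_conductor import ExtracellularProfile

    params = params or HHParams()
    fiber = fiber or FiberGeometry()
    if isinstance(profile, ExtracellularProfile):
        arc = profile.arc_length
        ve_profile = profile.v_e
    else:
        ve_profile = np.asarray(profile, dtype=float)
        arc = np.arange(len(ve_profile)) * fiber.dx_eff
    n_nodes = len(ve_profile)
    if n_nodes != fiber.n_nodes:
        raise ValueError(
            f"profile length {n_nodes} does not match fibre node count {fiber.n_nodes}"
        )

    g_a = axial_conductance(fiber, params)
    c_m = params.c_m_area * fiber.capacitance_area
    area = fiber.membrane_area
    g_na_max = params.g_na_at_t * area
    g_k_max = params.g_k_at_t * area
    g_l_max = params.g_l_at_t * area
    v_na, v_k, v_l = params.v_na_max, params.v_k_max, params.v_l_max
    gm = GatingModel(params.gating, params.temperature, params.rate_cap)

    def rhs(t, y, ve_scale):
        u = y.reshape(-1, 4)
        v = u[:, 0]
        m = np.clip(u[:, 1], 0.0, 1.0)
        n = np.clip(u[:, 2], 0.0, 1.0)
        h = np.clip(u[:, 3], 0.0, 1.0)
        am, bm, ah, bh, an, bn = gm.rates(v)
        i_ion = (
            g_na_max * m**3 * h * (v - v_na)
            + g_k_max * n**4 * (v - v_k)
            + g_l_max * (v - v_l)
        )
        dv = (_apply_cable(v + ve_scale * ve_profile, g_a) - i_ion) / c_m
        out = np.empty_like(u)
        out[:, 0] = dv
        out[:, 1] = am * (1.0 - m) - bm * m
        out[:, 2] = an * (1.0 - n) - bn * n
        out[:, 3] = ah * (1.0 - h) - bh * h
        return out.ravel()

    state0 = initial_state or resting_state(n_nodes, params)
    y = state0.pack()
    atol = np.tile([atol_v, atol_gate, atol_gate, atol_gate], n_nodes)

    # segment boundaries at the pulse edges keep the stiff solver honest
    edges = [t_start]
    for edge in (pulse.onset, pulse.onset + pulse.width, t_end):
        if t_start < edge <= t_end and edge > edges[-1]:
            edges.append(edge)
    if edges[-1] < t_end:
        edges.append(t_end)

    times = [np.array([t_start])]
    vs = [state0.v[None, :]]
    gates_traj = {"m": [state0.m[None, :]], "n": [state0.n[None, :]],
                  "h": [state0.h[None, :]]} if keep_gates else None
    nfev = 0
    njev = 0
    for a, b in zip(edges[:-1], edges[1:]):
        on = pulse.is_on(0.5 * (a + b))
        ve_scale = pulse.amplitude if on else 0.0
        n_samples = max(int(np.ceil((b - a) / sample_dt)), 2)
        t_eval = np.linspace(a, b, n_samples + 1)[1:]
        kwargs = dict(rtol=rtol, atol=atol, t_eval=t_eval, method=method)
        if method == "LSODA":
            kwargs.update(lband=4, uband=4)
        sol = solve_ivp(rhs, (a, b), y, args=(ve_scale,), **kwargs)
        if not sol.success:
            raise RuntimeError(
                f"cable integration failed on [{a:.4g}, {b:.4g}] s: {sol.message}"
            )
        if not np.all(np.isfinite(sol.y)):
            raise RuntimeError("non-finite state encountered during integration")
        nfev += sol.nfev
        njev += getattr(sol, "njev", 0)
        y = sol.y[:, -1]
        u = sol.y.T.reshape(len(sol.t), n_nodes, 4)
        times.append(sol.t)
        vs.append(u[:, :, 0])
        if keep_gates:
            for j, gname in enumerate(("m", "n", "h"), start=1):
                gates_traj[gname].append(np.clip(u[:, :, j], 0.0, 1.0))

    t_all = np.concatenate(times)
    v_all = np.vstack(vs)
    keep = np.concatenate([[True], np.diff(t_all) > 1e-15])
    result = CableSimResult(
        t=t_all[keep],
        v=v_all[keep],
        arc_length=np.asarray(arc, dtype=float),
        stimulus={"pulse_onset_s": pulse.onset, "pulse_width_s": pulse.width,
                  "profile_max_V": float(np.max(np.abs(ve_profile)))},
        gates={k: np.vstack(v)[keep] for k, v in gates_traj.items()} if keep_gates else None,
        diagnostics={"nfev": nfev, "njev": njev, "method": method,
                     "rtol": rtol, "segments": len(edges) - 1},
    )
    # gates must stay physical; V must stay finite (checked above)
    if keep_gates:
        for gname, traj in result.gates.items():
            if np.any(traj < 0) or np.any(traj > 1):
                raise RuntimeError(f"gating variable {gname} left [0, 1]")
    return result
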