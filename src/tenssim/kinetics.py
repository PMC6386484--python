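"""Temperature-compensated Hodgkin-Huxley kinetics for human myelinated nerve fibres.

The membrane model is the classical HH formalism with rate constants adapted to
human sensory fibres: each gate's opening/closing rates carry a per-gate
acceleration factor (4.42 for m, 1.47 for h, 0.2 for n) folded into the ``A``
coefficient, an explicit Q10 temperature correction, and the factor 1000 that
converts the classical mV/ms rate laws to SI volts and seconds.  Membrane
potentials throughout are *reduced* potentials: V = 0 at rest, positive values
are depolarisations.

Three algebraic forms occur:

* "singular"    rate = 1000*A*Q10f * u / (D*(exp(u) - 1)),  u = B - 1000*C*V
                 (alpha_m, alpha_n; removable singularity at u = 0)
* "exponential" rate = 1000*A*Q10f * B * exp(-1000*V/C)
                 (beta_m, alpha_h, beta_n)
* "logistic"    rate = 1000*A*Q10f / (exp(B - 1000*C*V) + 1)
                 (beta_h)

with Q10f = Q10**((T - T0)/10).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "FARADAY",
    "Q10Param",
    "RateConstants",
    "GatingConstants",
    "HHParams",
    "q10_factor",
    "nernst_potential",
    "rate_constants",
    "gating_steady_state",
    "GatingModel",
]

#: Universal gas constant, J/(K mol)
GAS_CONSTANT = 8.315
#: Faraday constant, C/mol
FARADAY = 9.649e4

_KELVIN = 273.15

# Exponent clip that keeps exp() finite in double precision.
_EXP_CLIP = 500.0


def q10_factor(q10: float, t: float, t0: float) -> float:
    """Q10 temperature scaling ``q10 ** ((t - t0) / 10)``.

    Parameters
    ----------
    q10 : factor per 10 degC change (must be > 0).
    t, t0 : operating and reference temperature, degC.
    """
    if q10 <= 0:
        raise ValueError(f"Q10 must be positive, got {q10}")
    return float(q10) ** ((t - t0) / 10.0)


def nernst_potential(ratio: float, t: float, v_r: float) -> float:
    """Reduced reversal potential from the Nernst equation.

    ``(R*T_K/F) * ln(ratio) - v_r`` with ``T_K = t + 273.15``; the resting
    potential ``v_r`` (a negative number, in volts) is subtracted so the
    result is on the reduced-potential scale used by the cable model.

    Parameters
    ----------
    ratio : extracellular-to-intracellular concentration ratio (> 0).
    t : temperature, degC.
    v_r : resting potential, V.
    """
    if ratio <= 0:
        raise ValueError(f"concentration ratio must be positive, got {ratio}")
    return GAS_CONSTANT * (t + _KELVIN) / FARADAY * np.log(ratio) - v_r


@dataclass(frozen=True)
class Q10Param:
    """A physical parameter with Q10 temperature dependence."""

    value: float
    q10: float = 1.0
    t0: float = 20.0

    def at(self, t: float) -> float:
        """Value corrected to temperature ``t`` degC."""
        return self.value * q10_factor(self.q10, t, self.t0)


@dataclass(frozen=True)
class RateConstants:
    """Coefficients A, B, C (and D for the singular form) of one rate law."""

    form: str  # "singular" | "exponential" | "logistic"
    a: float
    b: float
    c: float
    d: float | None = None
    q10: float = 1.0
    t0: float = 20.0

    def __post_init__(self) -> None:
        if self.form not in ("singular", "exponential", "logistic"):
            raise ValueError(f"unknown rate form {self.form!r}")
        if self.form == "singular" and self.d is None:
            raise ValueError("singular rate form requires coefficient D")
        if self.q10 < 1.0:
            raise ValueError("rate Q10 must be >= 1")

    def __call__(self, v, t: float, cap: float = 1e8):
        """Evaluate the rate (1/s) at reduced potential ``v`` (V), temp ``t`` degC.

        Rates are saturated at ``cap`` (1/s): extreme extracellular drive can
        push the membrane far outside the rate laws' validity range, and the
        saturation keeps the ODE system finite there.
        """
        v = np.asarray(v, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite membrane potential passed to rate law")
        scale = 1000.0 * self.a * q10_factor(self.q10, t, self.t0)
        if self.form == "singular":
            u = self.b - 1000.0 * self.c * v
            uc = np.clip(u, -_EXP_CLIP, _EXP_CLIP)
            small = np.abs(u) < 1e-6
            # series of u / (exp(u) - 1) about u = 0
            ratio = np.where(
                small, 1.0 - u / 2.0 + u * u / 12.0, uc / np.expm1(np.where(small, 1.0, uc))
            )
            rate = scale * ratio / self.d
        elif self.form == "exponential":
            arg = np.clip(-1000.0 * v / self.c, -_EXP_CLIP, _EXP_CLIP)
            rate = scale * self.b * np.exp(arg)
        else:  # logistic
            u = np.clip(self.b - 1000.0 * self.c * v, -_EXP_CLIP, _EXP_CLIP)
            rate = scale / (np.exp(u) + 1.0)
        return np.minimum(rate, cap)


def _default_rows() -> dict[str, RateConstants]:
    # Human-fibre HH rate coefficients.  The published parameter table lists
    # the h- and n-gate rows against each other's algebraic forms; the
    # assignment below restores the classical correspondence (the D column
    # only fits the singular form, and the resulting per-gate acceleration
    # factors are uniform: 4.42 for m, 1.47 for h, 0.2 for n) and reproduces
    # the classical steady states m=0.053, h=0.60, n=0.318 at rest.
    return {
        "alpha_m": RateConstants("singular", a=4.42, b=2.5, c=0.1, d=1.0, q10=2.23, t0=6.3),
        "beta_m": RateConstants("exponential", a=4.42, b=4.0, c=18.0, q10=2.23, t0=6.3),
        "alpha_h": RateConstants("exponential", a=1.47, b=0.07, c=20.0, q10=1.5, t0=6.3),
        "beta_h": RateConstants("logistic", a=1.47, b=3.0, c=0.1, q10=1.5, t0=6.3),
        "alpha_n": RateConstants("singular", a=0.2, b=1.0, c=0.1, d=10.0, q10=1.5, t0=6.3),
        "beta_n": RateConstants("exponential", a=0.2, b=0.125, c=80.0, q10=1.5, t0=6.3),
    }


@dataclass(frozen=True)
class GatingConstants:
    """The six rate laws governing the m, n and h gates."""

    alpha_m: RateConstants
    beta_m: RateConstants
    alpha_h: RateConstants
    beta_h: RateConstants
    alpha_n: RateConstants
    beta_n: RateConstants

    @classmethod
    def default(cls) -> "GatingConstants":
        return cls(**_default_rows())

    def as_tuple(self) -> tuple[RateConstants, ...]:
        return (self.alpha_m, self.beta_m, self.alpha_h, self.beta_h, self.alpha_n, self.beta_n)


@dataclass(frozen=True)
class HHParams:
    """Full physiological parameter set for the human myelinated fibre membrane.

    All quantities are SI.  Conductances per membrane area (S/m^2), the
    axoplasmic resistivity (ohm m) and the resting potential carry Q10
    metadata and are corrected to the operating temperature ``temperature``
    (degC) on access through the ``*_at_t`` properties.
    """

    v_r: Q10Param = Q10Param(-79.4e-3, q10=1.035, t0=6.3)
    na_ratio: float = 7.210
    k_ratio: float = 0.036
    leak_ratio: float = 0.0367
    g_na: Q10Param = Q10Param(6400.0, q10=1.02, t0=24.0)
    g_k: Q10Param = Q10Param(600.0, q10=1.16, t0=20.0)
    g_l: Q10Param = Q10Param(575.0, q10=1.418, t0=24.0)
    rho_i: Q10Param = Q10Param(0.25, q10=1 / 1.35, t0=37.0)
    c_m_area: float = 0.028
    temperature: float = 20.0
    gating: GatingConstants = field(default_factory=GatingConstants.default)
    rate_cap: float = 1e8
    #: apply the resting potential's Q10 correction (the printed conductance
    #: and concentration set is equilibrated at rest only with it applied)
    correct_v_r: bool = True
    #: apply the axoplasmic resistivity's Q10 correction at ``temperature``
    correct_rho_i: bool = True

    def __post_init__(self) -> None:
        for name in ("na_ratio", "k_ratio", "leak_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("g_na", "g_k", "g_l", "rho_i"):
            if getattr(self, name).value <= 0:
                raise ValueError(f"{name} must be positive")
        if self.c_m_area <= 0:
            raise ValueError("c_m_area must be positive")

    # -- temperature-corrected values ------------------------------------
    @property
    def v_r_at_t(self) -> float:
        return self.v_r.at(self.temperature) if self.correct_v_r else self.v_r.value

    @property
    def g_na_at_t(self) -> float:
        return self.g_na.at(self.temperature)

    @property
    def g_k_at_t(self) -> float:
        return self.g_k.at(self.temperature)

    @property
    def g_l_at_t(self) -> float:
        return self.g_l.at(self.temperature)

    @property
    def rho_i_at_t(self) -> float:
        return self.rho_i.at(self.temperature) if self.correct_rho_i else self.rho_i.value

    # -- reduced reversal potentials -------------------------------------
    @property
    def v_na_max(self) -> float:
        return nernst_potential(self.na_ratio, self.temperature, self.v_r_at_t)

    @property
    def v_k_max(self) -> float:
        return nernst_potential(self.k_ratio, self.temperature, self.v_r_at_t)

    @property
    def v_l_max(self) -> float:
        return nernst_potential(self.leak_ratio, self.temperature, self.v_r_at_t)


def rate_constants(v, constants: GatingConstants | None = None, t: float = 20.0, cap: float = 1e8):
    """Evaluate all six gating rates (1/s) at reduced potential ``v`` (V).

    Returns
    -------
    dict with keys alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n.
    """
    constants = constants or GatingConstants.default()
    names = ("alpha_m", "beta_m", "alpha_h", "beta_h", "alpha_n", "beta_n")
    return {name: rc(v, t, cap) for name, rc in zip(names, constants.as_tuple())}


def gating_steady_state(v, constants: GatingConstants | None = None, t: float = 20.0):
    """Steady-state gate values (m_inf, n_inf, h_inf) at reduced potential ``v``.

    Each is ``alpha / (alpha + beta)``, the fixed point of the first-order
    gate dynamics.
    """
    r = rate_constants(v, constants, t)
    m = r["alpha_m"] / (r["alpha_m"] + r["beta_m"])
    n = r["alpha_n"] / (r["alpha_n"] + r["beta_n"])
    h = r["alpha_h"] / (r["alpha_h"] + r["beta_h"])
    return m, n, h


class GatingModel:
    """Vectorised gate-rate evaluator with temperature factors precomputed.

    Used inside the ODE right-hand side, where the per-call overhead of
    re-deriving Q10 factors matters.
    """

    def __init__(self, constants: GatingConstants | None = None, t: float = 20.0,
                 rate_cap: float = 1e8):
        self.constants = constants or GatingConstants.default()
        self.t = t
        self.rate_cap = rate_cap
        rows = self.constants.as_tuple()
        self._scales = [1000.0 * rc.a * q10_factor(rc.q10, t, rc.t0) for rc in rows]

    def rates(self, v):
        """Return (alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n) arrays."""
        am_c, bm_c, ah_c, bh_c, an_c, bn_c = self.constants.as_tuple()
        s_am, s_bm, s_ah, s_bh, s_an, s_bn = self._scales
        cap = self.rate_cap

        def singular(scale, rc):
            u = rc.b - 1000.0 * rc.c * v
            uc = np.clip(u, -_EXP_CLIP, _EXP_CLIP)
            small = np.abs(u) < 1e-6
            ratio = np.where(
                small, 1.0 - u / 2.0 + u * u / 12.0, uc / np.expm1(np.where(small, 1.0, uc))
            )
            return np.minimum(scale * ratio / rc.d, cap)

        def exponential(scale, rc):
            arg = np.clip(-1000.0 * v / rc.c, -_EXP_CLIP, _EXP_CLIP)
            return np.minimum(scale * rc.b * np.exp(arg), cap)

        def logistic(scale, rc):
            u = np.clip(rc.b - 1000.0 * rc.c * v, -_EXP_CLIP, _EXP_CLIP)
            return np.minimum(scale / (np.exp(u) + 1.0), cap)

        return (
            singular(s_am, am_c),
            exponential(s_bm, bm_c),
            exponential(s_ah, ah_c),
            logistic(s_bh, bh_c),
            singular(s_an, an_c),
            exponential(s_bn, bn_c),
        )

    def steady_state(self, v):
        am, bm, ah, bh, an, bn = self.rates(np.asarray(v, dtype=float))
        return am / (am + bm), an / (an + bn), ah / (ah + bh)
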