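"""Stimulus waveforms and electrode-current patterns.

Patterns are signed per-electrode currents in amperes, bounded by the
+/-5 mA comfort/safety limit and (approximately) charge-balanced across the
array so that no net current is pushed deep into the body.  Sources are
published fixtures, a uniform rejection sampler, and reduced-electrode
derivations that keep only the CNS-ward end of the array active.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CURRENT_BOUND",
    "StimulusPulse",
    "StimulationPattern",
    "random_pattern",
    "pattern_stream",
    "preset_pattern",
    "reduce_pattern",
    "PRESET_NAMES",
]

#: safety bound on any single electrode current, A
CURRENT_BOUND = 5e-3
#: default tolerance on the pattern sum, A (the published eight-electrode
#: validation pattern sums to -0.008 mA, consistent with this choice)
DEFAULT_BALANCE_TOL = 0.01e-3


@dataclass(frozen=True)
class StimulusPulse:
    """Monophasic square pulse: 0/1 scaling function with onset and width.

    Defaults follow the study protocol: onset at 10 ms, width 0.45 ms
    (within the 0.2-0.7 ms chronaxie range of small myelinated axons).
    """

    onset: float = 0.01
    width: float = 0.00045
    amplitude: float = 1.0
    shape: str = "monophasic-square"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("pulse width must be positive")
        if self.onset < 0:
            raise ValueError("pulse onset must be non-negative")

    def is_on(self, t: float) -> bool:
        return self.onset <= t < self.onset + self.width

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return np.where((t >= self.onset) & (t < self.onset + self.width),
                        self.amplitude, 0.0)


@dataclass(frozen=True)
class StimulationPattern:
    """Signed per-electrode currents (A) with provenance and balance metadata."""

    currents: np.ndarray
    provenance: str = "unspecified"
    balance_tol: float = DEFAULT_BALANCE_TOL

    def __post_init__(self) -> None:
        arr = np.asarray(self.currents, dtype=float)
        object.__setattr__(self, "currents", arr)
        over = np.abs(arr) > CURRENT_BOUND * (1 + 1e-12)
        if np.any(over):
            k = int(np.argmax(over))
            raise ValueError(
                f"electrode {k + 1} current {arr[k] * 1e3:.3f} mA exceeds the "
                f"+/-{CURRENT_BOUND * 1e3:g} mA safety bound"
            )
        if self.balance_tol is not None and abs(arr.sum()) > self.balance_tol + 1e-15:
            raise ValueError(
                f"pattern sum {arr.sum() * 1e3:.4f} mA exceeds balance tolerance "
                f"{self.balance_tol * 1e3:g} mA"
            )

    @property
    def n_electrodes(self) -> int:
        return len(self.currents)

    @property
    def total(self) -> float:
        return float(self.currents.sum())

    def currents_mA(self) -> np.ndarray:
        return self.currents * 1e3


def random_pattern(
    rng: np.random.Generator,
    n_electrodes: int = 8,
    bound: float = CURRENT_BOUND,
    balance_tol: float = DEFAULT_BALANCE_TOL,
    max_draws: int = 200_000,
    provenance: str = "random",
) -> StimulationPattern:
    """Draw one accepted pattern: i.i.d. uniform(-bound, bound) per electrode,
    redrawn until the pattern sum is within ``balance_tol`` of zero.

    The acceptance region makes low total-magnitude patterns more likely
    than high ones; that bias is an emergent property of the sampler, not a
    separate shaping step.
    """
    if balance_tol <= 0:
        raise ValueError("balance tolerance must be positive")
    for _ in range(max_draws):
        draw = rng.uniform(-bound, bound, size=n_electrodes)
        if abs(draw.sum()) <= balance_tol:
            return StimulationPattern(draw, provenance=provenance, balance_tol=balance_tol)
    raise RuntimeError(
        f"no balanced pattern found in {max_draws} draws "
        f"(tolerance {balance_tol * 1e3:g} mA is pathologically tight)"
    )


def pattern_stream(seed: int, n_patterns: int, n_electrodes: int = 8,
                   bound: float = CURRENT_BOUND,
                   balance_tol: float = DEFAULT_BALANCE_TOL) -> list[StimulationPattern]:
    """Reproducible list of accepted patterns.

    A master seed spawns one independent substream per pattern, so the list
    is order-independent and byte-identical across runs and platforms.
    """
    children = np.random.SeedSequence(seed).spawn(n_patterns)
    return [
        random_pattern(
            np.random.default_rng(child), n_electrodes, bound, balance_tol,
            provenance=f"random[seed={seed},index={i}]",
        )
        for i, child in enumerate(children)
    ]


_PRESETS_mA = {
    # two-electrode validation: +3 mA at 7 mm, -3 mA at 9 mm (electrodes 1, 2)
    "validation_2el": [3.0, -3.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    # eight-electrode validation pattern
    "validation_8el": [-0.43, -0.453, 0.36, 0.23, -0.024, 0.36, -0.047, -0.004],
    # anodic stimulation: main electrode 4 sources, the others return
    "anodic_8": [-0.01, -0.01, -0.01, 0.07, -0.01, -0.01, -0.01, -0.01],
    # cathodic stimulation: main electrode 4 sinks three times the anodic drive
    "cathodic_8": [0.03, 0.03, 0.03, -0.21, 0.03, 0.03, 0.03, 0.03],
}

PRESET_NAMES = tuple(_PRESETS_mA)


def preset_pattern(name: str) -> StimulationPattern:
    """Return one of the published fixture patterns by name."""
    if name not in _PRESETS_mA:
        raise KeyError(
            f"unknown preset {name!r}; valid fixtures: {', '.join(PRESET_NAMES)}"
        )
    return StimulationPattern(
        np.array(_PRESETS_mA[name]) * 1e-3, provenance=f"fixture:{name}"
    )


def reduce_pattern(pattern: StimulationPattern, active: int) -> StimulationPattern:
    """Derive a 3- or 2-active-electrode pattern from an 8-electrode one.

    * ``active=3``: electrodes 7 and 8 keep their currents, electrode 6
      balances them, electrodes 1-5 carry nothing.
    * ``active=2``: electrode 8 keeps its current, electrode 7 carries the
      inverse, electrodes 1-6 carry nothing.

    The result is exactly balanced.
    """
    if pattern.n_electrodes != 8:
        raise ValueError("reduction is defined for 8-electrode patterns")
    if active not in (2, 3):
        raise ValueError("active electrode count must be 2 or 3")
    out = np.zeros(8)
    if active == 3:
        out[6], out[7] = pattern.currents[6], pattern.currents[7]
        out[5] = -(out[6] + out[7])
        balancing = out[5]
    else:
        out[7] = pattern.currents[7]
        out[6] = -out[7]
        balancing = out[6]
    if abs(balancing) > CURRENT_BOUND:
        raise ValueError(
            f"balancing current {balancing * 1e3:.3f} mA exceeds the "
            f"+/-{CURRENT_BOUND * 1e3:g} mA safety bound"
        )
    return StimulationPattern(
        out, provenance=f"reduced[{active}]<-{pattern.provenance}", balance_tol=1e-12
    )
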