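"""Activation/inhibition classification and selectivity taxonomy.

A fibre counts as *activated* when the action potential propagates to the
last model node (the CNS-ward end of the 30 mm span); it counts as
*inhibited* when no AP is found there.  Inhibited fibres are sub-classified
by mechanism: a stimulus too weak to excite the fibre at all, an anodic
inhibition (positive current at the last electrode hyperpolarising the
escape path), or a cathodic block (strong hyperpolarising flank of a
negative last-electrode current extinguishing the travelling spike).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cable import CableSimResult
from .stimulation import StimulationPattern, StimulusPulse

__all__ = [
    "FiberOutcome",
    "OutcomeRecord",
    "detect_activation",
    "consecutive_runs",
    "assess_fiber",
    "classify_selectivity",
    "MECHANISMS",
    "PAIR_LABELS",
]

#: per-fibre mechanism tags (mutually exclusive)
MECHANISMS = ("activated", "no_significant_response", "anodic_inhibition", "cathodic_block")

#: pattern-level taxonomy for a (shallow, deep) fibre pair
PAIR_LABELS = (
    "non_selective",
    "no_activation",
    "selective_shallow_weak",
    "selective_shallow_anodic",
    "selective_shallow_cathodic_block",
    "selective_deep_weak",
    "selective_deep_anodic",
    "selective_deep_cathodic_block",
)

#: default AP detection threshold at the last node, V above rest (chosen
#: midway between subthreshold responses < 30 mV and full APs > 80 mV)
DEFAULT_AP_THRESHOLD = 0.04
#: reduced-potential magnitude below which a node does not count towards a
#: depolarised/hyperpolarised run, V
DEFAULT_NOISE_FLOOR = 0.5e-3
#: peak |V| below which a fibre's response is "no significant response", V
WEAK_RESPONSE_LIMIT = 5e-3


def detect_activation(result: CableSimResult, threshold: float = DEFAULT_AP_THRESHOLD,
                      min_post_pulse: float = 0.015) -> tuple[bool, float]:
    """Decide activation from the last-node trace.

    Returns ``(activated, arrival_time)``; arrival is the first threshold
    crossing at the last node (NaN when not activated).  Requires the
    simulation to extend at least ``min_post_pulse`` beyond pulse onset so
    a propagating spike has time to arrive.
    """
    onset = result.stimulus.get("pulse_onset_s", 0.0)
    if result.t[-1] < onset + min_post_pulse:
        raise ValueError(
            f"simulation horizon {result.t[-1]:.4g} s too short: need at least "
            f"{min_post_pulse:.4g} s beyond pulse onset at {onset:.4g} s"
        )
    trace = result.last_node_trace()
    above = trace > threshold
    if not np.any(above):
        return False, float("nan")
    return True, float(result.t[int(np.argmax(above))])


def consecutive_runs(profile: np.ndarray, polarity: str,
                     noise_floor: float = DEFAULT_NOISE_FLOOR) -> int:
    """Longest run of consecutive nodes whose V matches ``polarity``.

    ``polarity`` is "depolarized" (V > +floor) or "hyperpolarized"
    (V < -floor).  The floor suppresses numerically-quiet nodes.
    """
    profile = np.asarray(profile, dtype=float)
    if polarity == "depolarized":
        mask = profile > noise_floor
    elif polarity == "hyperpolarized":
        mask = profile < -noise_floor
    else:
        raise ValueError("polarity must be 'depolarized' or 'hyperpolarized'")
    best = cur = 0
    for hit in mask:
        cur = cur + 1 if hit else 0
        if cur > best:
            best = cur
    return best


@dataclass
class FiberOutcome:
    """Classification of one fibre's response to one pattern."""

    fiber: str
    activated: bool
    arrival_time: float
    peak_last_node: float
    peak_anywhere: float
    depol_run: int
    hyperpol_run: int
    mechanism: str

    def as_row(self) -> dict:
        return {
            "fibre": self.fiber,
            "activated": self.activated,
            "mechanism": self.mechanism,
            "arrival_time_s": self.arrival_time,
            "peak_last_node_mV": self.peak_last_node * 1e3,
            "peak_anywhere_mV": self.peak_anywhere * 1e3,
            "depol_run": self.depol_run,
            "hyperpol_run": self.hyperpol_run,
        }


def assess_fiber(
    result: CableSimResult,
    pattern: StimulationPattern,
    fiber: str = "",
    threshold: float = DEFAULT_AP_THRESHOLD,
    noise_floor: float = DEFAULT_NOISE_FLOOR,
    snapshot_delay: float = 1e-3,
) -> FiberOutcome:
    """Classify one fibre's simulated response and tag its mechanism.

    Run lengths are measured on the membrane snapshot ``snapshot_delay``
    after pulse onset (1 ms, the study's display time).  The mechanism tag
    for inhibited fibres uses the weak-response limit and the sign of the
    last electrode's current.
    """
    activated, arrival = detect_activation(result, threshold)
    onset = result.stimulus.get("pulse_onset_s", 0.0)
    snap = result.snapshot(onset + snapshot_delay)
    peak_any = float(result.v.max())
    if activated:
        mech = "activated"
    elif peak_any < WEAK_RESPONSE_LIMIT:
        mech = "no_significant_response"
    elif pattern.currents[-1] >= 0:
        mech = "anodic_inhibition"
    else:
        mech = "cathodic_block"
    return FiberOutcome(
        fiber=fiber,
        activated=activated,
        arrival_time=arrival,
        peak_last_node=float(result.last_node_trace().max()),
        peak_anywhere=peak_any,
        depol_run=consecutive_runs(snap, "depolarized", noise_floor),
        hyperpol_run=consecutive_runs(snap, "hyperpolarized", noise_floor),
        mechanism=mech,
    )


@dataclass
class OutcomeRecord:
    """Per-pattern record: both fibres' outcomes plus the pair-level label."""

    pattern_id: str
    outcomes: dict[str, FiberOutcome]
    label: str
    pattern: StimulationPattern | None = None

    def as_rows(self) -> list[dict]:
        rows = []
        for outcome in self.outcomes.values():
            row = {"pattern_id": self.pattern_id, "label": self.label}
            row.update(outcome.as_row())
            rows.append(row)
        return rows


def classify_selectivity(
    shallow: FiberOutcome,
    deep: FiberOutcome,
    pattern: StimulationPattern,
    pattern_id: str = "",
) -> OutcomeRecord:
    """Assign the pair-level selectivity label for a (shallow, deep) fibre pair.

    The labels partition all outcomes: both activated (non-selective),
    neither, or one selectively activated with the silent fibre's mechanism
    (weak stimulus / anodic inhibition / cathodic block) appended.
    """
    if shallow.activated and deep.activated:
        label = "non_selective"
    elif not shallow.activated and not deep.activated:
        label = "no_activation"
    else:
        winner = "shallow" if shallow.activated else "deep"
        silent = deep if shallow.activated else shallow
        suffix = {
            "no_significant_response": "weak",
            "anodic_inhibition": "anodic",
            "cathodic_block": "cathodic_block",
        }[silent.mechanism]
        label = f"selective_{winner}_{suffix}"
    return OutcomeRecord(
        pattern_id=pattern_id,
        outcomes={shallow.fiber or "shallow": shallow, deep.fiber or "deep": deep},
        label=label,
        pattern=pattern,
    )
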