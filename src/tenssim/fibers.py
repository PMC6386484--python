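"""Nerve fibre discretisation and 3-D trajectories through the finger.

A myelinated fibre is modelled as a chain of active compartments, each
representing a *group* of nodes of Ranvier (default: four), placed at equal
arc-length intervals ``dx_eff = grouping * dx_ranvier`` along a 3-D
trajectory.  Trajectories run from the receptor end (near the fingertip, or
at the shallow end of a perpendicular segment) towards the CNS; the last
model node is the CNS-ward end at which action-potential arrival is judged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import FingerGeometry

__all__ = [
    "FiberGeometry",
    "FiberTrajectory",
    "parallel_fiber",
    "perpendicular_fiber",
    "standard_fibers",
]


@dataclass(frozen=True)
class FiberGeometry:
    """Geometric/discretisation constants of one myelinated fibre."""

    diameter: float = 4e-6
    dx_ranvier: float = 78.461e-6
    nodal_length: float = 1.061e-6
    grouping: int = 4
    span: float = 0.03
    #: scale nodal membrane area by ``grouping`` (keeps membrane per unit
    #: fibre length invariant under grouping); if False a model node carries
    #: a single Ranvier node's membrane.
    group_membrane_area: bool = True
    #: membrane length governing the compartment capacitance: "nodal"
    #: charges the lumped active nodal membrane (the myelinated-fibre
    #: reading; default), "segment" charges the full segment length dx_eff
    #: as in an unmyelinated-cable compartment model (exploration only:
    #: the resulting fibre does not sustain saltatory propagation).
    capacitance_extent: str = "nodal"

    def __post_init__(self) -> None:
        if self.grouping < 1:
            raise ValueError("grouping must be >= 1")
        if self.capacitance_extent not in ("segment", "nodal"):
            raise ValueError("capacitance_extent must be 'segment' or 'nodal'")
        for name in ("diameter", "dx_ranvier", "nodal_length", "span"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def dx_eff(self) -> float:
        """Effective model-node spacing (m)."""
        return self.grouping * self.dx_ranvier

    @property
    def membrane_length(self) -> float:
        """Active membrane length lumped into one model node (m)."""
        return (self.grouping if self.group_membrane_area else 1) * self.nodal_length

    @property
    def membrane_area(self) -> float:
        """Active (conducting) membrane area of one model node (m^2)."""
        return math.pi * self.diameter * self.membrane_length

    @property
    def capacitance_area(self) -> float:
        """Membrane area charged by the compartment capacitance (m^2)."""
        length = self.dx_eff if self.capacitance_extent == "segment" else self.membrane_length
        return math.pi * self.diameter * length

    @property
    def n_nodes(self) -> int:
        """Model node count over the fibre span."""
        return int(math.floor(self.span / self.dx_eff)) + 1


@dataclass(frozen=True)
class FiberTrajectory:
    """Ordered model-node coordinates along a fibre.

    ``points`` is (n, 3) in metres; ``arc_length`` the cumulative arc length
    per node, starting at 0 at the receptor end.  ``tag`` describes the
    course ("parallel@<depth>" or "perpendicular").
    """

    points: np.ndarray
    arc_length: np.ndarray
    tag: str

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        arc = np.asarray(self.arc_length, dtype=float)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "arc_length", arc)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        if len(arc) != len(pts):
            raise ValueError("arc_length must match points")
        if np.any(np.diff(arc) <= 0):
            raise ValueError("arc length must be strictly increasing")

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    @property
    def spacing(self) -> float:
        return float(np.mean(np.diff(self.arc_length)))


def _resample_polyline(poly: np.ndarray, spacing: float, n_nodes: int,
                       tag: str) -> FiberTrajectory:
    """Place ``n_nodes`` points at equal arc-length ``spacing`` along a polyline."""
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s_nodes = spacing * np.arange(n_nodes)
    if s_nodes[-1] > s[-1] + 1e-12:
        raise ValueError(
            f"polyline of length {s[-1]:.4g} m too short for {n_nodes} nodes "
            f"at {spacing:.4g} m spacing"
        )
    pts = np.column_stack([np.interp(s_nodes, s, poly[:, i]) for i in range(3)])
    return FiberTrajectory(points=pts, arc_length=s_nodes, tag=tag)


def parallel_fiber(depth: float, finger: FingerGeometry | None = None,
                   fiber: FiberGeometry | None = None) -> FiberTrajectory:
    """Fibre running parallel to the skin at constant ``depth`` below the pad.

    The trajectory follows the pad midline (y = 0); near a spherical
    fingertip it curves with the skin surface, staying ``depth`` below it,
    so every node lies inside the tissue.
    """
    finger = finger or FingerGeometry()
    fiber = fiber or FiberGeometry()
    if depth <= 0 or depth >= finger.radius:
        raise ValueError(f"depth {depth} outside (0, finger radius)")
    # start where the local pad surface is deep enough for the fibre
    if finger.spherical_tip:
        h_min = depth + 2e-4
        if h_min >= finger.radius:
            raise ValueError("fibre too deep for the tip cap")
        x_start = finger.radius - math.sqrt(finger.radius**2 - h_min**2)
    else:
        x_start = 0.0
    x_dense = np.linspace(x_start, x_start + 1.2 * fiber.span, 4096)
    z_dense = finger.pad_surface_z(x_dense) + depth
    poly = np.column_stack([x_dense, np.zeros_like(x_dense), z_dense])
    return _resample_polyline(poly, fiber.dx_eff, fiber.n_nodes,
                              tag=f"parallel@{depth * 1e3:g}mm")


def perpendicular_fiber(x_origin: float, depth_from: float = 1e-3,
                        depth_to: float = 1.5e-3,
                        finger: FingerGeometry | None = None,
                        fiber: FiberGeometry | None = None) -> FiberTrajectory:
    """Fibre running perpendicular to the skin, then parallel towards the CNS.

    Starts at ``depth_from`` below the pad at ``x_origin`` (e.g. directly
    under an electrode), descends vertically to ``depth_to``, then turns
    CNS-ward at constant depth.
    """
    finger = finger or FingerGeometry()
    fiber = fiber or FiberGeometry()
    if not 0 < depth_from < depth_to < finger.radius:
        raise ValueError("need 0 < depth_from < depth_to < finger radius")
    z_surf = float(finger.pad_surface_z(np.asarray(x_origin)))
    x_dense = np.linspace(x_origin, x_origin + 1.2 * fiber.span, 4096)
    z_dense = finger.pad_surface_z(x_dense) + depth_to
    poly = np.vstack(
        [
            [x_origin, 0.0, z_surf + depth_from],
            np.column_stack([x_dense, np.zeros_like(x_dense), z_dense]),
        ]
    )
    return _resample_polyline(poly, fiber.dx_eff, fiber.n_nodes, tag="perpendicular")


def standard_fibers(finger: FingerGeometry | None = None,
                    fiber: FiberGeometry | None = None,
                    n2_origin: float | None = None) -> dict[str, FiberTrajectory]:
    """The three study fibres.

    * N1 - parallel at 1.5 mm depth (Merkel),
    * N2 - perpendicular from 1 to 1.5 mm depth under the fourth electrode,
      then parallel (Meissner); ``n2_origin`` overrides the bend position,
    * N3 - parallel at 2 mm depth (Pacinian).
    """
    from .geometry import ElectrodeArray

    finger = finger or FingerGeometry()
    fiber = fiber or FiberGeometry()
    if n2_origin is None:
        n2_origin = float(ElectrodeArray().centres[3])
    return {
        "N1": parallel_fiber(1.5e-3, finger, fiber),
        "N2": perpendicular_fiber(n2_origin, 1e-3, 1.5e-3, finger, fiber),
        "N3": parallel_fiber(2e-3, finger, fiber),
    }
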