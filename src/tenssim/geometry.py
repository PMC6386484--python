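"""Finger geometry, tissue conductivities and the stimulation electrode array.

Coordinate convention (SI metres internally, millimetres in reports):

* ``x``  distance from the fingertip along the finger axis,
* ``y``  lateral coordinate across the finger pad (0 on the midline),
* ``z``  vertical coordinate; the finger axis is at z = 0, the pad surface
  (where the electrode array sits) at z = -radius, the dorsal surface
  (fingernail, ground) at z = +radius.

"Depth" always means vertical distance below the pad skin surface on the
midline, i.e. a point at depth d sits at z = -radius + d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FingerGeometry", "TissueConductivities", "ElectrodeArray"]


@dataclass(frozen=True)
class FingerGeometry:
    """Idealised three-tissue finger: bone core, fat pulp, skin shell.

    A cylinder of ``finger_length`` capped (optionally) by a hemispherical
    fingertip whose radius equals the finger radius.
    """

    finger_diameter: float = 0.02
    bone_diameter: float = 0.005
    skin_thickness: float = 0.0009
    finger_length: float = 0.084
    spherical_tip: bool = True

    def __post_init__(self) -> None:
        for name in ("finger_diameter", "bone_diameter", "skin_thickness", "finger_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.bone_diameter + 2 * self.skin_thickness >= self.finger_diameter:
            raise ValueError(
                "bone plus skin does not fit inside the finger: "
                f"bone {self.bone_diameter} + 2*skin {self.skin_thickness} >= "
                f"diameter {self.finger_diameter}"
            )
        if self.spherical_tip and self.finger_length < self.finger_diameter / 2:
            raise ValueError("finger shorter than its own tip cap")

    @property
    def radius(self) -> float:
        return self.finger_diameter / 2

    @property
    def bone_radius(self) -> float:
        return self.bone_diameter / 2

    def pad_surface_z(self, x) -> np.ndarray:
        """z of the bottom (pad-side) skin surface on the midline (y = 0)."""
        x = np.asarray(x, dtype=float)
        r = self.radius
        if not self.spherical_tip:
            return np.full_like(x, -r)
        z = np.full_like(x, -r)
        cap = x < r
        dx = r - np.minimum(x, r)
        z[cap] = -np.sqrt(np.maximum(r**2 - dx[cap] ** 2, 0.0))
        return z

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: which (n, 3) points lie inside the tissue volume."""
        p = np.atleast_2d(points)
        x, y, z = p[:, 0], p[:, 1], p[:, 2]
        r = self.radius
        inside = (y**2 + z**2 <= r**2) & (x >= 0) & (x <= self.finger_length)
        if self.spherical_tip:
            cap = x < r
            inside[cap] = ((x[cap] - r) ** 2 + y[cap] ** 2 + z[cap] ** 2) <= r**2
        return inside


@dataclass(frozen=True)
class TissueConductivities:
    """Electrical conductivities of the three finger tissues, S/m (dry skin)."""

    sigma_skin: float = 0.0552
    sigma_fat: float = 0.0417
    sigma_bone: float = 0.0202

    def __post_init__(self) -> None:
        for name in ("sigma_skin", "sigma_fat", "sigma_bone"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def by_label(self) -> np.ndarray:
        """Conductivity lookup indexed by tissue label (1 skin, 2 fat, 3 bone)."""
        return np.array([np.nan, self.sigma_skin, self.sigma_fat, self.sigma_bone])


@dataclass(frozen=True)
class ElectrodeArray:
    """Linear array of rectangular surface electrodes in direct skin contact.

    Electrodes are ``electrode_width`` long along the finger axis and
    ``electrode_length`` across the pad, spaced ``pitch`` centre-to-centre.
    ``longitudinal_offset`` is the x-coordinate of the *centre* of the first
    electrode, measured from the fingertip.  The default places electrode 1
    at 7 mm so that the first two electrodes coincide with the two-electrode
    validation positions (7 and 9 mm).
    """

    n_electrodes: int = 8
    electrode_width: float = 0.001
    electrode_length: float = 0.0085
    pitch: float = 0.002
    longitudinal_offset: float = 0.007

    def __post_init__(self) -> None:
        if self.n_electrodes < 1:
            raise ValueError("need at least one electrode")
        if self.pitch - self.electrode_width <= 0:
            raise ValueError(
                f"electrodes overlap: pitch {self.pitch} <= width {self.electrode_width}"
            )
        for name in ("electrode_width", "electrode_length", "pitch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def centres(self) -> np.ndarray:
        """x-coordinates of the electrode centres (m)."""
        return self.longitudinal_offset + self.pitch * np.arange(self.n_electrodes)

    @property
    def gap(self) -> float:
        return self.pitch - self.electrode_width

    def footprint(self, k: int) -> tuple[float, float, float, float]:
        """(x0, x1, y0, y1) footprint of electrode ``k`` (0-based)."""
        c = self.centres[k]
        half_w = self.electrode_width / 2
        half_l = self.electrode_length / 2
        return (c - half_w, c + half_w, -half_l, half_l)

    def span(self) -> tuple[float, float]:
        """x-extent of the whole array footprint."""
        return (
            self.longitudinal_offset - self.electrode_width / 2,
            self.longitudinal_offset + self.pitch * (self.n_electrodes - 1)
            + self.electrode_width / 2,
        )
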