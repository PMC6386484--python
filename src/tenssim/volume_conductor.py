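"""Quasi-static volume-conductor model of the finger.

Solves the current-conduction problem div(sigma grad phi) = 0 on a
voxelised finger with unit current injected through each electrode patch
and returned through the grounded fingernail patch (Dirichlet phi = 0).
Because conduction is purely resistive the per-electrode unit-current
solutions form a basis: the field of any stimulation pattern is the
current-weighted superposition of the basis fields, and the time course of
the extracellular potential at a fibre node is profile x pulse(t).

Discretisation: regular structured grid, cell-centred finite volumes with a
7-point stencil and harmonic-mean face conductivities.  Electrodes are
uniform-current-density Neumann patches on the pad-side boundary faces;
the nail ground is a Dirichlet patch on the dorsal boundary faces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import bicgstab, spilu, splu, LinearOperator

from .geometry import ElectrodeArray, FingerGeometry, TissueConductivities
from .fibers import FiberTrajectory

__all__ = [
    "FingerModel",
    "BasisFieldSet",
    "Field3D",
    "ExtracellularProfile",
    "build_finger_model",
    "solve_basis_potentials",
    "superpose",
    "sample_along_fiber",
]

# tissue labels
AIR, SKIN, FAT, BONE = 0, 1, 2, 3


@dataclass(frozen=True)
class NailPatch:
    """Grounded fingernail patch on the dorsal surface: x-extent and width."""

    x_start: float = 0.002
    length: float = 0.010
    width: float = 0.008


@dataclass
class FingerModel:
    """Voxelised finger volume with electrode and ground boundary patches.

    ``labels`` is the (nx, ny, nz) tissue-label array (0 = outside);
    ``electrode_faces[k]`` lists flat cell indices whose pad-side boundary
    face belongs to electrode ``k``; ``ground_faces`` likewise for the nail.
    """

    geometry: FingerGeometry
    conductivities: TissueConductivities
    array: ElectrodeArray
    resolution: float
    labels: np.ndarray
    origin: np.ndarray
    nail: NailPatch
    electrode_faces: list[np.ndarray] = field(default_factory=list)
    ground_faces: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def active(self) -> np.ndarray:
        return self.labels > 0

    @property
    def n_active(self) -> int:
        return int(np.count_nonzero(self.labels))

    def cell_centers_1d(self):
        """Per-axis cell-centre coordinate vectors."""
        h = self.resolution
        return tuple(
            self.origin[i] + h * (np.arange(self.shape[i]) + 0.5) for i in range(3)
        )

    def tissue_volume(self, label: int) -> float:
        """Total volume (m^3) of cells carrying ``label``."""
        return float(np.count_nonzero(self.labels == label)) * self.resolution**3


def build_finger_model(
    geometry: FingerGeometry | None = None,
    conductivities: TissueConductivities | None = None,
    array: ElectrodeArray | None = None,
    resolution: float = 0.3e-3,
    nail: NailPatch | None = None,
) -> FingerModel:
    """Voxelise the finger and attach electrode and ground boundary patches.

    ``resolution`` (m) must not exceed the skin thickness so the skin layer
    is resolved by at least one cell.
    """
    geometry = geometry or FingerGeometry()
    conductivities = conductivities or TissueConductivities()
    array = array or ElectrodeArray()
    nail = nail or NailPatch()

    if resolution > geometry.skin_thickness:
        raise ValueError(
            f"resolution {resolution} m too coarse to resolve the "
            f"{geometry.skin_thickness} m skin layer"
        )
    x0_arr, x1_arr = array.span()
    if x0_arr < 0 or x1_arr > geometry.finger_length:
        raise ValueError("electrode array footprint extends beyond the finger pad")
    if array.electrode_length > geometry.finger_diameter:
        raise ValueError("electrodes wider than the finger pad")

    h = resolution
    r = geometry.radius
    nx = int(math.ceil(geometry.finger_length / h))
    nyz = int(math.ceil(geometry.finger_diameter / h))
    origin = np.array([0.0, -nyz * h / 2, -nyz * h / 2])
    xs = origin[0] + h * (np.arange(nx) + 0.5)
    ys = origin[1] + h * (np.arange(nyz) + 0.5)
    zs = origin[2] + h * (np.arange(nyz) + 0.5)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")

    r_cyl = np.sqrt(Y**2 + Z**2)
    if geometry.spherical_tip:
        cap = X < r
        r_tip = np.sqrt((X - r) ** 2 + Y**2 + Z**2)
        r_surf = np.where(cap, r_tip, r_cyl)
    else:
        r_surf = r_cyl
    inside = r_surf <= r

    labels = np.zeros((nx, nyz, nyz), dtype=np.int8)
    labels[inside] = FAT
    labels[inside & (r_surf >= r - geometry.skin_thickness)] = SKIN
    bone_region = inside & (r_cyl <= geometry.bone_radius)
    if geometry.spherical_tip:
        bone_region &= X >= r
    labels[bone_region] = BONE

    model = FingerModel(
        geometry=geometry,
        conductivities=conductivities,
        array=array,
        resolution=h,
        labels=labels,
        origin=origin,
        nail=nail,
    )

    # --- electrode patches: pad-side (minimum z) boundary faces ----------
    active = labels > 0
    # index of the lowest active cell in each (ix, iy) column; -1 if none
    any_active = active.any(axis=2)
    lowest = np.where(any_active, np.argmax(active, axis=2), -1)
    flat = np.arange(labels.size).reshape(labels.shape)
    for k in range(array.n_electrodes):
        ex0, ex1, ey0, ey1 = array.footprint(k)
        cols = (
            (xs[:, None] >= ex0) & (xs[:, None] <= ex1)
            & (ys[None, :] >= ey0) & (ys[None, :] <= ey1)
            & any_active
        )
        ii, jj = np.nonzero(cols)
        if len(ii) == 0:
            raise ValueError(f"electrode {k + 1} footprint contains no surface cells")
        model.electrode_faces.append(flat[ii, jj, lowest[ii, jj]])

    # --- ground patch: dorsal (maximum z) boundary faces ------------------
    highest = np.where(any_active, nyz - 1 - np.argmax(active[:, :, ::-1], axis=2), -1)
    gx0, gx1 = nail.x_start, nail.x_start + nail.length
    gy = nail.width / 2
    cols = (
        (xs[:, None] >= gx0) & (xs[:, None] <= gx1)
        & (ys[None, :] >= -gy) & (ys[None, :] <= gy)
        & any_active
    )
    ii, jj = np.nonzero(cols)
    if len(ii) == 0:
        raise ValueError("nail ground patch contains no surface cells")
    model.ground_faces = flat[ii, jj, highest[ii, jj]]

    overlap = set()
    for faces in model.electrode_faces:
        fs = set(faces.tolist())
        if fs & overlap:
            raise ValueError("electrode patches overlap")
        overlap |= fs
    if overlap & set(model.ground_faces.tolist()):
        raise ValueError("ground patch overlaps an electrode patch")
    return model


@dataclass
class Field3D:
    """Scalar potential on the model grid (V), NaN outside the tissue."""

    values: np.ndarray
    model: FingerModel

    def interpolator(self):
        """Trilinear interpolator over the grid, inactive cells filled by
        nearest active neighbour so near-surface fibre nodes interpolate
        cleanly."""
        from scipy.interpolate import RegularGridInterpolator
        from scipy.ndimage import distance_transform_edt

        vals = self.values
        if np.any(~np.isfinite(vals)):
            filled = vals.copy()
            invalid = ~np.isfinite(vals)
            idx = distance_transform_edt(invalid, return_distances=False,
                                         return_indices=True)
            filled = vals[tuple(idx)]
        else:
            filled = vals
        return RegularGridInterpolator(
            self.model.cell_centers_1d(), filled, method="linear",
            bounds_error=False, fill_value=None,
        )


@dataclass
class BasisFieldSet:
    """Per-electrode unit-current (1 A) potential solutions plus solver metadata.

    Linear in the injected currents: the field of a pattern ``I`` is
    ``sum_k I_k phi_k``; every basis field is zero on the ground patch.
    """

    model: FingerModel
    fields: np.ndarray  # (n_electrodes, nx, ny, nz), NaN outside tissue
    meta: dict = field(default_factory=dict)

    @property
    def n_electrodes(self) -> int:
        return self.fields.shape[0]

    def combine(self, currents) -> Field3D:
        return superpose(self, currents)

    def sampling_matrix(self, trajectory: FiberTrajectory) -> np.ndarray:
        """(n_nodes, n_electrodes) matrix S with S @ I the fibre profile.

        Precomputing S makes the per-pattern field cost a single small
        matrix-vector product.
        """
        cols = []
        for k in range(self.n_electrodes):
            f = Field3D(self.fields[k], self.model)
            cols.append(_sample_points(f, trajectory))
        return np.column_stack(cols)


def _assemble(model: FingerModel):
    """Finite-volume system matrix (SPD) and index maps for active cells."""
    labels = model.labels
    h = model.resolution
    sigma_lut = model.conductivities.by_label()
    sigma = np.zeros(labels.shape)
    act = labels > 0
    sigma[act] = sigma_lut[labels[act]]

    index = -np.ones(labels.shape, dtype=np.int64)
    index[act] = np.arange(np.count_nonzero(act))
    n = int(np.count_nonzero(act))

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        sa, sb = sigma[tuple(sl_a)], sigma[tuple(sl_b)]
        both = act[tuple(sl_a)] & act[tuple(sl_b)]
        # harmonic mean face conductivity, face conductance g = sigma_f * h
        g = np.zeros_like(sa)
        g[both] = 2.0 * sa[both] * sb[both] / (sa[both] + sb[both]) * h
        ia = index[tuple(sl_a)][both]
        ib = index[tuple(sl_b)][both]
        gb = g[both]
        rows.append(ia)
        cols.append(ib)
        vals.append(-gb)
        rows.append(ib)
        cols.append(ia)
        vals.append(-gb)
        np.add.at(diag, ia, gb)
        np.add.at(diag, ib, gb)

    # Dirichlet ground faces: half-cell conductance to phi = 0
    flat_sigma = sigma.ravel()
    g_idx = index.ravel()[model.ground_faces]
    g_cond = flat_sigma[model.ground_faces] * h * 2.0
    np.add.at(diag, g_idx, g_cond)

    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    a = sparse.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return a, index, g_idx, g_cond


def solve_basis_potentials(
    model: FingerModel,
    tolerance: float = 1e-12,
    method: str = "direct",
    max_iter: int = 50_000,
) -> BasisFieldSet:
    """Solve for each electrode's unit-current potential field.

    ``method="direct"`` factorises the conduction matrix once (sparse LU)
    and back-substitutes the eight unit-current right-hand sides, which is
    deterministic and accurate to machine precision.  ``method="bicgstab"``
    runs ILU-preconditioned BiCGStab to relative residual ``tolerance``.
    Either way discrete current conservation is verified: the net current
    leaving through the grounded nail must equal the injected 1 A.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    a, index, g_idx, g_cond = _assemble(model)
    n = a.shape[0]

    rhs = np.zeros((model.array.n_electrodes, n))
    for k, faces in enumerate(model.electrode_faces):
        cells = index.ravel()[faces]
        rhs[k, cells] = 1.0 / len(faces)

    meta = {"method": method, "n_unknowns": n, "iterations": [], "residuals": []}
    sols = np.empty_like(rhs)
    if method == "direct":
        lu = splu(a)
        for k in range(rhs.shape[0]):
            sols[k] = lu.solve(rhs[k])
            meta["iterations"].append(0)
            meta["residuals"].append(
                float(np.linalg.norm(a @ sols[k] - rhs[k]) / np.linalg.norm(rhs[k]))
            )
    elif method == "bicgstab":
        ilu = spilu(a, drop_tol=1e-5, fill_factor=20)
        pre = LinearOperator(a.shape, ilu.solve)
        for k in range(rhs.shape[0]):
            iters = 0

            def count(_xk):
                nonlocal iters
                iters += 1

            x, info = bicgstab(a, rhs[k], rtol=tolerance, atol=0.0,
                               maxiter=max_iter, M=pre, callback=count)
            resid = float(np.linalg.norm(a @ x - rhs[k]) / np.linalg.norm(rhs[k]))
            if info != 0:
                raise RuntimeError(
                    f"BiCGStab failed for electrode {k + 1} (info={info}, "
                    f"iterations={iters}, relative residual={resid:.3e})"
                )
            sols[k] = x
            meta["iterations"].append(iters)
            meta["residuals"].append(resid)
    else:
        raise ValueError(f"unknown solver method {method!r}")

    # discrete current conservation through the ground patch
    ground_flux = []
    for k in range(rhs.shape[0]):
        flux = float(np.sum(g_cond * sols[k][g_idx]))
        ground_flux.append(flux)
        if abs(flux - 1.0) > max(10 * tolerance, 1e-8):
            raise RuntimeError(
                f"current conservation violated for electrode {k + 1}: "
                f"ground flux {flux:.6e} A for 1 A injected"
            )
    meta["ground_flux_A"] = ground_flux

    fields = np.full((rhs.shape[0],) + model.shape, np.nan)
    act = model.active
    for k in range(rhs.shape[0]):
        f = np.full(model.shape, np.nan)
        f[act] = sols[k]
        fields[k] = f
    return BasisFieldSet(model=model, fields=fields, meta=meta)


def superpose(basis: BasisFieldSet, currents) -> Field3D:
    """Field of a stimulation pattern: sum_k I_k phi_k (currents in A)."""
    currents = np.asarray(currents, dtype=float)
    if currents.shape != (basis.n_electrodes,):
        raise ValueError(
            f"expected {basis.n_electrodes} electrode currents, got {currents.shape}"
        )
    from .stimulation import CURRENT_BOUND

    over = np.abs(currents) > CURRENT_BOUND * (1 + 1e-12)
    if np.any(over):
        k = int(np.argmax(over))
        raise ValueError(
            f"electrode {k + 1} current {currents[k] * 1e3:.3f} mA outside the "
            f"+/-{CURRENT_BOUND * 1e3:g} mA safety range"
        )
    values = np.tensordot(currents, basis.fields, axes=1)
    return Field3D(values=values, model=basis.model)


@dataclass(frozen=True)
class ExtracellularProfile:
    """Extracellular potential (V) at each fibre node for one pattern.

    The full space-time drive is ``v_e[node] * pulse(t)``.
    """

    v_e: np.ndarray
    arc_length: np.ndarray
    fiber_tag: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "v_e", np.asarray(self.v_e, dtype=float))
        object.__setattr__(self, "arc_length", np.asarray(self.arc_length, dtype=float))
        if self.v_e.shape != self.arc_length.shape:
            raise ValueError("v_e and arc_length must have matching length")

    def __len__(self) -> int:
        return len(self.v_e)


def _sample_points(f: Field3D, trajectory: FiberTrajectory) -> np.ndarray:
    inside = f.model.geometry.contains(trajectory.points)
    if not np.all(inside):
        bad = int(np.argmin(inside))
        raise ValueError(
            f"fibre node {bad} at {trajectory.points[bad]} lies outside the finger volume"
        )
    return f.interpolator()(trajectory.points)


def sample_along_fiber(f: Field3D, trajectory: FiberTrajectory) -> ExtracellularProfile:
    """Trilinearly interpolate the field at the fibre nodes, in arc-length order."""
    return ExtracellularProfile(
        v_e=_sample_points(f, trajectory),
        arc_length=trajectory.arc_length.copy(),
        fiber_tag=trajectory.tag,
    )
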