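"""Export helpers: HDF5 basis-field container and CSV profile/trace tables."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .volume_conductor import BasisFieldSet, ExtracellularProfile, FingerModel

__all__ = ["save_basis", "load_basis_fields", "profile_to_csv", "trace_to_csv"]


def save_basis(basis: BasisFieldSet, path) -> None:
    """Write the basis fields and grid description to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("fields", data=basis.fields, compression="gzip")
        f.create_dataset("labels", data=basis.model.labels, compression="gzip")
        f.attrs["resolution_m"] = basis.model.resolution
        f.attrs["origin_m"] = basis.model.origin
        f.attrs["n_electrodes"] = basis.n_electrodes
        f.attrs["meta_json"] = json.dumps(basis.meta)


def load_basis_fields(path):
    """Read back the raw field array and grid attributes (fields, attrs)."""
    with h5py.File(path, "r") as f:
        fields = f["fields"][...]
        attrs = dict(f.attrs)
    if "meta_json" in attrs:
        attrs["meta"] = json.loads(attrs.pop("meta_json"))
    return fields, attrs


def profile_to_csv(profile: ExtracellularProfile, path) -> None:
    """CSV of (arc-length mm, extracellular potential V) per fibre node."""
    pd.DataFrame(
        {"arc_length_mm": profile.arc_length * 1e3, "v_e_V": profile.v_e}
    ).to_csv(path, index=False)


def trace_to_csv(result, path, snapshot_time: float | None = None) -> None:
    """Long-format CSV of a cable simulation, or a single time snapshot."""
    if snapshot_time is None:
        result.to_frame().to_csv(path, index=False)
    else:
        snap = result.snapshot(snapshot_time)
        pd.DataFrame(
            {
                "arc_length_mm": result.arc_length * 1e3,
                "time_s": snapshot_time,
                "v_mV": snap * 1e3,
            }
        ).to_csv(path, index=False)
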