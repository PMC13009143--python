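"""File formats: HDF5 containers, TIFF/CSV interchange, YAML configs.

HDF5 is the canonical container (multi-array + attributes); the moment
video's power map can additionally be exported as multi-page TIFF, and
biomarker tables travel as CSV. Write-then-read is the identity for all
data and declared attributes; missing required attributes raise
:class:`~retiflow.errors.SchemaError` naming the field.
"""

from __future__ import annotations

import numpy as np

import h5py
import pandas as pd
import tifffile
import yaml

from .containers import ArterialMap, CrossSection, FrameStack, MomentVideo
from .errors import SchemaError

__all__ = [
    "write_stack", "read_stack", "write_moments", "read_moments",
    "write_map", "read_map", "write_m0_tiff", "read_m0_tiff",
    "append_biomarkers", "load_config",
]


def _require_attrs(group, names, path):
    for name in names:
        if name not in group.attrs:
            raise SchemaError(f"{path}: missing required attribute {name!r}")


def write_stack(path, stack: FrameStack):
    with h5py.File(path, "w") as f:
        d = f.create_dataset("frames", data=stack.frames)
        d.attrs["frame_rate_hz"] = stack.frame_rate_hz
        d.attrs["pixel_size_um"] = stack.pixel_size_um
        d.attrs["wavelength_nm"] = stack.wavelength_nm


def read_stack(path) -> FrameStack:
    with h5py.File(path, "r") as f:
        if "frames" not in f:
            raise SchemaError(f"{path}: missing dataset 'frames'")
        d = f["frames"]
        _require_attrs(d, ["frame_rate_hz", "pixel_size_um"], path)
        return FrameStack(d[()], float(d.attrs["frame_rate_hz"]),
                          float(d.attrs["pixel_size_um"]),
                          float(d.attrs.get("wavelength_nm", 852.0)))


def write_moments(path, video: MomentVideo, provenance: dict | None = None):
    with h5py.File(path, "w") as f:
        f.create_dataset("m0", data=video.m0)
        f.create_dataset("m2", data=video.m2)
        f.create_dataset("window_times_s", data=video.window_times_s)
        for k, v in dict(frame_rate_hz=video.frame_rate_hz,
                         pixel_size_um=video.pixel_size_um,
                         window_length=video.window_length, hop=video.hop,
                         band_lo_hz=video.band_lo_hz,
                         band_hi_hz=video.band_hi_hz).items():
            f.attrs[k] = v
        for k, v in (provenance or {}).items():
            f.attrs[f"provenance_{k}"] = v


def read_moments(path) -> MomentVideo:
    with h5py.File(path, "r") as f:
        for name in ("m0", "m2"):
            if name not in f:
                raise SchemaError(f"{path}: missing dataset {name!r}")
        _require_attrs(f, ["frame_rate_hz", "pixel_size_um", "band_lo_hz",
                           "band_hi_hz"], path)
        return MomentVideo(
            m0=f["m0"][()], m2=f["m2"][()],
            frame_rate_hz=float(f.attrs["frame_rate_hz"]),
            pixel_size_um=float(f.attrs["pixel_size_um"]),
            window_length=int(f.attrs.get("window_length", 512)),
            hop=int(f.attrs.get("hop", 512)),
            band_lo_hz=float(f.attrs["band_lo_hz"]),
            band_hi_hz=float(f.attrs["band_hi_hz"]),
            window_times_s=(f["window_times_s"][()]
                            if "window_times_s" in f else None))


def write_map(path, amap: ArterialMap):
    with h5py.File(path, "w") as f:
        f.create_dataset("artery_mask", data=amap.artery_mask.astype(np.uint8))
        f.create_dataset("background_mask",
                         data=amap.background_mask.astype(np.uint8))
        f.create_dataset("branch_labels", data=amap.branch_labels)
        if amap.vessel_mask is not None:
            f.create_dataset("vessel_mask",
                             data=amap.vessel_mask.astype(np.uint8))
        f.attrs["disc_center"] = list(amap.disc_center)
        f.attrs["disc_diameter_px"] = amap.disc_diameter_px
        if amap.sections:
            rows = [[s.branch_id, s.center[0], s.center[1], s.direction[0],
                     s.direction[1], s.half_length] for s in amap.sections]
            f.create_dataset("sections", data=np.asarray(rows, dtype=float))


def read_map(path) -> ArterialMap:
    with h5py.File(path, "r") as f:
        for name in ("artery_mask", "background_mask", "branch_labels"):
            if name not in f:
                raise SchemaError(f"{path}: missing dataset {name!r}")
        _require_attrs(f, ["disc_center", "disc_diameter_px"], path)
        amap = ArterialMap(
            artery_mask=f["artery_mask"][()].astype(bool),
            background_mask=f["background_mask"][()].astype(bool),
            branch_labels=f["branch_labels"][()],
            disc_center=tuple(f.attrs["disc_center"]),
            disc_diameter_px=float(f.attrs["disc_diameter_px"]),
            vessel_mask=(f["vessel_mask"][()].astype(bool)
                         if "vessel_mask" in f else None))
        if "sections" in f:
            for row in f["sections"][()]:
                amap.sections.append(CrossSection(
                    branch_id=int(row[0]), center=(row[1], row[2]),
                    direction=(row[3], row[4]), half_length=int(row[5])))
        return amap


def write_m0_tiff(path, video: MomentVideo):
    """Export the in-band power maps as a multi-page 16-bit TIFF."""
    m0 = video.m0
    peak = m0.max()
    scaled = (m0 / peak * 65535).astype(np.uint16) if peak > 0 \
        else np.zeros_like(m0, dtype=np.uint16)
    tifffile.imwrite(path, np.moveaxis(scaled, -1, 0))


def read_m0_tiff(path) -> np.ndarray:
    return np.moveaxis(tifffile.imread(path), 0, -1)


def append_biomarkers(path, row: dict):
    """Append one measurement row to a biomarker CSV (header on create)."""
    df = pd.DataFrame([row])
    try:
        existing = pd.read_csv(path)
        df = pd.concat([existing, df], ignore_index=True)
    except (FileNotFoundError, pd.errors.EmptyDataError):
        pass
    df.to_csv(path, index=False)


def load_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return cfg
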