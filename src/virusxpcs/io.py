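"""HDF5 containers and text configs.

Simulated and recorded data share one event-container layout (datasets
``frame_index``/``pixel_index``/``count`` plus shape and rate
attributes), so the correlator cannot tell them apart.  Analysis results
go into a single results container, one group per stage, each carrying
the seed and a config echo for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .correlator import G2Result
from .geometry import DetectorGeometry
from .simulate import PhotonEvents

__all__ = [
    "write_events",
    "read_events",
    "write_mask",
    "read_mask",
    "load_geometry",
    "save_geometry",
    "write_g2_result",
    "read_g2_result",
]


def write_events(path, events: PhotonEvents, seed: int | None = None,
                 config_echo: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("frame_index", data=events.frame_index, dtype="u4")
        f.create_dataset("pixel_index", data=events.pixel_index, dtype="u4")
        f.create_dataset("count", data=events.count, dtype="u2")
        if events.q_per_pixel is not None:
            f.create_dataset("q_per_pixel", data=events.q_per_pixel)
        f.attrs["n_frames"] = events.n_frames
        f.attrs["n_pixels"] = events.n_pixels
        f.attrs["frame_rate_hz"] = events.frame_rate
        if seed is not None:
            f.attrs["seed"] = seed
        if config_echo is not None:
            f.attrs["config_echo"] = json.dumps(config_echo, default=str)


def read_events(path) -> PhotonEvents:
    with h5py.File(path, "r") as f:
        return PhotonEvents(
            frame_index=f["frame_index"][:],
            pixel_index=f["pixel_index"][:],
            count=f["count"][:],
            n_frames=int(f.attrs["n_frames"]),
            n_pixels=int(f.attrs["n_pixels"]),
            frame_rate=float(f.attrs["frame_rate_hz"]),
            q_per_pixel=f["q_per_pixel"][:] if "q_per_pixel" in f else None,
        )


def write_mask(path, mask: np.ndarray) -> None:
    """Mask as an unsigned-8-bit dataset named "mask"; nonzero = usable."""
    with h5py.File(path, "a") as f:
        if "mask" in f:
            del f["mask"]
        f.create_dataset("mask", data=np.asarray(mask, dtype=np.uint8))


def read_mask(path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f["mask"][:].astype(bool)


def load_geometry(path) -> DetectorGeometry:
    """Geometry from a YAML block with keys pixel_pitch_um, distance_m,
    energy_keV, beam_center, frame_rate_hz, shape."""
    cfg = yaml.safe_load(Path(path).read_text())
    return geometry_from_dict(cfg)


def geometry_from_dict(cfg: dict) -> DetectorGeometry:
    return DetectorGeometry(
        pixel_pitch=float(cfg["pixel_pitch_um"]),
        distance=float(cfg["distance_m"]),
        photon_energy=float(cfg["energy_keV"]),
        beam_center=tuple(float(x) for x in cfg["beam_center"]),
        frame_rate=float(cfg["frame_rate_hz"]),
        shape=tuple(int(x) for x in cfg["shape"]),
    )


def save_geometry(path, geom: DetectorGeometry) -> None:
    cfg = {
        "pixel_pitch_um": geom.pixel_pitch,
        "distance_m": geom.distance,
        "energy_keV": geom.photon_energy,
        "beam_center": list(geom.beam_center),
        "frame_rate_hz": geom.frame_rate,
        "shape": list(geom.shape),
    }
    Path(path).write_text(yaml.safe_dump(cfg))


def write_g2_result(path, result: G2Result, group: str = "g2",
                    attrs: dict | None = None) -> None:
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("q_coarse", data=result.q)
        g.create_dataset("delays_s", data=result.delays)
        g.create_dataset("g2", data=result.g2)
        g.create_dataset("sigma_g2", data=result.sigma_g2)
        g.create_dataset("n_pixels", data=result.n_pixels)
        g.create_dataset("q_fine", data=result.q_fine)
        g.create_dataset("g2_fine", data=result.g2_fine)
        g.attrs["frame_rate_hz"] = result.frame_rate
        if result.beta_used is not None:
            g.attrs["beta_used"] = result.beta_used
        for k, v in (attrs or {}).items():
            g.attrs[k] = v


def read_g2_result(path, group: str = "g2") -> G2Result:
    with h5py.File(path, "r") as f:
        g = f[group]
        return G2Result(
            q=g["q_coarse"][:],
            delays=g["delays_s"][:],
            g2=g["g2"][:],
            sigma_g2=g["sigma_g2"][:],
            n_pixels=g["n_pixels"][:],
            q_fine=g["q_fine"][:],
            g2_fine=g["g2_fine"][:],
            beta_used=float(g.attrs["beta_used"]) if "beta_used" in g.attrs else None,
            frame_rate=float(g.attrs.get("frame_rate_hz", 0.0)),
        )
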