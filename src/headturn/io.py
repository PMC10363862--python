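"""File interfaces: BRIR WAV export/import and scene configuration files.

Scene configs are YAML (JSON also parses) with keys ``dims``, ``absorption``
(band center Hz -> alpha), ``listener``, ``sources`` (each azimuth_deg /
distance_m / level_db_spl), optional ``scattering``; angles in degrees,
distances in meters, azimuth 0 = facing direction, positive clockwise from
above.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from scipy.io import wavfile

from .room import ImpulseResponsePair, RoomScene, SourcePlacement

__all__ = ["save_brir", "load_brir", "scene_to_dict", "scene_from_dict",
           "save_scene", "load_scene"]


def save_brir(path, brir: ImpulseResponsePair) -> None:
    """Write a BRIR as 2-channel float32 WAV (sample rate in the header)."""
    data = np.stack([brir.left, brir.right], axis=1).astype(np.float32)
    wavfile.write(str(path), int(brir.sample_rate), data)


def load_brir(path) -> ImpulseResponsePair:
    fs, data = wavfile.read(str(path))
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("expected a 2-channel WAV")
    return ImpulseResponsePair(data[:, 0].astype(float), data[:, 1].astype(float), float(fs))


def scene_to_dict(scene: RoomScene) -> dict:
    return {
        "dims": list(scene.dims),
        "absorption": {float(k): float(v) for k, v in scene.band_absorption.items()},
        "listener": list(scene.listener_position),
        "scattering": scene.scattering,
        "sources": [
            {"azimuth_deg": s.azimuth_deg, "distance_m": s.distance_m,
             "level_db_spl": s.level_db_spl}
            for s in scene.sources
        ],
    }


def scene_from_dict(data: dict) -> RoomScene:
    return RoomScene(
        dims=tuple(data["dims"]),
        band_absorption={float(k): float(v) for k, v in data["absorption"].items()},
        listener_position=tuple(data["listener"]),
        sources=[
            SourcePlacement(s["azimuth_deg"], s["distance_m"],
                            s.get("level_db_spl", 60.0))
            for s in data.get("sources", [])
        ],
        scattering=float(data.get("scattering", 0.3)),
    )


def save_scene(path, scene: RoomScene) -> None:
    Path(path).write_text(yaml.safe_dump(scene_to_dict(scene), sort_keys=False))


def load_scene(path) -> RoomScene:
    return scene_from_dict(yaml.safe_load(Path(path).read_text()))
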