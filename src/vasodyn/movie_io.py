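"""Movies, networks and tables on disk.

Movies are multi-page TIFFs (one page per frame) with a JSON sidecar holding
the channel, frame period, pixel size and, for synthetic data, the generative
parameters.  Networks are JSON polylines; trial and behavior tables are CSV
with a header row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .geometry import Segment, VesselNetwork


@dataclass
class Movie:
    """A time x y x x intensity grid with acquisition metadata."""
    frames: np.ndarray              # (T, H, W), arbitrary units >= 0
    channel: str                    # "gcamp" | "ios"
    frame_period: float             # s
    pixel_size: float               # µm / pixel
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or min(self.frames.shape) < 1:
            raise ValueError("frames must be a non-empty (T, H, W) array")
        if self.frame_period <= 0 or self.pixel_size <= 0:
            raise ValueError("frame period and pixel size must be positive")
        if self.channel not in ("gcamp", "ios"):
            raise ValueError("channel must be 'gcamp' or 'ios'")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_period


def write_movie(movie: Movie, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(movie.frames, dtype=np.float32))
    sidecar = {
        "channel": movie.channel,
        "frame_period": movie.frame_period,
        "pixel_size": movie.pixel_size,
        "meta": movie.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_movie(path: str | Path) -> Movie:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return Movie(frames=frames, channel=sidecar["channel"],
                 frame_period=sidecar["frame_period"],
                 pixel_size=sidecar["pixel_size"],
                 meta=sidecar.get("meta", {}))


def write_network(network: VesselNetwork, path: str | Path) -> None:
    payload = {
        "source": list(network.source),
        "field_size": list(network.field_size),
        "segments": [
            {
                "points": np.asarray(s.points).tolist(),
                "d0": s.d0,
                "cls": s.cls,
                "parent": s.parent,
                "attach_arc": s.attach_arc,
            }
            for s in network.segments
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_network(path: str | Path) -> VesselNetwork:
    payload = json.loads(Path(path).read_text())
    segments = [
        Segment(points=np.asarray(s["points"], dtype=float), d0=s["d0"],
                cls=s.get("cls", "artery"), parent=s.get("parent"),
                attach_arc=s.get("attach_arc", 0.0))
        for s in payload["segments"]
    ]
    return VesselNetwork(segments=segments, source=tuple(payload["source"]),
                         field_size=tuple(payload["field_size"]))
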