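"""Planar vessel-network geometry.

Coordinates are (x, y) in micrometres, origin at the top-left of the imaging
field, y increasing downward.  Pixel centres sit at integer+0.5 pixel
coordinates.  Distances are Euclidean unless explicitly traced along the
vasculature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def polyline_arclength(points: np.ndarray) -> np.ndarray:
    """Cumulative arc length (µm) at each vertex of an (N, 2) polyline."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2 or points.shape[1] != 2:
        raise ValueError("polyline must be an (N>=2, 2) array")
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(points: np.ndarray, arc_positions: np.ndarray) -> np.ndarray:
    """Positions on the polyline at the requested arc distances (µm)."""
    points = np.asarray(points, dtype=float)
    s = polyline_arclength(points)
    arc = np.asarray(arc_positions, dtype=float)
    if np.any(arc < -1e-9) or np.any(arc > s[-1] + 1e-9):
        raise ValueError("arc position outside polyline")
    x = np.interp(arc, s, points[:, 0])
    y = np.interp(arc, s, points[:, 1])
    return np.column_stack([x, y])


def polyline_tangents(points: np.ndarray, arc_positions: np.ndarray,
                      h: float = 1.0) -> np.ndarray:
    """Unit tangents at arc positions via centred finite differences.

    The step is clipped at the polyline ends, where one-sided differences
    are used instead.
    """
    s = polyline_arclength(points)
    total = s[-1]
    arc = np.asarray(arc_positions, dtype=float)
    lo = np.clip(arc - h, 0.0, total)
    hi = np.clip(arc + h, 0.0, total)
    p_lo = resample_polyline(points, lo)
    p_hi = resample_polyline(points, hi)
    d = p_hi - p_lo
    norm = np.linalg.norm(d, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return d / norm


@dataclass
class Segment:
    """One vessel segment: a polyline with a class and a baseline diameter."""
    points: np.ndarray              # (N, 2) µm
    d0: float                       # baseline diameter, µm
    cls: str = "artery"             # artery | vein | capillary
    parent: int | None = None       # index of parent segment, None = root
    attach_arc: float = 0.0         # arc distance on parent where this starts

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.d0 <= 0:
            raise ValueError("baseline diameter must be positive")
        if self.cls not in ("artery", "vein", "capillary"):
            raise ValueError(f"unknown vessel class {self.cls!r}")

    @property
    def length(self) -> float:
        return float(polyline_arclength(self.points)[-1])


@dataclass
class VesselNetwork:
    """Planar vascular network: a tree of polyline segments rooted at the
    activity/stimulation source point."""
    segments: list[Segment]
    source: tuple[float, float]
    field_size: tuple[float, float] = (2000.0, 2000.0)   # (width, height) µm
    _root_offsets: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._root_offsets = self._path_offsets()

    def _path_offsets(self) -> np.ndarray:
        """(root_src_arc, start_distance) bookkeeping.

        For the root segment the source lies on the polyline at arc position
        src_arc (found by projection); for every other segment the start
        distance is the path distance of its attachment point on the parent.
        Returns an array where entry i is the path distance from the source
        to the start of segment i (the root stores -src_arc as a sentinel so
        distances within it fold around the source).
        """
        offs = np.full(len(self.segments), np.nan)
        root_idx = None
        for i, seg in enumerate(self.segments):
            if seg.parent is None:
                if root_idx is not None:
                    raise ValueError("network must have a single root segment")
                root_idx = i
                s = polyline_arclength(seg.points)
                grid = np.linspace(0, s[-1], 2048)
                dense = resample_polyline(seg.points, grid)
                j = int(np.argmin(np.linalg.norm(dense - np.asarray(self.source), axis=1)))
                offs[i] = -grid[j]
        if root_idx is None:
            raise ValueError("network has no root segment")
        changed = True
        while changed:
            changed = False
            for i, seg in enumerate(self.segments):
                if np.isnan(offs[i]) and seg.parent is not None and not np.isnan(offs[seg.parent]):
                    offs[i] = self._distance_on(seg.parent, seg.attach_arc, offs)
                    changed = True
        if np.any(np.isnan(offs)):
            raise ValueError("network contains segments unreachable from the source")
        return offs

    def _distance_on(self, seg_index: int, arc, offs: np.ndarray):
        seg = self.segments[seg_index]
        arc = np.asarray(arc, dtype=float)
        if seg.parent is None:
            return np.abs(arc + offs[seg_index])
        return offs[seg_index] + arc

    def path_distance(self, seg_index: int, arc: np.ndarray | float) -> np.ndarray:
        """Path distance (µm) from the source, traced along the vasculature,
        for points at the given within-segment arc positions."""
        return self._distance_on(seg_index, arc, self._root_offsets)

    def connected_to_source(self) -> bool:
        try:
            self._path_offsets()
            return True
        except ValueError:
            return False


def make_network(config: dict, seed: int) -> VesselNetwork:
    """Generate a random planar arterial tree with known geometry.

    config keys: n_branches (total segments incl. trunk), length_range (µm),
    d0_range (µm), field_size (w, h µm), trunk_length (optional µm),
    cls (default "artery"), jitter (waviness amplitude, µm, default 0).
    """
    rng = np.random.default_rng(seed)
    w, h = config.get("field_size", (2000.0, 2000.0))
    n = int(config.get("n_branches", 1))
    lmin, lmax = config.get("length_range", (400.0, 1200.0))
    dmin, dmax = config.get("d0_range", (20.0, 30.0))
    cls = config.get("cls", "artery")
    jitter = float(config.get("jitter", 0.0))
    margin = 50.0
    if w < 2 * margin + lmin / 4 or h < 2 * margin:
        raise ValueError("field size too small to place the requested branches")

    def _wavy(p0: np.ndarray, ang: float, length: float) -> np.ndarray:
        npts = max(int(length / 20.0) + 2, 4)
        t = np.linspace(0.0, length, npts)
        direc = np.array([np.cos(ang), np.sin(ang)])
        perp = np.array([-np.sin(ang), np.cos(ang)])
        wig = jitter * np.sin(2 * np.pi * t / max(length, 1.0) * rng.uniform(1, 3)
                              + rng.uniform(0, 2 * np.pi)) if jitter > 0 else 0.0
        pts = p0[None, :] + t[:, None] * direc[None, :] + np.atleast_1d(wig)[:, None] * perp[None, :]
        return np.clip(pts, [margin / 2, margin / 2], [w - margin / 2, h - margin / 2])

    trunk_len = float(config.get("trunk_length", rng.uniform(lmin, lmax)))
    start = np.array([margin, h / 2.0])
    trunk = _wavy(start, 0.0, min(trunk_len, w - 2 * margin))
    segments = [Segment(points=trunk, d0=float(rng.uniform(dmin, dmax)), cls=cls)]
    for _ in range(n - 1):
        parent = int(rng.integers(0, len(segments)))
        pseg = segments[parent]
        attach = float(rng.uniform(0.1, 0.9)) * pseg.length
        p0 = resample_polyline(pseg.points, np.array([attach]))[0]
        ang = rng.uniform(-np.pi / 2.5, np.pi / 2.5) + rng.choice([0.0, np.pi])
        length = float(rng.uniform(lmin, lmax))
        pts = _wavy(p0, ang, length)
        segments.append(Segment(points=pts, d0=float(rng.uniform(dmin, dmax)),
                                cls=cls, parent=parent, attach_arc=attach))
    return VesselNetwork(segments=segments, source=tuple(start),
                         field_size=(float(w), float(h)))
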