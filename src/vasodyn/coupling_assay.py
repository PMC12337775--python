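"""Gap-junction tracer-transfer quantification (serotonin/SERT assay).

The coupling index is the background-corrected ratio of tracer intensity in
a transporter-expressing probe cell to the mean intensity of the 3a nearest
pixels of contiguous vasculature (a = probe area in pixels).  Values near 1
indicate strong gap-junction transfer; a non-positive denominator (no
transfer) is censored-high.  Vessel segments are classified along the
arterio-venous axis from diameter, plexus and traced proximity rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage import measure

from .synthgen import CouplingScene


@dataclass
class CouplingResult:
    index: float
    censored_high: bool
    numerator: float
    denominator: float
    probe_area: int


def nearest_vasculature_pixels(scene: CouplingScene,
                               count: int | None = None) -> np.ndarray:
    """(row, col) array of the ``count`` (default 3a) vasculature pixels in
    the probe's connected component, excluding the probe, ranked by Euclidean
    distance to the probe boundary with raster-order tie-breaks."""
    probe = scene.probe_mask
    vasc = scene.vasc_mask
    a = scene.probe_area
    if count is None:
        count = 3 * a
    labels = measure.label(vasc, connectivity=2)
    probe_labels = np.unique(labels[probe])
    probe_labels = probe_labels[probe_labels > 0]
    if len(probe_labels) != 1:
        raise ValueError("probe must lie in a single connected vasculature component")
    comp = labels == probe_labels[0]
    pool = comp & ~probe
    rr, cc = np.nonzero(pool)
    if len(rr) < count:
        raise ValueError(f"fewer than {count} eligible vasculature pixels")
    probe_pts = np.argwhere(probe)
    d, _ = cKDTree(probe_pts).query(np.column_stack([rr, cc]))
    order = np.lexsort((cc, rr, np.round(d, 9)))
    sel = order[:count]
    return np.column_stack([rr[sel], cc[sel]])


def coupling_index(scene: CouplingScene) -> CouplingResult:
    """Background-corrected probe / nearest-neighborhood intensity ratio."""
    a = scene.probe_area
    neighbors = nearest_vasculature_pixels(scene, count=3 * a)
    img = np.asarray(scene.image, dtype=float)
    num = float(img[scene.probe_mask].mean() - scene.background)
    den = float(img[neighbors[:, 0], neighbors[:, 1]].mean() - scene.background)
    if den <= 0:
        return CouplingResult(index=np.inf, censored_high=True,
                              numerator=num, denominator=den, probe_area=a)
    return CouplingResult(index=num / den, censored_high=False,
                          numerator=num, denominator=den, probe_area=a)


def apply_censor_cap(results: list[CouplingResult]) -> np.ndarray:
    """Batch-level cap for censored-high indices: the 99th percentile of the
    finite indices in the batch (documented, flagged in output)."""
    finite = [r.index for r in results if not r.censored_high and np.isfinite(r.index)]
    cap = float(np.percentile(finite, 99.0)) if finite else np.nan
    return np.array([cap if r.censored_high else r.index for r in results])


# ---------------------------------------------------------------------------
# arterio-venous classification

@dataclass
class SegmentClassInput:
    """Morphological features used to place a vessel segment on the
    arterio-venous axis."""
    diameter_um: float
    plexus: str                         # superficial | intermediate | deep
    traced_distance_um: float           # along the vasculature to the nearest
                                        # clearly defined artery or vein
    reference_class: str                # that vessel's class: artery | vein

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("diameter must be positive")
        if self.traced_distance_um < 0:
            raise ValueError("traced distance must be >= 0")
        if self.plexus not in ("superficial", "intermediate", "deep"):
            raise ValueError(f"unknown plexus {self.plexus!r}")
        if self.reference_class not in ("artery", "vein"):
            raise ValueError("reference class must be artery or vein")


def classify_segment(inp: SegmentClassInput) -> str:
    """Arterio-venous decision tree.

    > 7 µm: artery or vein (the supplied reference class); < 5.5 µm:
    capillary; 5.5-7 µm (closed interval): capillary in the intermediate
    plexus, otherwise arterial/venous when < 60 µm traced from a clearly
    defined artery/vein, else capillary.
    """
    d = inp.diameter_um
    if d > 7.0:
        return inp.reference_class
    if d < 5.5:
        return "capillary"
    if inp.plexus == "intermediate":
        return "capillary"
    if inp.traced_distance_um < 60.0:
        return inp.reference_class
    return "capillary"
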