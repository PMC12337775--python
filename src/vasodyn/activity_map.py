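"""Evoked neural-activity maps from GCaMP movies.

Produces hemoglobin-corrected, session-normalized response images, binary
activation masks (threshold 0.5; a conservative 0.2 variant for local
activity), Euclidean distance-to-activity, and the quartic-exponential
local-activity statistic l = sum exp(-D^4 / (2 sigma^4)) with sigma = 400 µm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .movie_io import Movie

ACTIVITY_THRESHOLD = 0.5
CONSERVATIVE_THRESHOLD = 0.2
KERNEL_SIGMA_UM = 400.0
EVOKED_WINDOW_S = 1.12
SMOOTH_KERNEL_UM = 90.0


@dataclass
class ActivityMap:
    """Normalized evoked-response image with its binarized mask."""
    response: np.ndarray            # nominally 0-1
    mask: np.ndarray                # bool, response > threshold
    pixel_size: float               # µm / pixel
    threshold: float = ACTIVITY_THRESHOLD
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.response.shape != self.mask.shape:
            raise ValueError("mask and response must share shape")

    def conservative_mask(self) -> np.ndarray:
        return self.response > CONSERVATIVE_THRESHOLD


def hb_correct(gcamp: np.ndarray, ios: np.ndarray, ios_baseline: np.ndarray,
               exponent: float = 1.0) -> np.ndarray:
    """Ratiometric hemoglobin-absorption correction of a 470 nm frame using
    the simultaneous 530 nm (isosbestic) reflectance.

    corrected = gcamp / (ios / ios_baseline)**exponent; first-order
    Beer-Lambert at the isosbestic point.  Pixels with non-positive baseline
    are marked invalid (NaN).
    """
    gcamp = np.asarray(gcamp, dtype=float)
    ios = np.asarray(ios, dtype=float)
    base = np.asarray(ios_baseline, dtype=float)
    bad = base <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(bad, np.nan, ios / np.where(bad, 1.0, base))
        out = gcamp / np.power(ratio, exponent)
    out[bad] = np.nan
    return out


def _hot_pixel_correct(frames: np.ndarray, pct: float = 99.99) -> np.ndarray:
    thr = np.percentile(frames, pct)
    hot = frames > thr
    if not hot.any():
        return frames
    out = frames.copy()
    for k in np.unique(np.nonzero(hot)[0]):
        med = ndimage.median_filter(frames[k], size=3)
        out[k] = np.where(hot[k], med, frames[k])
    return out


def normalize_session(movies: list[Movie], trial_table: pd.DataFrame,
                      aperture_mask: np.ndarray | None = None,
                      smooth_um: float = SMOOTH_KERNEL_UM,
                      temporal_moving_average: int | None = None,
                      rescale: bool = True,
                      hot_pixel: bool = True) -> list[Movie]:
    """Hot-pixel correct, smooth (90 µm), divide by the per-pixel pre-stimulus
    cross-trial mean, then rescale so the session's 15th percentile maps to 0
    and the 99th to 1 (pixels outside the aperture excluded from the
    percentiles).  Degenerate percentiles return all-0.5 with a warning.

    ``temporal_moving_average`` optionally applies an N-frame moving average
    after smoothing (used in trial-wise analyses; off by default here).
    """
    if len(trial_table) < 1:
        raise ValueError("need at least one trial")
    out_frames = []
    for mv, row in zip(movies, trial_table.itertuples()):
        fr = np.asarray(mv.frames, dtype=float)
        if hot_pixel:
            fr = _hot_pixel_correct(fr)
        sig = smooth_um / mv.pixel_size
        fr = np.stack([ndimage.gaussian_filter(f, sig) for f in fr])
        if temporal_moving_average and temporal_moving_average > 1:
            kern = np.ones(temporal_moving_average) / temporal_moving_average
            fr = ndimage.convolve1d(fr, kern, axis=0, mode="nearest")
        out_frames.append(fr)

    onsets = trial_table["onset_frame"].to_numpy(int)
    pre = np.concatenate([fr[:o] for fr, o in zip(out_frames, onsets)], axis=0)
    if pre.size == 0:
        raise ValueError("pre-stimulus window is empty")
    baseline = pre.mean(axis=0)
    bad = baseline == 0
    baseline_safe = np.where(bad, 1.0, baseline)
    normed = []
    for fr in out_frames:
        nf = fr / baseline_safe[None]
        nf[:, bad] = np.nan
        normed.append(nf)

    if rescale:
        if aperture_mask is None:
            aperture_mask = np.ones(baseline.shape, dtype=bool)
        pool = np.concatenate([nf[:, aperture_mask] for nf in normed], axis=0)
        pool = pool[np.isfinite(pool)]
        lo, hi = np.percentile(pool, [15.0, 99.0])
        if np.isclose(hi, lo):
            warnings.warn("degenerate session percentiles; returning 0.5")
            normed = [np.full_like(nf, 0.5) for nf in normed]
        else:
            normed = [(nf - lo) / (hi - lo) for nf in normed]

    return [Movie(frames=nf, channel=mv.channel, frame_period=mv.frame_period,
                  pixel_size=mv.pixel_size, meta=mv.meta)
            for nf, mv in zip(normed, movies)]


def evoked_map(normalized_movies: list[Movie], trial_table: pd.DataFrame,
               window_s: float = EVOKED_WINDOW_S,
               threshold: float = ACTIVITY_THRESHOLD) -> ActivityMap:
    """Average response in a 1.12 s post-onset window, averaged across
    trials, binarized at a strict > threshold."""
    if len(normalized_movies) == 0 or len(trial_table) == 0:
        raise ValueError("no trials to map")
    per_trial = []
    for mv, row in zip(normalized_movies, trial_table.itertuples()):
        onset = int(row.onset_frame)
        n_win = max(int(round(window_s / mv.frame_period)), 1)
        if onset + n_win > mv.n_frames:
            raise ValueError("evoked window does not fit within the trial")
        per_trial.append(np.asarray(mv.frames[onset:onset + n_win], dtype=float).mean(axis=0))
    resp = np.mean(per_trial, axis=0)
    mask = resp > threshold
    return ActivityMap(response=resp, mask=mask,
                       pixel_size=normalized_movies[0].pixel_size,
                       threshold=threshold,
                       provenance={"n_trials": len(per_trial), "window_s": window_s})


def distance_to_activity(mask: np.ndarray, point_um: tuple[float, float],
                         pixel_size: float) -> float:
    """Euclidean distance (µm) from a point to the nearest activated pixel
    centre; 0 if the point lies on an activated pixel (the "<1 µm" bin)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty activity mask: distance undefined")
    px = np.floor(np.asarray(point_um) / pixel_size).astype(int)
    px = np.clip(px, 0, [mask.shape[1] - 1, mask.shape[0] - 1])
    if mask[px[1], px[0]]:
        return 0.0
    rr, cc = np.nonzero(mask)
    centers = np.column_stack([(cc + 0.5) * pixel_size, (rr + 0.5) * pixel_size])
    d, _ = cKDTree(centers).query(np.asarray(point_um, dtype=float))
    return float(d)


def local_activity(conservative_mask: np.ndarray,
                   position_um: tuple[float, float], pixel_size: float,
                   sigma_um: float = KERNEL_SIGMA_UM) -> float:
    """l = sum over activated pixels of exp(-D^4 / (2 sigma^4)); the kernel is
    radially symmetric, non-increasing in D and additive over disjoint masks."""
    if sigma_um <= 0:
        raise ValueError("sigma must be positive")
    mask = np.asarray(conservative_mask, dtype=bool)
    if not mask.any():
        return 0.0
    rr, cc = np.nonzero(mask)
    dx = (cc + 0.5) * pixel_size - position_um[0]
    dy = (rr + 0.5) * pixel_size - position_um[1]
    d2 = dx * dx + dy * dy
    return float(np.exp(-(d2 * d2) / (2.0 * sigma_um ** 4)).sum())


def local_activity_exclusion(log_l_prestim_mean: float,
                             threshold: float = 6.0) -> bool:
    """True (exclude) when the pre-stimulus mean of log l exceeds the
    threshold (natural log)."""
    return log_l_prestim_mean > threshold
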