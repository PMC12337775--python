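"""Derived vasomotion parameters and the two spatial estimators.

* max dilation and time-to-peak within the paradigm-specific window;
* dilation onset from a sigmoid fit, y(t) = a + b / (1 + exp((c - t)/d)),
  over the window from 1.5 s before stimulus onset to 0.5 s after peak
  dilation, onset at 10% of the fitted amplitude (closed form c - d ln 9);
* propagation velocity as the inverse slope of the ordinary-least-squares
  line through onset time versus arc distance (45 µm sampling);
* decay length lambda from a single exponential, y = A exp(-x/lambda) +
  floor, with the floor fixed to the pooled blank-trial mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, stats

LN9 = np.log(9.0)
VELOCITY_SPACING_UM = 45.0


def max_dilation(values: np.ndarray, onset_index: int, frame_period: float,
                 paradigm: str = "visual", stim_duration_s: float = 4.0):
    """(maximum vasomotion value, time-to-peak in s) within the paradigm
    window: [onset, onset + 4 s] for visual and blank trials, [onset, onset +
    stimulus + 4 s] for optogenetic."""
    if paradigm not in ("visual", "optogenetic", "blank"):
        raise ValueError("paradigm must be visual, optogenetic or blank")
    values = np.asarray(values, dtype=float)
    win_s = 4.0 if paradigm in ("visual", "blank") else stim_duration_s + 4.0
    stop = min(onset_index + int(round(win_s / frame_period)) + 1, len(values))
    if stop <= onset_index:
        raise ValueError("analysis window lies outside the trajectory")
    win = values[onset_index:stop]
    if np.all(~np.isfinite(win)):
        return np.nan, np.nan
    k = int(np.nanargmax(win))
    return float(win[k]), float(k * frame_period)


@dataclass
class SigmoidFit:
    a: float                        # baseline, fractional units
    b: float                        # amplitude, fractional units
    c: float                        # half-rise time, s
    d: float                        # rise timescale, s
    rss: float = np.nan
    window: tuple[float, float] = (np.nan, np.nan)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return _sigmoid(np.asarray(t, dtype=float), self.a, self.b, self.c, self.d)

    def onset(self, mode: str = "amplitude") -> float:
        """Time at which the fit reaches 10% of its maximum.

        mode="amplitude" (default): 10% of the fitted amplitude b above
        baseline a, the closed form c - d ln 9.  mode="absolute": the level
        is 10% of the absolute fitted maximum (a + b).
        """
        if mode == "amplitude":
            return self.c - self.d * LN9
        level = 0.1 * (self.a + self.b)
        if not (self.a < level < self.a + self.b):
            return np.nan
        frac = (level - self.a) / self.b
        return self.c - self.d * np.log(1.0 / frac - 1.0)


def _sigmoid(t, a, b, c, d):
    return a + b / (1.0 + np.exp(np.clip((c - t) / d, -500, 500)))


def fit_onset(values: np.ndarray, times: np.ndarray, stim_onset_s: float,
              pre_window_s: float = 1.5, post_peak_s: float = 0.5,
              search_window_s: float | None = None,
              onset_mode: str = "amplitude",
              peak_smooth_s: float = 0.3):
    """Fit the rising phase of an average trajectory to a sigmoid and return
    (SigmoidFit, onset time in s).

    The fit window runs from ``stim_onset_s - 1.5 s`` to 0.5 s after the time
    of maximum dilation (peak located on a lightly smoothed copy, searched
    after onset, optionally within ``search_window_s``).  Initialisation:
    a = pre-stimulus mean, b = peak - a, c = half-rise time of the smoothed
    trajectory, d = 0.25 s, with d bounded in (0.01, 10] s.  Returns onset
    NaN on non-convergence or non-positive fitted amplitude.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    ok = np.isfinite(values)
    values, times = values[ok], times[ok]
    if len(values) < 8:
        return None, np.nan
    dt = np.median(np.diff(times))
    smooth = ndimage.uniform_filter1d(values, max(int(round(peak_smooth_s / dt)), 1))
    post = times >= stim_onset_s
    if search_window_s is not None:
        post &= times <= stim_onset_s + search_window_s
    if not post.any():
        return None, np.nan
    pk_rel = int(np.argmax(smooth[post]))
    t_peak = times[post][pk_rel]
    peak_val = smooth[post][pk_rel]

    in_win = (times >= stim_onset_s - pre_window_s) & (times <= t_peak + post_peak_s)
    tw, yw = times[in_win], values[in_win]
    if len(tw) < 6:
        return None, np.nan
    pre = values[(times < stim_onset_s) & in_win]
    a0 = float(pre.mean()) if len(pre) else float(yw[0])
    b0 = float(peak_val - a0)
    if b0 <= 0:
        return None, np.nan
    half_level = a0 + b0 / 2.0
    above = np.nonzero(smooth[in_win] >= half_level)[0]
    c0 = float(tw[above[0]]) if len(above) else float((stim_onset_s + t_peak) / 2)
    p0 = [a0, b0, c0, 0.25]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                _sigmoid, tw, yw, p0=p0,
                bounds=([-np.inf, 0.0, tw[0] - 5.0, 0.01],
                        [np.inf, np.inf, tw[-1] + 5.0, 10.0]),
                maxfev=20000)
    except (RuntimeError, ValueError):
        return None, np.nan
    fit = SigmoidFit(a=float(popt[0]), b=float(popt[1]), c=float(popt[2]),
                     d=float(popt[3]),
                     rss=float(np.sum((_sigmoid(tw, *popt) - yw) ** 2)),
                     window=(float(tw[0]), float(tw[-1])))
    if fit.b <= 0:
        return fit, np.nan
    return fit, float(fit.onset(mode=onset_mode))


@dataclass
class VelocityFit:
    distances_um: np.ndarray
    onsets_s: np.ndarray
    slope_s_per_um: float
    intercept_s: float
    velocity_mm_s: float
    r_value: float
    stderr: float
    propagating: bool
    fits: list = field(default_factory=list)


def _refit_fixed_d(values, times, fit: SigmoidFit, d_fixed: float,
                   b_fixed: float | None = None):
    """Re-fit with the rise timescale (and optionally the amplitude) held
    fixed; only the remaining parameters are free."""
    m = (times >= fit.window[0]) & (times <= fit.window[1])
    tw, yw = times[m], values[m]
    ok = np.isfinite(yw)
    tw, yw = tw[ok], yw[ok]

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if b_fixed is None:
                def model(t, a, b, c):
                    return _sigmoid(t, a, b, c, d_fixed)
                popt, _ = optimize.curve_fit(model, tw, yw,
                                             p0=[fit.a, max(fit.b, 1e-6), fit.c],
                                             maxfev=20000)
                a, b, c = popt
            else:
                def model(t, a, c):
                    return _sigmoid(t, a, b_fixed, c, d_fixed)
                popt, _ = optimize.curve_fit(model, tw, yw,
                                             p0=[fit.a, fit.c], maxfev=20000)
                a, c = popt
                b = b_fixed
        rss = float(np.sum((_sigmoid(tw, a, b, c, d_fixed) - yw) ** 2))
    except (RuntimeError, ValueError):
        return None
    return SigmoidFit(a=float(a), b=float(b), c=float(c), d=d_fixed,
                      rss=rss, window=fit.window)


def propagation_velocity(position_trajectories, times: np.ndarray,
                         distances_um: np.ndarray, stim_onset_s: float,
                         search_window_s: float | None = None,
                         onset_mode: str = "amplitude",
                         shared_rise_time: bool = True,
                         smooth_amplitude: bool = True) -> VelocityFit:
    """Propagation velocity from onset times along one artery.

    ``position_trajectories`` is an (n_positions, T) array of across-replicate
    average trajectories at arc distances ``distances_um``.  Onset is fitted
    per position; an unweighted straight line through onset versus distance
    gives the velocity as the inverse slope (reported in mm/s).  A
    non-positive slope is flagged as non-propagating.

    With ``shared_rise_time`` (default) the sigmoid fits are run twice: the
    median rise timescale d across positions is fixed in a second pass.  The
    wave's rise time does not vary along the artery, and freeing d per
    position lets low-amplitude distal fits trade d against c, inflating
    onset noise.
    """
    traj = np.asarray(position_trajectories, dtype=float)
    distances_um = np.asarray(distances_um, dtype=float)
    onsets = np.full(len(distances_um), np.nan)
    fits = []
    for i in range(traj.shape[0]):
        f, t_on = fit_onset(traj[i], times, stim_onset_s,
                            search_window_s=search_window_s,
                            onset_mode=onset_mode)
        fits.append(f)
        onsets[i] = t_on
    if shared_rise_time:
        ds = [f.d for f, on in zip(fits, onsets) if f is not None and np.isfinite(on)]
        if len(ds) >= 3:
            d_med = float(np.median(ds))
            # re-locate each position's fit window with peak smoothing
            # proportional to the rise time: a noisy mid-rise bump must not
            # beat the plateau, or the truncated window drags onsets early
            for i in range(traj.shape[0]):
                f, t_on = fit_onset(traj[i], times, stim_onset_s,
                                    search_window_s=search_window_s,
                                    onset_mode=onset_mode,
                                    peak_smooth_s=max(0.3, 2.0 * d_med))
                if f is not None:
                    fits[i] = f
                    onsets[i] = t_on
            for i, f in enumerate(fits):
                if f is None:
                    continue
                f2 = _refit_fixed_d(traj[i], times, f, d_med)
                if f2 is not None and f2.b > 0:
                    fits[i] = f2
                    onsets[i] = float(f2.onset(mode=onset_mode))
            if smooth_amplitude and len(ds) >= 7:
                # amplitude varies smoothly along an artery: hold each
                # position's amplitude at the running median of its
                # neighbours so the final fit estimates (a, c) only —
                # removing the noise-asymmetric amplitude/phase trade-off
                bs = np.array([f.b if f is not None else np.nan for f in fits])
                order = np.argsort(distances_um)
                b_s = np.full_like(bs, np.nan)
                half = 3
                for j, i in enumerate(order):
                    if not np.isfinite(bs[i]):
                        continue
                    lo, hi = max(j - half, 0), min(j + half + 1, len(order))
                    vals = bs[order[lo:hi]]
                    b_s[i] = np.nanmedian(vals)
                for i, f in enumerate(fits):
                    if f is None or not np.isfinite(b_s[i]) or b_s[i] <= 0:
                        continue
                    f3 = _refit_fixed_d(traj[i], times, f, d_med, b_fixed=float(b_s[i]))
                    if f3 is not None:
                        fits[i] = f3
                        onsets[i] = float(f3.onset(mode=onset_mode))
    ok = np.isfinite(onsets)
    if ok.sum() < 3:
        raise ValueError("need onset estimates at >= 3 positions")
    res = stats.linregress(distances_um[ok], onsets[ok])
    slope = float(res.slope)
    if slope <= 0:
        return VelocityFit(distances_um=distances_um, onsets_s=onsets,
                           slope_s_per_um=slope, intercept_s=float(res.intercept),
                           velocity_mm_s=np.inf if slope == 0 else np.nan,
                           r_value=float(res.rvalue), stderr=float(res.stderr),
                           propagating=False, fits=fits)
    velocity = 1.0 / slope / 1000.0   # (µm/s) -> mm/s
    return VelocityFit(distances_um=distances_um, onsets_s=onsets,
                       slope_s_per_um=slope, intercept_s=float(res.intercept),
                       velocity_mm_s=float(velocity), r_value=float(res.rvalue),
                       stderr=float(res.stderr), propagating=True, fits=fits)


@dataclass
class DecayFit:
    lam_um: float
    amplitude: float
    floor: float
    ci_um: tuple[float, float]
    identifiable: bool


def decay_constant(distances_um: np.ndarray, max_dilations: np.ndarray,
                   blank_floor: float, n_boot: int = 1000, seed: int = 0,
                   lam_bounds=(1.0, 1e6)) -> DecayFit:
    """Decay length constant of evoked dilation versus distance.

    Least-squares fit of y(x) = A exp(-x/lambda) + floor with the floor fixed
    to the pooled blank-trial mean; a bootstrap (resampling points) gives the
    confidence interval.  Non-decaying data (lambda at its bound, or A ~ 0)
    is flagged unidentifiable.
    """
    x = np.asarray(distances_um, dtype=float)
    y = np.asarray(max_dilations, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValueError("need at least 4 distance bins")

    def model(x_, A, lam):
        return A * np.exp(-x_ / lam) + blank_floor

    def _fit(x_, y_):
        a0 = max(y_.max() - blank_floor, 1e-6)
        lam0 = max(x_.max() / 2.0, lam_bounds[0] * 2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                model, x_, y_, p0=[a0, lam0],
                bounds=([0.0, lam_bounds[0]], [np.inf, lam_bounds[1]]),
                maxfev=20000)
        return popt

    try:
        A, lam = _fit(x, y)
    except (RuntimeError, ValueError):
        return DecayFit(lam_um=np.nan, amplitude=np.nan, floor=blank_floor,
                        ci_um=(np.nan, np.nan), identifiable=False)
    span = y.max() - y.min()
    identifiable = (span > 1e-12 and A > 0.05 * span
                    and lam < 0.99 * lam_bounds[1] and lam > 1.01 * lam_bounds[0])
    rng = np.random.default_rng(seed)
    lams = []
    if identifiable:
        for _ in range(n_boot):
            idx = rng.integers(0, len(x), len(x))
            if len(np.unique(x[idx])) < 3:
                continue
            try:
                _, lb = _fit(x[idx], y[idx])
                lams.append(lb)
            except (RuntimeError, ValueError):
                continue
    ci = (float(np.percentile(lams, 2.5)), float(np.percentile(lams, 97.5))) \
        if len(lams) >= 10 else (np.nan, np.nan)
    return DecayFit(lam_um=float(lam), amplitude=float(A), floor=blank_floor,
                    ci_um=ci, identifiable=bool(identifiable))
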