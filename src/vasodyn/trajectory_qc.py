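"""Trajectory quality control and behavioral correction.

Two filters precede kinetic quantification of two-photon dilation data:

* a baseline-excursion filter — trials whose pre-stimulus |Z| 96th percentile
  exceeds 3 are excluded;
* a spectral noise gate — trajectories whose 0.5-1.3 Hz band power within
  2.3 s of stimulus onset falls below 3 dB/Hz (percent units) are replaced
  by zeros (kept, not dropped).

Behavioral state (locomotion, pupil) is regressed out with a random-intercept
mixed model; only slopes significant at p < 0.01 are corrected for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .vessel_quant import Trajectory

Z_PERCENTILE = 96.0
Z_THRESHOLD = 3.0
NOISE_BAND_HZ = (0.5, 1.3)
NOISE_THRESHOLD_DB = 3.0
NOISE_WINDOW_S = 2.3
SLOPE_ALPHA = 0.01


@dataclass
class QCResult:
    keep: bool
    reason: str = ""
    statistic: float = np.nan


def zscore_filter(trajectory: Trajectory, baseline_mean: float,
                  baseline_sd: float) -> QCResult:
    """Exclude trials with excessive pre-stimulus vasomotion.

    Z(t) = (value - session baseline mean) / sd over the pre-stimulus window;
    the trial is excluded iff the 96th percentile of |Z| exceeds 3.  The
    percentile rule tolerates rare spikes (a single outlier among 100 samples
    does not trigger it).
    """
    if baseline_sd <= 0:
        return QCResult(keep=False, reason="degenerate baseline")
    pre = trajectory.values[: trajectory.onset_index]
    if len(pre) == 0:
        return QCResult(keep=False, reason="no pre-stimulus samples")
    z = np.abs((pre - baseline_mean) / baseline_sd)
    q = float(np.percentile(z, Z_PERCENTILE))
    if q > Z_THRESHOLD:
        return QCResult(keep=False, reason="pre-stimulus excursion", statistic=q)
    return QCResult(keep=True, statistic=q)


def band_power_db(values: np.ndarray, fs: float, onset_index: int,
                  band: tuple[float, float] = NOISE_BAND_HZ,
                  window_s: float = NOISE_WINDOW_S,
                  segment_s: float = 4.0,
                  percent_units: bool = True) -> float:
    """Mean spectral power density (dB/Hz) in the dilation band over the
    post-onset window, from a Hann-windowed spectrogram (4 s segments, 50%
    overlap).  ``percent_units`` scales fractional trajectories to percent
    before the PSD, the unit in which the 3 dB/Hz threshold is calibrated.
    """
    x = np.asarray(values, dtype=float)
    if percent_units:
        x = 100.0 * x
    nperseg = min(int(round(segment_s * fs)), len(x))
    if nperseg < 8:
        raise ValueError("trajectory too short for the spectral gate")
    f, tt, Sxx = signal.spectrogram(x, fs=fs, window="hann", nperseg=nperseg,
                                    noverlap=nperseg // 2, detrend="constant",
                                    scaling="density", mode="psd")
    t_on = onset_index / fs
    centers_in = (tt >= t_on) & (tt <= t_on + window_s)
    if not centers_in.any():
        # short recordings: use segments overlapping the window
        half = nperseg / (2 * fs)
        centers_in = (tt + half >= t_on) & (tt - half <= t_on + window_s)
    if not centers_in.any():
        raise ValueError("no spectrogram segment overlaps the onset window")
    in_band = (f >= band[0]) & (f <= band[1])
    if not in_band.any():
        raise ValueError("frequency band empty; check the sampling rate")
    p = Sxx[np.ix_(in_band, centers_in)].mean()
    with np.errstate(divide="ignore"):
        return float(10.0 * np.log10(p))


def noise_gate(trajectory: Trajectory,
               threshold_db: float = NOISE_THRESHOLD_DB,
               band: tuple[float, float] = NOISE_BAND_HZ,
               window_s: float = NOISE_WINDOW_S) -> tuple[Trajectory, float]:
    """Zero out trajectories whose post-onset band power is below threshold.

    The trajectory is never altered except to be replaced entirely by zeros.
    Returns (possibly zeroed trajectory, measured band power in dB/Hz).
    """
    fs = 1.0 / trajectory.frame_period
    if fs < 2.0 * band[1]:
        raise ValueError("frame rate below Nyquist for the dilation band")
    db = band_power_db(trajectory.values, fs, trajectory.onset_index,
                       band=band, window_s=window_s)
    if db < threshold_db:
        zeroed = Trajectory(values=np.zeros_like(trajectory.values),
                            onset_index=trajectory.onset_index,
                            frame_period=trajectory.frame_period,
                            mouse=trajectory.mouse, fov=trajectory.fov,
                            vessel=trajectory.vessel, trial=trajectory.trial,
                            distance_um=trajectory.distance_um,
                            baseline_diameter_um=trajectory.baseline_diameter_um,
                            measure=trajectory.measure)
        return zeroed, db
    return trajectory, db


# ---------------------------------------------------------------------------
# behavioral correction

@dataclass
class BehaviorModelFit:
    """Random-intercept behavioral model y = b00 + b10 l + b20 p + U0j + e."""
    beta00: float
    beta10: float
    beta20: float
    p_locomotion: float
    p_pupil: float
    random_intercepts: dict
    corrected_locomotion: bool = False
    corrected_pupil: bool = False
    dropped: tuple = ()


def behavior_correct(y: np.ndarray, locomotion: np.ndarray, pupil: np.ndarray,
                     groups: np.ndarray,
                     alpha: float = SLOPE_ALPHA) -> tuple[np.ndarray, BehaviorModelFit]:
    """Regress behavioral state out of trajectory summaries.

    Fits a random-intercept model per vessel-stimulus combination (groups j)
    by REML; slope p-values from the large-sample normal approximation.  Each
    slope significant at p < alpha is subtracted (slope x covariate) from
    every observation; non-significant slopes leave the data untouched.
    Constant covariates are dropped with a warning.
    """
    y = np.asarray(y, dtype=float)
    df = pd.DataFrame({"y": y, "l": np.asarray(locomotion, dtype=float),
                       "p": np.asarray(pupil, dtype=float),
                       "j": np.asarray(groups)})
    use = []
    dropped = []
    for name in ("l", "p"):
        if df[name].std() > 0:
            use.append(name)
        else:
            dropped.append(name)
            warnings.warn(f"covariate {name!r} is constant; slope skipped")
    if not use:
        fit = BehaviorModelFit(beta00=float(y.mean()), beta10=0.0, beta20=0.0,
                               p_locomotion=1.0, p_pupil=1.0,
                               random_intercepts={}, dropped=tuple(dropped))
        return y.copy(), fit

    formula = "y ~ " + " + ".join(use)
    if df["j"].nunique() > 1:
        model = smf.mixedlm(formula, df, groups=df["j"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=True)
        params, pvalues = res.params, res.pvalues
        try:
            rand = {k: float(v.iloc[0]) for k, v in res.random_effects.items()}
        except ValueError:
            # group variance estimated at zero: no predictable intercepts
            rand = {}
    else:
        res = sm.OLS(df["y"], sm.add_constant(df[use])).fit()
        params, pvalues = res.params, res.pvalues
        rand = {}

    b10 = float(params.get("l", 0.0))
    b20 = float(params.get("p", 0.0))
    p10 = float(pvalues.get("l", 1.0))
    p20 = float(pvalues.get("p", 1.0))
    corrected = y.copy()
    c_l = "l" in use and p10 < alpha
    c_p = "p" in use and p20 < alpha
    if c_l:
        corrected = corrected - b10 * df["l"].to_numpy()
    if c_p:
        corrected = corrected - b20 * df["p"].to_numpy()
    fit = BehaviorModelFit(beta00=float(params.get("Intercept", params.get("const", np.nan))),
                           beta10=b10, beta20=b20, p_locomotion=p10,
                           p_pupil=p20, random_intercepts=rand,
                           corrected_locomotion=c_l, corrected_pupil=c_p,
                           dropped=tuple(dropped))
    return corrected, fit
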