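"""Ground-truth generators: dilation waves, rendered movies, behavior,
and gap-junction coupling scenes.

The generative model mirrors the estimators in :mod:`vasodyn.kinetics`:
a dilation wave launched at the stimulation source travels along the
vasculature at speed v, its amplitude decays as exp(-x/lambda) with traced
distance x, and the local time course is a logistic rise (timescale d) to a
plateau followed by exponential relaxation.  Every parameter is carried in
:class:`GroundTruth` so downstream stages can be validated by parameter
recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal, ndimage

from .geometry import VesselNetwork, resample_polyline, polyline_tangents, polyline_arclength

# Logistic half-rise is placed LOGISTIC_LEAD rise-times after wave arrival so
# the curve is effectively zero (~e^-5) at the arrival instant.
LOGISTIC_LEAD = 5.0


@dataclass
class GroundTruth:
    """Generative parameters for a dilation wave."""
    v: float = 4.13                 # propagation velocity, mm/s
    lam: float = 1600.0             # decay length, µm
    a0: float = 0.08                # peak fractional amplitude at the source
    d_rise: float = 0.25            # logistic rise timescale, s
    t0: float = 3.0                 # stimulus onset, s
    duration: float = 2.0           # stimulus duration, s
    tau_relax: float = 2.0          # post-plateau relaxation constant, s
    noise_sd: float = 0.010         # vasomotion noise sd, fraction of baseline
    noise_fmax: float = 0.3         # vasomotion band upper edge, Hz
    noise_fmin: float = 0.05        # vasomotion band lower edge, Hz
    beta10: float = 0.0             # locomotion coupling (fraction / a.u.)
    beta20: float = 0.0             # pupil coupling (fraction / a.u.)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.v <= 0:
            raise ValueError("propagation velocity must be positive")
        if self.lam <= 0:
            raise ValueError("decay length must be positive")
        if not 0 <= self.a0 < 1:
            raise ValueError("peak fractional amplitude must lie in [0, 1)")
        if self.d_rise <= 0 or self.duration < 0 or self.tau_relax <= 0:
            raise ValueError("time constants must be positive")

    @property
    def plateau_end(self) -> float:
        """Local time (after wave arrival) at which relaxation begins."""
        return LOGISTIC_LEAD * self.d_rise + 3.0 * self.d_rise + self.duration

    def envelope(self, tau: np.ndarray) -> np.ndarray:
        """Noiseless local time course g(tau), tau measured from wave arrival.

        Logistic rise (half-rise LOGISTIC_LEAD*d after arrival) times a
        plateau-then-exponential-relaxation envelope; saturates at ~1.
        """
        tau = np.asarray(tau, dtype=float)
        c0 = LOGISTIC_LEAD * self.d_rise
        rise = 1.0 / (1.0 + np.exp(np.clip((c0 - tau) / self.d_rise, -500, 500)))
        tp = self.plateau_end
        relax = np.where(tau > tp, np.exp(-(np.maximum(tau - tp, 0.0)) / self.tau_relax), 1.0)
        return rise * relax

    def asdict(self) -> dict:
        return asdict(self)


def bandlimited_noise(n: int, fs: float, sd: float, fmax: float,
                      rng: np.random.Generator,
                      fmin: float = 0.0) -> np.ndarray:
    """Gaussian noise band-limited to [fmin, fmax] Hz, rescaled to sd.

    With fmin = 0 this is a plain low-pass; spontaneous vasomotion uses a
    band-pass (default 0.05-0.3 Hz) so noise oscillates on the ~0.1 Hz
    timescale rather than drifting within a trial.
    """
    if sd == 0 or n == 0:
        return np.zeros(n)
    pad = max(256, int(4 * fs / max(fmin, 0.01)))
    white = rng.standard_normal(n + 2 * pad)
    nyq = fs / 2.0
    if fmax >= nyq and fmin <= 0:
        out = white
    elif fmin <= 0:
        b, a = signal.butter(3, fmax / nyq, btype="low")
        out = signal.filtfilt(b, a, white)
    else:
        b, a = signal.butter(2, [fmin / nyq, min(fmax / nyq, 0.99)], btype="band")
        out = signal.filtfilt(b, a, white)
    out = out[pad:pad + n]
    s = out.std()
    return out * (sd / s) if s > 0 else out


@dataclass
class DilationField:
    """Per-point diameter series D(s, t) on a sampled network."""
    network: VesselNetwork
    seg_index: np.ndarray           # (S,) segment of each sample
    arc: np.ndarray                 # (S,) within-segment arc, µm
    positions: np.ndarray           # (S, 2) µm
    tangents: np.ndarray            # (S, 2)
    path_dist: np.ndarray           # (S,) traced distance from source, µm
    d0: np.ndarray                  # (S,) baseline diameters, µm
    t: np.ndarray                   # (T,) seconds
    diam: np.ndarray                # (T, S) µm
    truth: GroundTruth | None = None

    @property
    def fractional(self) -> np.ndarray:
        """Fractional dilation (D - D0)/D0, shape (T, S)."""
        return self.diam / self.d0[None, :] - 1.0


def sample_network(network: VesselNetwork, ds: float = 5.0):
    """Sample every segment at arc spacing ds; returns the arrays used by
    :class:`DilationField`."""
    seg_idx, arcs, pos, tan, dist, d0 = [], [], [], [], [], []
    for i, seg in enumerate(network.segments):
        length = seg.length
        a = np.arange(0.0, length + ds / 2, ds)
        a[-1] = min(a[-1], length)
        p = resample_polyline(seg.points, a)
        tg = polyline_tangents(seg.points, a)
        seg_idx.append(np.full(len(a), i))
        arcs.append(a)
        pos.append(p)
        tan.append(tg)
        dist.append(network.path_distance(i, a))
        d0.append(np.full(len(a), seg.d0))
    return (np.concatenate(seg_idx), np.concatenate(arcs), np.vstack(pos),
            np.vstack(tan), np.concatenate(dist), np.concatenate(d0))


def simulate_dilation(network: VesselNetwork, truth: GroundTruth,
                      t: np.ndarray, ds: float = 5.0,
                      rng: np.random.Generator | None = None) -> DilationField:
    """Simulate D(s, t) = D0 (1 + A(s) g(t - t0 - x/v)) + vasomotion noise.

    A(s) = a0 exp(-x(s)/lam); x(s) is the traced distance from the source.
    Vasomotion noise is band-limited below ``truth.noise_fmax`` and coherent
    along the vessel (one trace per call, scaled by baseline), emulating the
    mm-scale coherence of spontaneous vasomotion.
    """
    t = np.asarray(t, dtype=float)
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    seg_idx, arcs, pos, tan, dist, d0 = sample_network(network, ds)
    amp = truth.a0 * np.exp(-dist / truth.lam)
    tau = t[:, None] - truth.t0 - (dist[None, :] / (truth.v * 1000.0))
    frac = amp[None, :] * truth.envelope(tau)
    if truth.noise_sd > 0:
        fs = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 1.0
        eta = bandlimited_noise(len(t), fs, truth.noise_sd, truth.noise_fmax,
                                rng, fmin=truth.noise_fmin)
        frac = frac + eta[:, None]
    diam = d0[None, :] * (1.0 + frac)
    return DilationField(network=network, seg_index=seg_idx, arc=arcs,
                         positions=pos, tangents=tan, path_dist=dist, d0=d0,
                         t=t, diam=diam, truth=truth)


# ---------------------------------------------------------------------------
# movie rendering

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))   # Gaussian FWHM / sigma


@dataclass
class RenderConfig:
    pixel_size: float = 10.0        # µm / pixel
    frame_period: float = 0.14      # s
    background: float = 10000.0     # counts (~1e4 photoelectrons/pixel)
    absorb_gain: float = 0.35       # peak fractional absorbance at D = d_ref
    depth_power: float = 1.0        # absorbance depth ~ (D/d_ref)**depth_power
    d_ref: float = 25.0             # reference diameter, µm
    photon_scale: float = 0.0       # Poisson-like noise scale (0 = none)
    # gcamp channel
    gcamp_baseline: float = 500.0
    blob_amp: float = 500.0
    blob_sigma: float = 300.0       # µm
    kappa: float = 0.0              # hemoglobin crosstalk strength


def _pixel_grid(shape: tuple[int, int], pixel_size: float):
    h, w = shape
    xs = (np.arange(w) + 0.5) * pixel_size
    ys = (np.arange(h) + 0.5) * pixel_size
    return np.meshgrid(xs, ys)


def _vessel_pixel_assignment(field: DilationField, shape, pixel_size, max_r):
    """For each pixel within max_r of the vasculature: nearest sample index
    and perpendicular distance (µm)."""
    from scipy.spatial import cKDTree
    gx, gy = _pixel_grid(shape, pixel_size)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    tree = cKDTree(field.positions)
    dd, ii = tree.query(pts, k=1, distance_upper_bound=max_r)
    mask = np.isfinite(dd)
    return pts, dd, ii, mask


def render_movie(field: DilationField, channel: str, cfg: RenderConfig,
                 rng: np.random.Generator | None = None,
                 stim_course: np.ndarray | None = None):
    """Render a widefield movie from a dilation field.

    ios: background minus a per-vessel Gaussian absorbance profile whose
    width tracks D(s, t) (rendered FWHM equals the true diameter) and whose
    depth tracks blood content ((D/d_ref)**depth_power) — dilated vessels
    are darker and wider.  gcamp: baseline plus an activity blob around the
    source following ``stim_course``, multiplied by (1 - kappa * local
    fractional absorbance) to emulate hemoglobin crosstalk.  Poisson-like
    noise is applied last.
    """
    from .movie_io import Movie
    if channel not in ("ios", "gcamp"):
        raise ValueError("channel must be 'ios' or 'gcamp'")
    net = field.network
    w_um, h_um = net.field_size
    shape = (int(round(h_um / cfg.pixel_size)), int(round(w_um / cfg.pixel_size)))
    dmax = float(field.diam.max())
    sigma_max = dmax / _FWHM
    max_r = 4.0 * sigma_max
    pts, dd, ii, mask = _vessel_pixel_assignment(field, shape, cfg.pixel_size, max_r)
    ii = np.where(mask, ii, 0)
    T = len(field.t)
    frames = np.empty((T,) + shape, dtype=np.float32)

    peak_depth = cfg.absorb_gain * (dmax / cfg.d_ref) ** cfg.depth_power
    if channel == "ios" and peak_depth * cfg.background > cfg.background:
        raise ValueError("absorbance exceeds background; reduce absorb_gain")

    # static absorbance ingredients
    r2 = dd[mask] ** 2
    samp = ii[mask]
    flat_mask = np.flatnonzero(mask)

    if channel == "gcamp":
        gx, gy = _pixel_grid(shape, cfg.pixel_size)
        rho2 = (gx - net.source[0]) ** 2 + (gy - net.source[1]) ** 2
        blob = np.exp(-rho2 / (2.0 * cfg.blob_sigma ** 2))
        if stim_course is None:
            stim_course = np.zeros(T)

    for k in range(T):
        d_here = field.diam[k, samp]
        sigma = d_here / _FWHM
        depth = cfg.absorb_gain * (d_here / cfg.d_ref) ** cfg.depth_power
        absorb_frac = np.zeros(pts.shape[0])
        absorb_frac[flat_mask] = depth * np.exp(-r2 / (2.0 * sigma ** 2))
        if channel == "ios":
            frame = cfg.background * (1.0 - absorb_frac)
        else:
            frame = (cfg.gcamp_baseline + cfg.blob_amp * stim_course[k] * blob.ravel())
            frame = frame * (1.0 - cfg.kappa * absorb_frac)
        frames[k] = frame.reshape(shape)

    if cfg.photon_scale > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        frames = frames + rng.standard_normal(frames.shape).astype(np.float32) * \
            np.sqrt(np.maximum(frames, 0.0)) * cfg.photon_scale
        frames = np.maximum(frames, 0.0)

    return Movie(frames=frames, channel=channel, frame_period=cfg.frame_period,
                 pixel_size=cfg.pixel_size,
                 meta={"truth": field.truth.asdict() if field.truth else None})


# ---------------------------------------------------------------------------
# stimulus schedules

def visual_schedule(n_trials: int, duration: float = 4.0, iti: float = 29.0):
    """Visual schedule: fixed stimulus duration, fixed inter-trial interval.
    Returns trial onset times (s)."""
    return np.arange(n_trials) * (duration + iti)


def optogenetic_schedule(n_trials: int, seed: int, duration: float = 2.0,
                         iti_mean: float = 30.0, iti_sd: float = 5.0,
                         iti_min: float = 20.0):
    """Optogenetic schedule: Gaussian ITI (mean 30 s, sd 5 s) truncated at a
    20 s minimum."""
    rng = np.random.default_rng(seed)
    itis = np.maximum(rng.normal(iti_mean, iti_sd, n_trials), iti_min)
    onsets = np.concatenate([[0.0], np.cumsum(duration + itis)[:-1]])
    return onsets


# ---------------------------------------------------------------------------
# behavior

@dataclass
class BehaviorTrace:
    """Per-trial locomotion and pupil covariates, centred per mouse."""
    locomotion: np.ndarray          # (n_trials,) deviation from mouse mean
    pupil: np.ndarray               # (n_trials,)

    def __post_init__(self) -> None:
        for name in ("locomotion", "pupil"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if len(v) and abs(v.mean()) > 1e-9 * max(1.0, np.abs(v).max()):
                raise ValueError(f"{name} deviations must have zero mean per mouse")


def simulate_behavior(n_trials: int, truth: GroundTruth, seed: int,
                      loc_sd: float = 1.0, pupil_sd: float = 1.0):
    """Draw per-trial behavioral covariates and the additive contamination
    beta10*l + beta20*p they impose on trajectory amplitudes."""
    if n_trials < 2:
        raise ValueError("need at least two trials")
    rng = np.random.default_rng(seed)
    l = rng.normal(0.0, loc_sd, n_trials)
    p = rng.normal(0.0, pupil_sd, n_trials)
    l -= l.mean()
    p -= p.mean()
    contamination = truth.beta10 * l + truth.beta20 * p
    return BehaviorTrace(locomotion=l, pupil=p), contamination


# ---------------------------------------------------------------------------
# coupling-assay scenes

@dataclass
class CouplingScene:
    """Serotonin image with probe-cell and contiguous-vasculature masks."""
    image: np.ndarray               # (H, W) intensity, a.u.
    probe_mask: np.ndarray          # bool
    vasc_mask: np.ndarray           # bool (includes probe)
    background: float
    pixel_size: float               # µm / pixel

    def __post_init__(self) -> None:
        if not np.all(self.vasc_mask[self.probe_mask]):
            raise ValueError("probe mask must lie within the vasculature mask")
        if self.probe_mask.sum() < 1:
            raise ValueError("probe must cover at least one pixel")

    @property
    def probe_area(self) -> int:
        return int(self.probe_mask.sum())


def render_coupling_scene(k: float, geometry: dict | None = None,
                          seed: int = 0) -> CouplingScene:
    """Render a serotonin tracer-transfer scene with known transfer length k.

    The probe cell is painted at ``i_probe``; vasculature pixels at traced
    (geodesic, along the vessel mask) distance r from the probe are painted at
    bg + (i_probe - bg) * exp(-r/k) for k > 0, or bg for k = 0.  k = inf gives
    a uniform fill.
    """
    if k < 0:
        raise ValueError("transfer strength must be >= 0")
    geometry = geometry or {}
    shape = geometry.get("shape", (80, 120))
    pixel_size = float(geometry.get("pixel_size", 1.0))
    bg = float(geometry.get("background", 50.0))
    i_probe = float(geometry.get("i_probe", 1000.0))
    vessel_halfwidth = int(geometry.get("vessel_halfwidth", 2))
    probe_radius = float(geometry.get("probe_radius", 5.0))
    noise_sd = float(geometry.get("noise_sd", 0.0))
    rng = np.random.default_rng(seed)

    h, w = shape
    row = h // 2
    vasc = np.zeros(shape, dtype=bool)
    vasc[row - vessel_halfwidth: row + vessel_halfwidth + 1, :] = True
    cx, cy = w // 3, row
    gx, gy = np.meshgrid(np.arange(w), np.arange(h))
    probe = ((gx - cx) ** 2 + (gy - cy) ** 2) <= (probe_radius / pixel_size) ** 2
    probe &= vasc

    image = np.full(shape, bg, dtype=float)
    if k == 0:
        pass
    else:
        # geodesic distance along the vasculature from the probe boundary
        from skimage.graph import MCP_Geometric
        cost = np.where(vasc, 1.0, np.inf)
        mcp = MCP_Geometric(cost)
        starts = np.argwhere(probe)
        dist, _ = mcp.find_costs(starts)
        r = dist * pixel_size
        with np.errstate(over="ignore"):
            decay = np.exp(-np.where(np.isfinite(r), r, np.inf) / k) if np.isfinite(k) \
                else np.where(np.isfinite(r), 1.0, 0.0)
        image[vasc] = bg + (i_probe - bg) * decay[vasc]
    image[probe] = i_probe
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, shape)
    return CouplingScene(image=image, probe_mask=probe, vasc_mask=vasc,
                         background=bg, pixel_size=pixel_size)
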