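"""Hierarchical models for binned vasomotion and trajectory confidence bands.

Per distance bin, vasomotion is modelled as an intercept plus nested random
intercepts (trial within vessel within field-of-view within mouse for
two-photon data; trial within mouse for widefield), fitted by REML.  The
genotype contrast adds a dummy fixed effect (optionally with a centred
baseline-diameter slope).  Trajectory confidence bands come from a
hierarchical bootstrap that resamples mice, then trials within each sampled
mouse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

DISTANCE_BINS_UM = (0.0, 1.0, 400.0, 800.0, 1200.0, 1600.0, 2000.0)


@dataclass
class HierarchicalFit:
    beta00: float
    ci: tuple[float, float]
    se: float
    variance_components: dict
    residual_var: float
    nesting: tuple
    genotype_coef: float = np.nan
    genotype_ci: tuple = (np.nan, np.nan)
    genotype_p: float = np.nan
    diameter_slope: float = np.nan
    dropped_tiers: tuple = ()
    n_obs: int = 0


def _crit_value(df: pd.DataFrame, nesting: list[str], n_fixed: int,
                kind: str) -> float:
    """95% critical value for fixed-effect CIs.

    Group-level t quantile with df = (#top-level units - #fixed effects):
    the large-sample normal value undercovers at cohort-scale group counts
    (checked by simulation), while the group-level t restores nominal
    coverage.  Falls back to the normal value when df is large or the model
    degenerates to OLS on many observations.
    """
    if kind == "ols" or not nesting:
        return 1.96
    n_groups = df[nesting[0]].nunique()
    dof = max(n_groups - n_fixed, 1)
    return float(sps.t.ppf(0.975, dof))


def _prepare_nesting(df: pd.DataFrame, nesting: list[str]):
    """Drop tiers with a single level; return (usable tiers, dropped)."""
    usable, dropped = [], []
    for tier in nesting:
        if df[tier].nunique() > 1:
            usable.append(tier)
        else:
            dropped.append(tier)
            warnings.warn(f"nesting tier {tier!r} has a single level; dropped")
    return usable, dropped


def _mixed_fit(df: pd.DataFrame, fixed: str, nesting: list[str]):
    """REML random-intercept fit with nested tiers.

    The first usable tier becomes the grouping factor; deeper tiers enter as
    nested variance components.  With no usable tier the model reduces to
    OLS on the fixed effects.
    """
    usable, dropped = _prepare_nesting(df, nesting)
    if not usable:
        res = smf.ols(fixed, df).fit()
        return res, {}, dropped, "ols"
    top = usable[0]
    vc = {}
    key = None
    for tier in usable[1:]:
        key = tier if key is None else f"{key}_{tier}"
        df = df.copy()
        df[f"_vc_{key}"] = df[usable[0]].astype(str)
        for t2 in usable[1:usable.index(tier) + 1]:
            df[f"_vc_{key}"] = df[f"_vc_{key}"] + ":" + df[t2].astype(str)
        vc[key] = f"0 + C(_vc_{key})"
    model = smf.mixedlm(fixed, df, groups=df[top],
                        vc_formula=vc if vc else None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
    vcomp = {top: float(res.cov_re.iloc[0, 0]) if res.cov_re.size else 0.0}
    if vc:
        for i, name in enumerate(model.exog_vc.names):
            vcomp[name] = float(res.vcomp[i])
    return res, vcomp, dropped, "mixed"


def fit_bin(values: np.ndarray, nesting_keys: pd.DataFrame,
            nesting: list[str] | None = None) -> HierarchicalFit:
    """Random-intercept estimate of the bin mean with a 95% CI.

    ``nesting_keys`` carries one column per tier, outermost first (e.g.
    mouse, fov, vessel); trials are the residual level.  Equal-weighting of
    top-level units follows from the random-intercept structure: with
    between-mouse variance dominating, the estimate tends to the mean of
    mouse means rather than the pooled-observation mean.
    """
    df = nesting_keys.copy()
    df["y"] = np.asarray(values, dtype=float)
    if len(df) == 0:
        raise ValueError("bin is empty")
    nesting = list(nesting if nesting is not None else nesting_keys.columns)
    if np.allclose(df["y"], df["y"].iloc[0]):
        v = float(df["y"].iloc[0])
        return HierarchicalFit(beta00=v, ci=(v, v), se=0.0,
                               variance_components={k: 0.0 for k in nesting},
                               residual_var=0.0, nesting=tuple(nesting),
                               n_obs=len(df))
    res, vcomp, dropped, kind = _mixed_fit(df, "y ~ 1", nesting)
    beta = float(res.params.get("Intercept", res.params.iloc[0]))
    se = float(res.bse.get("Intercept", res.bse.iloc[0]))
    crit = _crit_value(df, nesting, n_fixed=1, kind=kind)
    ci = (beta - crit * se, beta + crit * se)
    resid_var = float(res.scale) if kind == "mixed" else float(res.mse_resid)
    return HierarchicalFit(beta00=beta, ci=ci, se=se,
                           variance_components=vcomp, residual_var=resid_var,
                           nesting=tuple(nesting), dropped_tiers=tuple(dropped),
                           n_obs=len(df))


def genotype_contrast(values: np.ndarray, genotype: np.ndarray,
                      nesting_keys: pd.DataFrame,
                      diameter_deviation: np.ndarray | None = None,
                      nesting: list[str] | None = None) -> HierarchicalFit:
    """Genotype coefficient (with CI and p) from the pooled model.

    Adds a genotype indicator fixed effect, optionally a slope for baseline
    diameter expressed as deviation from the across-mice mean.  A diameter
    covariate collinear with genotype is dropped with a warning.
    """
    df = nesting_keys.copy()
    df["y"] = np.asarray(values, dtype=float)
    g = pd.Series(genotype).astype("category")
    if g.nunique() < 2:
        raise ValueError("both genotypes must be present")
    df["geno"] = (g == g.cat.categories[-1]).astype(float).to_numpy()
    fixed = "y ~ geno"
    if diameter_deviation is not None:
        dev = np.asarray(diameter_deviation, dtype=float)
        corr = np.corrcoef(dev, df["geno"])[0, 1] if dev.std() > 0 else 1.0
        if dev.std() == 0 or abs(corr) > 0.999:
            warnings.warn("diameter covariate collinear with genotype; dropped")
        else:
            df["diam"] = dev - dev.mean()
            fixed += " + diam"
    nesting = list(nesting if nesting is not None else nesting_keys.columns)
    res, vcomp, dropped, kind = _mixed_fit(df, fixed, nesting)
    coef = float(res.params["geno"])
    se_g = float(res.bse["geno"])
    p_g = float(res.pvalues["geno"])
    beta = float(res.params.get("Intercept", res.params.iloc[0]))
    se = float(res.bse.get("Intercept", res.bse.iloc[0]))
    n_fixed = 2 + ("diam" in fixed)
    crit = _crit_value(df, nesting, n_fixed=n_fixed, kind=kind)
    return HierarchicalFit(
        beta00=beta, ci=(beta - crit * se, beta + crit * se), se=se,
        variance_components=vcomp,
        residual_var=float(res.scale) if kind == "mixed" else float(res.mse_resid),
        nesting=tuple(nesting), genotype_coef=coef,
        genotype_ci=(coef - crit * se_g, coef + crit * se_g), genotype_p=p_g,
        diameter_slope=float(res.params.get("diam", np.nan)),
        dropped_tiers=tuple(dropped), n_obs=len(df))


@dataclass
class BootstrapBand:
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    n_boot: int
    single_unit: bool = False


def hierarchical_bootstrap(trajectories: np.ndarray, mouse_ids: np.ndarray,
                           n_boot: int = 1000, seed: int = 0) -> BootstrapBand:
    """Mean trajectory with a pointwise 95% band from a two-stage bootstrap.

    Resamples mice with replacement, then trials within each sampled mouse
    with replacement; the band is the 2.5/97.5 percentile envelope of the
    replicate mean trajectories.  Deterministic for a fixed seed.  A single
    top-level unit is flagged (within-mouse resampling only).
    """
    traj = np.atleast_2d(np.asarray(trajectories, dtype=float))
    mouse_ids = np.asarray(mouse_ids)
    if len(mouse_ids) != traj.shape[0]:
        raise ValueError("one mouse id per trajectory required")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable confidence bands")
    mice = np.unique(mouse_ids)
    single = len(mice) < 2
    rng = np.random.default_rng(seed)
    idx_by_mouse = {m: np.nonzero(mouse_ids == m)[0] for m in mice}
    reps = np.empty((n_boot, traj.shape[1]))
    for b in range(n_boot):
        picked = rng.choice(mice, size=len(mice), replace=True)
        rows = []
        for m in picked:
            pool = idx_by_mouse[m]
            rows.append(rng.choice(pool, size=len(pool), replace=True))
        rows = np.concatenate(rows)
        reps[b] = traj[rows].mean(axis=0)
    lo, hi = np.percentile(reps, [2.5, 97.5], axis=0)
    return BootstrapBand(mean=traj.mean(axis=0), lo=lo, hi=hi,
                         n_boot=n_boot, single_unit=single)


def assign_distance_bins(distances_um: np.ndarray,
                         edges: tuple = DISTANCE_BINS_UM) -> np.ndarray:
    """Distance-from-activity bin label per observation ("<1", "1-400", ...).
    Blank-trial pooling (a single bin irrespective of position) is handled by
    the caller tagging blank observations."""
    d = np.asarray(distances_um, dtype=float)
    edges = list(edges)
    names = ["<1"] + [f"{int(a)}-{int(b)}" for a, b in zip(edges[1:-1], edges[2:])]
    out = np.empty(len(d), dtype=object)
    for i, x in enumerate(d):
        j = np.searchsorted(edges, x, side="right") - 1
        out[i] = names[min(max(j, 0), len(names) - 1)]
    return out
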