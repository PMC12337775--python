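# vasodyn

Quantification of vasodilation propagation during neurovascular coupling,
from raw dual-channel widefield / two-photon movies to vessel dilation
trajectories, propagation velocity, spatial decay constants, gap-junction
coupling indices, and hierarchical genotype contrasts — together with a
synthetic-movie generator with known ground truth, so that every stage of
the pipeline is verifiable by parameter recovery.

## The problem

When neurons fire, nearby arterioles dilate within hundreds of
milliseconds, and the dilation travels millimetres along the pial arterial
network to recruit upstream supply — a process mediated by endothelial gap
junctions. Quantifying it from imaging data requires a chain of delicate
steps: extracting vessel width and blood content (HbT, from 530 nm
intrinsic optical signal) along centerlines, filtering trajectories
contaminated by spontaneous vasomotion and behavioral state, and turning
trial-averaged dilation time courses into physical parameters.

The two headline estimators are:

* **Propagation velocity.** ΔHbT/HbT is measured every 45 µm along an
  artery; each position's trial-averaged trajectory is fitted with a
  sigmoid y(t) = a + b/(1 + e^((c−t)/d)); onset is where the fit reaches
  10% of its amplitude (closed form c − d·ln 9); and the velocity is the
  inverse slope of the straight line through onset versus distance.
* **Decay length λ.** Peak dilation versus distance from neural activity is
  fitted with A·e^(−x/λ) + floor, the floor fixed to the blank-trial level.

Because these quantities come from live-animal experiments, correctness is
established here by closing the loop: the `synthgen` module renders movies
from a known dilation wave — D(x,t) = D₀·(1 + A₀ e^(−x/λ) g(t − t₀ − x/v))
plus coherent band-limited vasomotion and photon noise — and the pipeline
must recover v, λ, onset times, widths, and behavioral slopes from the
pixels alone. See `docs/methods.md` for the full model and estimator
details.

## Worked example

Recover the propagation velocity of a known 4.13 mm/s dilation wave from
rendered IOS movies (one synthetic animal = one 2.1 mm artery, 30 trials):

```python
import vasodyn as vd

rec = vd.velocity_recovery_experiment(v_mm_s=4.13, d_rise_s=0.25, seed=1)
print(f"recovered {rec.fit.velocity_mm_s:.2f} mm/s "
      f"from {rec.n_positions} positions "
      f"({rec.excluded_trials} trials excluded by QC)")
```

```
recovered 3.49 mm/s from 47 positions (4 trials excluded by QC)
```

The wave truly travelled at 4.13 mm/s; a single synthetic animal reads it
back off the movie to within ~15% — the residual is coherent vasomotion
noise surviving the 30-trial average, the same effect that limits single-
animal estimates in real recordings. A cohort of animals gives the
dispersion-aware estimate (per-animal inverse-slope velocities, plus the
cohort speed from the mean onset-versus-distance slope):

```python
cohort = vd.velocity_recovery_cohort(4.13, 0.25, seed=1, n_mice=6)
print(cohort.per_mouse_mm_s.round(2),
      round(cohort.speed_mm_s, 2), round(cohort.mean_mm_s, 2))
```

```
[4.03 4.11 5.55 3.3  5.02 3.03] 3.99 4.17
```

Numbered drivers under `analysis/` run the full narrative — simulate the
two-genotype cohort (control vs gap-junction-deficient parameters), extract
trajectories, recover velocities and decay lengths, compute distance-binned
statistics and coupling indices, and render a report — writing their tables
under `results/`.

The `vasodyn` CLI exposes the same stages
(`vasodyn simulate|quantify|kinetics|coupling|stats|report`).

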