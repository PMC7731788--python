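# csfflow

Particle-tracking velocimetry for embryonic cerebrospinal-fluid (CSF) flow.

Time-lapse cross-sectional movies of fluid-filled brain ventricles — for
example OCT B-scan sequences of *Xenopus* tadpole brains at 30 frames/s —
show sparse bright tracer particles (endogenous particles or injected
polystyrene microbeads) advected by cilia-driven CSF currents.  `csfflow`
turns such movies into quantitative, per-compartment flow maps.  It is aimed
at developmental-biology and ciliopathy labs that image ventricular flow and
need reproducible compartmental speed statistics rather than a GUI.

## Method

The velocimetry chain has three stages:

1. **Detection + linking.**  Particles are detected per frame by
   scale-matched Laplacian-of-Gaussian filtering (σ = r/√2 for blob radius
   r) with sub-pixel localization, then linked into trajectories frame to
   frame by solving the rectangular linear assignment problem with squared
   Euclidean cost c_ij = ‖x_i − x_j‖², distance-pruned candidates, a
   per-particle "no-link" alternative and a second global assignment pass
   that closes gaps of up to a few missed frames ("simple LAP" semantics —
   no splits or merges).
2. **Windowed weighted least squares.**  Each trajectory is partitioned into
   roughly half-second windows; in each window independent weighted linear
   regressions of x(t) and y(t) give one velocity vector
   v = (β̂_x, β̂_y),  β̂ = Σwᵢ(tᵢ−t̄)zᵢ / Σwᵢ(tᵢ−t̄)²,
   with the window's weight 1/(1 + RMS residual / pixel size).
3. **Gaussian-process regression.**  Each velocity component is modelled as
   a scalar GP over position with an isotropic squared-exponential kernel
   k(x, x′) = σ_f² exp(−‖x−x′‖²/2ℓ²) plus observation noise σ_n²/wᵢ;
   hyperparameters maximize the log marginal likelihood.  The posterior mean
   evaluated at every ROI pixel is the dense velocity field, and the
   posterior standard deviation is its per-pixel uncertainty map.

A compartment's summary statistic is the **median speed**: the median of
the vector norms collected over the compartment (dense-field pixels by
default).  Compartmental cross-sectional areas come from label-mask pixel
counts.  Pre/post comparisons use the Wilcoxon matched-pairs signed-rank
test and unpaired group comparisons the Mann–Whitney U test, both two-sided
with significance at p < 0.01 and exact small-sample distributions.
Temporal colour-coded polarity projections and line kymographs (with a
beat-frequency readout for ciliary motion) round out the toolbox.

Because raw in-vivo movies of this kind are rarely deposited, the package
ships a first-class synthetic generator: compartmentalized recirculating
vortex scenes with calibrated median speeds, uniform and static controls,
zero-mean pulsatile components, particle turnover and speckle-like noise,
with exact ground-truth trajectories — so the whole chain is validated by
parameter recovery against known flow.

## Worked example

```python
import numpy as np
from csfflow import (CompartmentSpec, FlowSpec, simulate_movie, analyze_movie,
                     DetectionConfig, LinkingConfig)
from csfflow.geometry import circle_polygon
from csfflow.synthetic import label_mask_from_spec

comp = CompartmentSpec(
    label="IVp", region=circle_polygon((64, 64), 56.0),
    flow_model="vortex", polarity="counterclockwise",
    median_speed_target=33.2, center=(64, 64), radius=56.0,
)
spec = FlowSpec(compartments=[comp], image_shape=(64, 64), seed=7)
movie, truth = simulate_movie(spec)

labels, names = label_mask_from_spec(spec)
result = analyze_movie(
    movie, labels, names,
    detection=DetectionConfig(blob_radius_um=3.0),
    linking=LinkingConfig(max_link_distance_um=3.2),
    seed=7,
)
print(result.reports[["label", "n_tracks", "median_speed_um_s", "area_um2"]]
      .to_string(index=False))
```

Output:

```
label  n_tracks  median_speed_um_s  area_um2
  IVp       166          32.275734    9796.0
```

The posterior-fourth-ventricle compartment was simulated with a median
speed of 33.2 µm/s; the pipeline estimates 32.3 µm/s from 166 recovered
tracks — a 2.8% error — and reports the compartment's cross-sectional area
from the label mask.  `result.fields["IVp"]` holds the dense per-pixel
velocity, speed and uncertainty grids.

The same pipeline is available from the shell (`csfflow simulate | detect |
track | velocity | field | run | polarity | kymo | stats-paired |
stats-unpaired | accept`), reading multi-page TIFF movies with a JSON
calibration sidecar and writing CSV tables.

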