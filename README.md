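# quatsmooth

Smoothing and classification of **unit-quaternion time series** — the kind
produced by wearable inertial sensors that record body-segment orientation
during walking, one unit quaternion `q = (w, x, y, z) ∈ H₁` per time point.

Orientation data live on the 3-sphere, so Euclidean smoothers cannot be
applied directly. `quatsmooth` maps a series to `R³` through one of two
tangent-space transforms, smooths there with standard functional-data
machinery, and maps back:

* **logarithm transform** — `q_i ↦ log(q_i)`, the tangent vector at the
  identity; the whole series lives in one tangent space (the ball of
  radius π).  Inverted point-wise by the quaternion exponential.
* **angular-velocity transform** — `v_i = log(q_i⁻¹ q_{i+1}) / h`, a
  finite-difference velocity in the tangent space *at `q_i`* (ball of
  radius π/h).  Inverted by accumulating increments
  `q̃_{i+1} = q̃_i · exp(h v_i)` from the first quaternion.

Three smoother families operate on the transformed series:

* **wavelet shrinkage** — component-wise DWT, *vector* soft thresholding of
  the 3-vectors of detail coefficients (`w̄ = 0` if `‖w‖ ≤ t_p`, else
  `(1 − t_p/‖w‖) w`) at the universal threshold `t_p = σ̂ √(3 log N)` with
  `σ̂ = MAD(d₁)/0.6745` estimated from the pooled level-1 details;
* **Fourier projection** — unpenalized least squares onto a truncated
  Fourier basis (20/40/60 basis functions);
* **penalized splines** — degree 1/3/5 regression splines on 71 interior
  knots, roughness-penalty weight chosen per curve by GCV.

Whether a transform/smoother combination *helps* is judged by what it does
to class-discriminating structure: a 5-nearest-neighbour classifier with a
dynamic-time-warping distance (geodesic local cost on H₁), evaluated by
stratified 5-fold cross-validation as accuracy and AUC.  A synthetic-data
module generates two-class gait-like benchmark series with
Gaussian-process noise (`C(s,t) = α e^{−β|s−t|}`) added in log
coordinates, and a bootstrap logit regression summarizes a whole
evaluation grid.

## Worked example

```python
from quatsmooth import (generate_dataset, NoiseParams, SmootherConfig,
                        run_pipeline, cross_validate)

# 54 series (27 per class), 128 points, high-variance correlated noise
data = generate_dataset(noise=NoiseParams(alpha=0.1, beta=0.01), seed=42)

acc, auc = cross_validate(data, k=5, n_folds=5, seed=1)
print(f"no smoothing:        accuracy={acc:.3f}  AUC={auc:.3f}")

cfg = SmootherConfig(family="wavelet", wavelet_name="d4", decomposition_level=4)
for transform in ("logarithm", "angular_velocity"):
    acc, auc = run_pipeline(data, transform, cfg, cv_seed=1)
    print(f"{transform:<20} accuracy={acc:.3f}  AUC={auc:.3f}")
```

prints

```
no smoothing:        accuracy=0.527  AUC=0.575
logarithm            accuracy=0.527  AUC=0.549
angular_velocity     accuracy=0.563  AUC=0.574
```

At this noise level the classes are barely separable (accuracy ≈ 0.53
without smoothing) and a single smoother configuration may or may not
help on a single dataset — which is exactly why conclusions are drawn
from a replicated grid (`run_grid`) and its regression summary
(`bootstrap_regression`) rather than from single cells.

A command-line interface wraps the same functions:

```sh
quatsmooth generate out/ --alpha 0.01 --beta 0.01 --seed 1
quatsmooth evaluate records.csv --n-replicates 5 --seed 1
quatsmooth regress records.csv coefs.csv --target accuracy
```

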