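# raftrack

Quantitative image analysis for punctate membrane-receptor domains in
fluorescence time-lapse microscopy.  `raftrack` is built for the
question "did the treatment cluster and immobilise the receptor?": it
segments bright domains and measures their morphometrics (area, mean
brightness, count per cell), detects sub-pixel spot centers with an
à-trous wavelet transform, links them frame to frame by solving an
exact assignment problem under a speed cap with no gap closing,
computes per-track speeds and the linearity ratio *rho*, and compares
conditions with a permutation test for means.  A ground-truthed
simulator of diffusing vs. clustered receptor movies makes every stage
testable end to end.

## The statistics at the core

For a trajectory x₁ … x_N sampled every Δt seconds at p µm/px:

- **speed** = mean frame-to-frame step, ⟨‖x_{i+1} − x_i‖⟩ · p / (Δt/60)
  in µm/min;
- **rho** = ‖x_N − x₁‖ / Σᵢ ‖x_{i+1} − x_i‖ ∈ [0, 1]: rho ≈ 1 for
  linear directed motion, rho → 0 for confined or random motion.

Tracks must be gap-free, last over four frames (≥ 5 points), and — for
the rho analysis — move at least 1 px/frame on average (stationary
areas are excluded).  Frame-pair linking minimises total squared
displacement over all admissible assignments, a link being admissible
up to 42 µm/min; births and deaths cost 1.05 × cap².  Group
comparisons use a two-sided permutation test for the difference of
means (10 000 permutations, add-one correction; exact enumeration for
small samples).  The companion cholesterol-efflux utility implements
media counts / (cells + media counts) × 100.

## Worked example

Simulate one untreated (freely diffusing) and one treated (clustered,
confined) movie at the default acquisition settings (60 frames, 2 s
lapse, 0.16 µm/px) and compare the five endpoints:

```python
from raftrack import ExperimentConfig, SegmentationParams, SimConfig
from raftrack.pipeline import run_experiment

cfg = ExperimentConfig(
    condition_a=SimConfig(seed=0),
    condition_b=SimConfig(seed=1000),
    segmentation=SegmentationParams(threshold=70.0),
    segment_frames=[0, 1, 2, 3, 4],
    seed=0,
)
report = run_experiment(cfg)
print(report.summary())
```

```
raftrack 0.1.0 condition comparison: untreated vs treated
endpoint             n_a   n_b    median_a    median_b  diff_means         p
domain_area          192    88       0.384      0.4352     -0.1446 9.999e-05
domain_brightness    192    88        77.2       78.87      -18.09 9.999e-05
domains_per_cell      20    20         9.5           5         5.2 9.999e-05
speed                 60    20       7.548       6.156       1.347 9.999e-05
rho                   57    17      0.2019     0.08592      0.1189    0.0013
```

Reading the table: the treated condition has fewer domains per
pseudo-cell (5 vs 9.5 per tile-frame), and those domains are larger
(median 0.44 vs 0.38 µm²) and brighter; its tracks are slower (median
6.2 vs 7.5 µm/min) and markedly less linear (median rho 0.086 vs 0.20)
— the clustering-and-arrest phenotype.  `diff_means` is mean(untreated)
− mean(treated) and `p` its two-sided permutation p-value; n_a/n_b are
the per-endpoint sample sizes (domains, tile-frames, or tracks).

The same pipeline runs from the shell:

```sh
raftrack simulate --config cfg.yaml --out sim/ --condition clustered
raftrack compare  --config cfg.yaml --out results/
```

plus `segment`, `detect`, `track` and `dynamics` subcommands for
individual stages on any calibrated TIFF stack.

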