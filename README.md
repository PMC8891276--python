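# noisescore

Quantify the statistical distortion that lossy image compression induces
in supervised-learning segmentation predictions, in units of the
predictive uncertainty caused by the sensor's own noise.

## The problem

Micrographs are noisy: a pixel recorded under fixed illumination follows
a Poisson–Gaussian law with mean μ and width σ(μ) set by photon shot
noise and the camera's electronics. Any prediction χ of a segmentation
pipeline (an object count, a total area, a Feret diameter, …) therefore
carries an irreducible spread σ_raw. Compressing the data before
inference perturbs predictions too — but by how much, relative to that
noise floor?

`noisescore` implements a four-step audit:

1. **Calibrate** the sensor with a photon-transfer-curve fit of
   flat-field stacks: `var(μ) = gain·(μ − offset) + read_noise²`.
2. **Replicate**: from a single raw image, generate n statistically
   raw-equivalent images by redrawing every pixel from the calibrated
   law at its observed value.
3. **Segment and measure** the raw image, the replicas, and each
   compressed variant with one random-forest pixel classifier trained
   only on the raw image (variants are upsampled back to 16 bit first),
   then extract 19 per-object morphological parameters and the global
   metrics N_tot and A_tot (V_tot, SA_tot in 3-D).
4. **Score** each variant with the standard score

       ε = (χ_raw − χ_c) / σ_raw

   where σ_raw is the SD of χ over the replicas. |ε| < 1 marks the
   distortion as *tolerable*: smaller than the variability the sensor
   noise alone produces.

Three data-reduction routes are audited: 16→8-bit depth reduction
(exactly 2:1), baseline JPEG at a target ratio (quality found by
bisection), and an open *noise-preserving* codec that quantizes each
pixel with a step proportional to its calibrated noise and restores
seeded pseudo-random dither on decode — spending a fixed 1.2 dB of
per-pixel SNR to reach ≥5:1 lossless-backend ratios while mimicking the
raw statistics.

Everything runs on built-in synthetic phantoms (microsphere fields with
aggregates, confluent cells, 3-D nuclei volumes, and a projection/FBP
tomography stage), so no external data are needed.

## Worked example

```python
from noisescore import AuditConfig, CompressionSpec, phantom_audit

cfg = AuditConfig(
    seed=3, n_replicas=10,
    phantom={"kind": "spheres", "n": 80, "radius_px": 4,
             "size": (256, 256)},
    variants=[CompressionSpec("noise_preserving"),
              CompressionSpec("jpeg", target_ratio=10.0),
              CompressionSpec("jpeg", target_ratio=100.0),
              CompressionSpec("bitdepth8")])
report = phantom_audit(cfg)

nt = report.global_scores["n_tot"]
print("N_tot raw:", nt["chi_raw"], "sigma_raw:", round(nt["sigma_raw"], 2))
for name, e in nt["variants"].items():
    print(f"  {name:18s} chi_c={e['chi_c']:.0f}  eps={e['epsilon']:.1f}")
s = report.object_summary
print(s.groupby("variant")["mean_epsilon"].apply(lambda x: x.abs().mean()))
```

prints (numbers from this exact configuration):

```
N_tot raw: 50.0 sigma_raw: 0.67
  noise_preserving   chi_c=50  eps=0.0
  jpeg_10to1         chi_c=55  eps=-7.4
  jpeg_100to1        chi_c=53  eps=-4.4
  bitdepth8          chi_c=55  eps=-7.4
variant
bitdepth8           1.160356
jpeg_100to1         5.714960
jpeg_10to1          2.291790
noise_preserving    0.123765
```

Read: the noise-preserving codec leaves the object count untouched and
keeps the mean |ε| over the 19 object parameters at ~0.12 — well inside
the noise floor — while depth reduction and JPEG shift predictions by
several σ_raw, and harder JPEG compression distorts more.

A command-line interface wraps the same machinery:

```sh
noisescore phantom --kind spheres --seed 1 --out scratch/demo
noisescore compress --method noise --model scratch/demo/model.json \
    scratch/demo/raw.tif scratch/demo/raw.npq
noisescore calibrate --stacks flats/ --out model.json
noisescore audit config.yaml
```

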