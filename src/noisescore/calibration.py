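"""Sensor noise calibration via the photon transfer curve (PTC).

A camera under stabilized, spatially flat illumination produces pixel
values whose temporal mean mu and variance var are linked by

    var(mu) = gain * (mu - offset) + read_noise**2        [ADU^2]

The slope of the mean-variance relation is the gain (ADU per
photoelectron), the dark level is the offset, and the intercept at zero
flux is the read-noise variance.  Fitting this line over a ladder of
illumination levels is the standard photon-transfer calibration; the
fitted model then defines the per-pixel noise sigma(mu) used everywhere
else in the package.

Temporal (per-pixel, across frames) statistics are used so that
fixed-pattern non-uniformity does not inflate the variance estimate.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .exceptions import FitFailureError, InsufficientDataError
from .rng import sample_counts

FULL_SCALE = 65535
SATURATION_FRACTION = 0.9


@dataclass
class FlatFieldStack:
    """Repeated exposures of a spatially uniform illumination level."""

    frames: np.ndarray  # (n_frames, H, W), uint16
    illumination_label: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, H, W)")
        if self.frames.shape[0] < 2:
            raise InsufficientDataError("a flat-field stack needs >= 2 frames")
        if self.frames.min() < 0 or self.frames.max() > FULL_SCALE:
            raise ValueError("pixel values must lie in [0, 65535]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def temporal_mean(self) -> float:
        return float(self.frames.mean())

    def temporal_variance(self) -> float:
        """Mean per-pixel temporal variance (fixed pattern removed)."""
        return float(self.frames.var(axis=0, ddof=1).mean())

    @classmethod
    def from_tiff(cls, path: str | Path, illumination_label: int = 0
                  ) -> "FlatFieldStack":
        return cls(tifffile.imread(path), illumination_label)

    def to_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(path, self.frames.astype(np.uint16))


@dataclass
class NoiseModel:
    """Calibrated Poisson-Gaussian sensor model.

    sigma(mu) = sqrt(gain * max(mu - offset, 0) + read_noise**2)
    """

    gain: float            # ADU per photoelectron
    offset: float          # dark level, ADU
    read_noise: float      # electronic noise SD, ADU
    valid_range: tuple[float, float] = (0.0, float(FULL_SCALE))
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise FitFailureError(f"gain must be positive, got {self.gain}")
        if self.read_noise < 0 or self.offset < 0:
            raise ValueError("read_noise and offset must be non-negative")
        self.valid_range = (float(self.valid_range[0]),
                            float(self.valid_range[1]))

    def sigma(self, mean_value):
        """Noise SD at the given mean, clamped to the calibrated range."""
        mu = np.asarray(mean_value, dtype=np.float64)
        lo, hi = self.valid_range
        if np.any(mu < lo) or np.any(mu > hi):
            warnings.warn("mean outside calibrated range; clamping",
                          stacklevel=2)
        mu = np.clip(mu, lo, hi)
        var = self.gain * np.maximum(mu - self.offset, 0.0) + self.read_noise ** 2
        out = np.sqrt(var)
        return float(out) if np.isscalar(mean_value) else out

    def flux_from_counts(self, counts) -> np.ndarray:
        """Invert the mean forward model: photoelectrons from observed ADU."""
        v = np.asarray(counts, dtype=np.float64)
        return np.maximum(v - self.offset, 0.0) / self.gain

    def content_hash(self) -> str:
        payload = json.dumps([self.gain, self.offset, self.read_noise,
                              list(self.valid_range)], sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps({"gain": self.gain, "offset": self.offset,
                          "read_noise": self.read_noise,
                          "valid_range": list(self.valid_range),
                          "provenance": self.provenance}, indent=2)
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, source: str | Path) -> "NoiseModel":
        text = Path(source).read_text() if Path(str(source)).exists() \
            else str(source)
        d = json.loads(text)
        return cls(d["gain"], d["offset"], d["read_noise"],
                   tuple(d["valid_range"]), d.get("provenance", {}))


def noise_sigma(model: NoiseModel, mean_value):
    """Functional alias for :meth:`NoiseModel.sigma`."""
    return model.sigma(mean_value)


def fit_photon_transfer(stacks: list[FlatFieldStack]) -> NoiseModel:
    """Fit gain, offset and read noise from flat-field stacks.

    The darkest stack's mean fixes the offset; the remaining levels enter
    a weighted least-squares fit of temporal variance against
    (mean - offset).  Levels above 90% of full scale are discarded
    because clipping biases their variance downward.
    """
    if len(stacks) < 3:
        raise InsufficientDataError("need >= 3 illumination levels")
    means = np.array([s.temporal_mean() for s in stacks])
    variances = np.array([s.temporal_variance() for s in stacks])
    n_eff = np.array([s.n_frames * s.frames[0].size for s in stacks],
                     dtype=np.float64)

    keep = means <= SATURATION_FRACTION * FULL_SCALE
    if keep.sum() < 3:
        raise InsufficientDataError(
            "fewer than 3 unsaturated illumination levels")
    means, variances, n_eff = means[keep], variances[keep], n_eff[keep]

    if np.all(variances == 0):
        raise FitFailureError("all stacks have zero temporal variance")

    offset = float(means.min())
    x = means - offset
    # var(sample variance) ~ 2 sigma^4 / n_eff  ->  weights 1/that
    w = n_eff / (2.0 * np.maximum(variances, 1e-12) ** 2)
    sw, swx, swy = w.sum(), (w * x).sum(), (w * variances).sum()
    swxx, swxy = (w * x * x).sum(), (w * x * variances).sum()
    denom = sw * swxx - swx ** 2
    if denom <= 0:
        raise FitFailureError("degenerate illumination ladder")
    gain = (sw * swxy - swx * swy) / denom
    intercept = (swy - gain * swx) / sw
    if gain <= 0:
        raise FitFailureError(f"non-positive fitted gain {gain:.4g}")
    read_noise = float(np.sqrt(max(intercept, 0.0)))
    return NoiseModel(
        gain=float(gain), offset=offset, read_noise=read_noise,
        valid_range=(float(means.min()), float(means.max())),
        provenance={"n_levels": int(len(means)),
                    "level_means": [float(m) for m in means]})


def simulate_sensor(truth_flux: np.ndarray, model: NoiseModel, seed: int,
                    stream: int = 0,
                    origin: tuple[int, ...] | None = None) -> np.ndarray:
    """Forward model: photoelectron flux -> noisy 16-bit counts.

    Deterministic given (seed, stream); see :mod:`noisescore.rng`.
    """
    return sample_counts(truth_flux, model.gain, model.offset,
                         model.read_noise, seed=seed, stream=stream,
                         origin=origin)


def simulate_flat_stacks(model: NoiseModel, flux_levels, n_frames: int = 50,
                         shape: tuple[int, int] = (64, 64), seed: int = 0
                         ) -> list[FlatFieldStack]:
    """Simulate a calibration ladder (one stack per photoelectron level)."""
    stacks = []
    for lvl, flux in enumerate(flux_levels):
        frames = np.stack([
            simulate_sensor(np.full(shape, float(flux)), model,
                            seed=seed, stream=lvl * 100000 + k)
            for k in range(n_frames)])
        stacks.append(FlatFieldStack(frames, illumination_label=lvl))
    return stacks


@dataclass
class NoiseDiagnostics:
    """Single-pixel relative-error diagnostics of a repeat stack."""

    samples: np.ndarray         # RE per frame
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    running_sd: np.ndarray      # SD of RE over the first k samples

    def __post_init__(self) -> None:
        assert int(self.hist_counts.sum()) == self.samples.size


def relative_error_diagnostics(stack: FlatFieldStack,
                               pixel: tuple[int, int],
                               bins: int = 20) -> NoiseDiagnostics:
    """Relative error RE_k = (x_k - mean) / mean at one pixel.

    Mirrors the usual single-pixel noise inspection: the RE histogram
    approximates the noise distribution scaled by the mean, and the
    running SD shows convergence with the number of samples.
    """
    series = stack.frames[(slice(None),) + tuple(pixel)].astype(np.float64)
    mean = series.mean()
    if mean == 0:
        raise ZeroDivisionError("zero mean at the selected pixel")
    re = (series - mean) / mean
    counts, edges = np.histogram(re, bins=bins)
    k = np.arange(1, re.size + 1)
    csum, csq = np.cumsum(re), np.cumsum(re ** 2)
    var = np.maximum(csq / k - (csum / k) ** 2, 0.0)
    return NoiseDiagnostics(re, counts, edges, np.sqrt(var))
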