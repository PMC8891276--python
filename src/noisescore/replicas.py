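"""Statistically raw-equivalent replicas and Monte-Carlo uncertainty.

A single raw micrograph is one draw from the sensor's noise law.  Given a
calibrated :class:`~noisescore.calibration.NoiseModel`, each observed
pixel value v is taken as the estimate of its own latent mean, and a new
value is drawn from the Poisson-Gaussian law at that mean.  Repeating
this n times yields n replicas that share the raw image's statistics;
propagating them through any prediction pipeline gives the spread
sigma_raw attributable to sensor noise alone, exactly as in a
Monte-Carlo simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .calibration import NoiseModel
from .exceptions import InsufficientDataError
from .rng import sample_counts


@dataclass
class RawImage:
    """A 16-bit micrograph (2-D) or stack (3-D) with provenance."""

    pixels: np.ndarray
    pixel_pitch: tuple[float, ...] | None = None
    provenance: str = ""
    origin: tuple[int, ...] | None = None  # absolute coordinate of [0, 0]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint16:
            raise TypeError("RawImage requires uint16 pixels")
        if self.pixels.ndim not in (2, 3):
            raise ValueError("RawImage must be 2-D or 3-D")
        if self.origin is None:
            self.origin = (0,) * self.pixels.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    def crop(self, *slices: slice) -> "RawImage":
        """Crop while tracking the absolute origin of the window."""
        starts = [s.indices(n)[0] for s, n in zip(slices, self.shape)]
        return RawImage(self.pixels[tuple(slices)].copy(),
                        pixel_pitch=self.pixel_pitch,
                        provenance=self.provenance,
                        origin=tuple(o + st for o, st in
                                     zip(self.origin, starts)))

    @classmethod
    def from_tiff(cls, path: str | Path) -> "RawImage":
        arr = tifffile.imread(path)
        return cls(arr.astype(np.uint16), provenance=str(path))

    def to_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(path, self.pixels)


@dataclass
class ReplicaSet:
    """n raw-equivalent images regenerable from (source, model, seed)."""

    source: RawImage
    model: NoiseModel
    replicas: list[np.ndarray] = field(default_factory=list)
    n: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        assert self.n == len(self.replicas)
        for r in self.replicas:
            assert r.shape == self.source.shape and r.dtype == np.uint16

    def __iter__(self):
        return iter(self.replicas)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.replicas[i]

    def to_tiff(self, path: str | Path) -> None:
        path = Path(path)
        tifffile.imwrite(path, np.stack(self.replicas))
        manifest = {"seed": self.seed, "n": self.n,
                    "model_hash": self.model.content_hash()}
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def generate_raw_equivalent(raw: RawImage, model: NoiseModel, n: int = 10,
                            seed: int = 0) -> ReplicaSet:
    """Generate n statistically raw-equivalent images.

    Each replica replaces every pixel value with a fresh draw from the
    calibrated Poisson-Gaussian law whose mean is the observed value
    (latent flux = max(v - offset, 0) / gain, the same forward model as
    ``simulate_sensor``).  Replicas are mutually independent streams of
    one counter-based generator, so the set is reproducible bit-exactly
    from (seed, n) and commutes with cropping when the crop origin is
    carried on the :class:`RawImage`.

    The default n = 10 is the replica count used throughout the audit.
    """
    if n < 1:
        raise ValueError("replica count must be >= 1")
    flux = model.flux_from_counts(raw.pixels)
    reps = [sample_counts(flux, model.gain, model.offset, model.read_noise,
                          seed=seed, stream=i, origin=raw.origin)
            for i in range(n)]
    return ReplicaSet(source=raw, model=model, replicas=reps, n=n, seed=seed)


def predictive_uncertainty(values) -> tuple[float, float]:
    """Monte-Carlo center and spread of a prediction over replicas.

    Returns ``(mean, sigma_raw)`` where sigma_raw is the sample standard
    deviation with the n-1 denominator.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise InsufficientDataError("need >= 2 replica predictions")
    return float(v.mean()), float(v.std(ddof=1))
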