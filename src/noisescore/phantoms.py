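"""Synthetic ground-truth scenes and a projection/FBP tomography stage.

The phantoms stand in for the three imaging regimes the audit targets:
phase-contrast-like fields of small bright microspheres (with
aggregates), confluent textured cells, and 3-D stacks of nuclei over a
smooth anatomy background.  Each scene carries a noiseless
photoelectron flux map plus a ground-truth label mask, so the whole
pipeline — sensor simulation, replica generation, compression,
segmentation, morphometry and scoring — runs end to end without any
external data.

Default flux levels put the foreground at shot-noise SNR ~ 10 and the
background at SNR ~ 3, typical of fluorescence/phase-contrast
micrographs at moderate exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as sk_label
from skimage.transform import iradon, radon

from .exceptions import InsufficientDataError, PackingError
from .segmentation import AnnotationSet

BACKGROUND_FLUX = 9.0    # e-, shot-noise SNR 3
FOREGROUND_FLUX = 100.0  # e-, shot-noise SNR 10


@dataclass
class Scene:
    """Noiseless ground truth: photoelectron flux plus label mask."""

    flux: np.ndarray
    labels: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.flux.shape == self.labels.shape
        assert np.all(self.flux >= 0)


def make_microsphere_scene(n: int = 200, radius_px: float = 4.0,
                           aggregation_prob: float = 0.3,
                           flux_levels: tuple[float, float] =
                           (BACKGROUND_FLUX, FOREGROUND_FLUX),
                           size: tuple[int, int] = (512, 512),
                           seed: int = 0) -> Scene:
    """Field of bright disks; some placed touching to form aggregates."""
    if n < 1 or radius_px < 1:
        raise ValueError("need n >= 1 and radius >= 1")
    rng = np.random.default_rng(seed)
    h, w = size
    margin = radius_px + 2
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n:
        attempts += 1
        if attempts > 200 * n:
            raise PackingError("could not place all microspheres")
        if centers and rng.random() < aggregation_prob:
            base = centers[rng.integers(len(centers))]
            ang = rng.uniform(0, 2 * np.pi)
            c = (base[0] + 2 * radius_px * np.sin(ang),
                 base[1] + 2 * radius_px * np.cos(ang))
        else:
            c = (rng.uniform(margin, h - margin),
                 rng.uniform(margin, w - margin))
        if not (margin <= c[0] <= h - margin and margin <= c[1] <= w - margin):
            continue
        centers.append(c)
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros(size, dtype=bool)
    for cy, cx in centers:
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px ** 2
    bg, fg = flux_levels
    flux = np.where(mask, fg, bg).astype(np.float64)
    labels = sk_label(mask, connectivity=2)
    return Scene(flux, labels, {
        "kind": "microspheres", "n": n, "radius_px": radius_px,
        "aggregation_prob": aggregation_prob, "seed": seed})


def make_cell_scene(confluence: float = 0.4, texture_scale: float = 12.0,
                    size: tuple[int, int] = (512, 512),
                    seed: int = 0) -> Scene:
    """Dense smoothed random-blob cells with textured interiors."""
    if not 0 < confluence < 1:
        raise ValueError("confluence must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    field_ = ndi.gaussian_filter(rng.normal(size=size), texture_scale)
    thresh = np.quantile(field_, 1.0 - confluence)
    mask = field_ > thresh
    texture = ndi.gaussian_filter(rng.normal(size=size), texture_scale / 4)
    texture = (texture - texture.min()) / np.ptp(texture)
    flux = np.where(mask,
                    FOREGROUND_FLUX * (0.7 + 0.6 * texture),
                    BACKGROUND_FLUX)
    return Scene(flux, sk_label(mask, connectivity=2), {
        "kind": "cells", "confluence": confluence,
        "texture_scale": texture_scale, "seed": seed})


def make_nuclei_volume(n_nuclei: int = 40, radius: float = 3.0,
                       size3d: tuple[int, int, int] = (64, 128, 128),
                       seed: int = 0) -> Scene:
    """3-D Gaussian-profile nuclei inside a smooth anatomy background.

    Ground-truth classes: 0 background, 1 anatomy, 2 nuclei.  A nucleus
    voxel is one where the Gaussian profile exceeds half its peak.
    """
    rng = np.random.default_rng(seed)
    d, h, w = size3d
    zz, yy, xx = np.mgrid[0:d, 0:h, 0:w].astype(np.float64)
    # ellipsoidal anatomy occupying the central region
    cz, cy, cx = d / 2, h / 2, w / 2
    anat = ((zz - cz) / (0.42 * d)) ** 2 + ((yy - cy) / (0.42 * h)) ** 2 \
        + ((xx - cx) / (0.42 * w)) ** 2 <= 1.0
    centers = []
    attempts = 0
    # overlapping Gaussian tails sum: profiles closer than ~3.3 r merge
    # above the half-max threshold, so keep 4 r between centers
    min_sep = 4.0 * radius
    while len(centers) < n_nuclei:
        attempts += 1
        if attempts > 500 * n_nuclei:
            raise PackingError("could not pack nuclei inside the anatomy")
        c = np.array([rng.uniform(0.2 * d, 0.8 * d),
                      rng.uniform(0.2 * h, 0.8 * h),
                      rng.uniform(0.2 * w, 0.8 * w)])
        if not anat[tuple(c.astype(int))]:
            continue
        if centers and np.min(np.linalg.norm(
                np.array(centers) - c, axis=1)) < min_sep:
            continue
        centers.append(c)
    nuc_flux = np.zeros(size3d)
    for c in centers:
        r2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        nuc_flux += np.exp(-r2 / (2 * radius ** 2))
    labels = np.zeros(size3d, dtype=np.int32)
    labels[anat] = 1
    labels[nuc_flux > 0.5] = 2  # above half of the unit peak
    flux = BACKGROUND_FLUX + 0.25 * FOREGROUND_FLUX * anat \
        + FOREGROUND_FLUX * nuc_flux
    return Scene(flux, labels, {
        "kind": "nuclei", "n_nuclei": n_nuclei, "radius": radius,
        "seed": seed, "centers": [list(map(float, c)) for c in centers]})


def make_annotations(scene: Scene, fraction: float = 0.05,
                     seed: int = 0, margin: int = 1) -> AnnotationSet:
    """Programmatic training scribbles from the ground truth.

    Foreground pixels are sampled from the eroded true objects and
    background pixels from the eroded complement (equivalently, the
    complement of the dilated foreground), so no annotation touches a
    true boundary.  Class counts are balanced.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    class_ids = sorted(set(np.unique(scene.labels)) | {0})
    multiclass = scene.labels.max() > 1 and scene.params.get("kind") == "nuclei"
    if multiclass:
        regions = {cid: scene.labels == cid for cid in class_ids}
        names = ("background", "anatomy", "nuclei")
    else:
        regions = {0: scene.labels == 0, 1: scene.labels > 0}
        names = ("background",
                 "cell" if scene.params.get("kind") != "nuclei" else "nuclei")
    struct = ndi.generate_binary_structure(scene.labels.ndim, 1)
    eroded = {}
    for cid, region in regions.items():
        er = ndi.binary_erosion(region, struct, iterations=margin)
        if not er.any():
            raise InsufficientDataError(
                f"erosion emptied class {cid}; enlarge the scene")
        eroded[cid] = er
    n_per_class = max(1, int(fraction * min(e.sum() for e in eroded.values())))
    out = np.zeros(scene.labels.shape, dtype=np.uint8)
    for class_idx, cid in enumerate(sorted(eroded), start=1):
        flat = np.flatnonzero(eroded[cid].ravel())
        pick = rng.choice(flat, size=min(n_per_class, flat.size),
                          replace=False)
        out.ravel()[pick] = class_idx
    return AnnotationSet(out, class_names=names)


@dataclass
class Sinogram:
    """Parallel-beam projections: (n_angles, detector bins)."""

    projections: np.ndarray
    angles: np.ndarray  # degrees, strictly increasing in [0, 360)

    def __post_init__(self) -> None:
        if len(self.angles) < 2:
            raise ValueError("need >= 2 projection angles")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")


def project(image: np.ndarray, angles: np.ndarray) -> Sinogram:
    """Discrete Radon transform (line integrals, linear interpolation)."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("projection expects a square 2-D slice")
    angles = np.asarray(angles, dtype=np.float64)
    sino = radon(image, theta=angles)  # (detector, n_angles)
    return Sinogram(sino.T.copy(), angles)


def reconstruct(sino: Sinogram) -> np.ndarray:
    """Filtered back projection: ramp filter, linear back-interpolation.

    The reconstruction is supported on the inscribed circle of the
    original square slice.
    """
    return iradon(sino.projections.T, theta=sino.angles,
                  filter_name="ramp", interpolation="linear", circle=True)
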