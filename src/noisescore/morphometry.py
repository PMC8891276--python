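"""Morphometric measurement of segmented objects and object matching.

Per 2-D object, the 19 classic particle-analysis parameters are
measured: area, center of mass (X_CM, Y_CM), perimeter, major and minor
ellipse axes, ellipse angle, circularity, the Feret set (max Feret, its
start coordinates and angle, minimum Feret), aspect ratio, roundness,
solidity, Feret aspect ratio, compactness and extent.

Conventions (fixed for reproducibility):

* coordinates are 0-based pixel centers, X = column, Y = row;
* perimeter is the 4-direction Crofton estimate;
* Feret diameters are caliper distances on the convex hull of pixel
  *corners* (so a single pixel has Feret sqrt(2) and min Feret 1);
* angles are degrees in [0, 180), measured counter-clockwise from +X
  with Y pointing up (image rows increasing downwards);
* circularity 4*pi*A/P^2 is capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from scipy.spatial.distance import cdist
from skimage.measure import (marching_cubes, mesh_surface_area,
                             perimeter_crofton, regionprops)

from .exceptions import InsufficientDataError
from .segmentation import LabeledMask

#: the 19 per-object parameters, in report order
PARAMETER_NAMES = (
    "area", "x_cm", "y_cm", "perimeter", "major_axis", "minor_axis",
    "ellipse_angle", "circularity", "feret", "feret_x", "feret_y",
    "feret_angle", "min_feret", "aspect_ratio", "roundness", "solidity",
    "feret_aspect_ratio", "compactness", "extent")

#: parameters that live on a 180-degree circle; differences are wrapped
ANGLE_PARAMETERS = frozenset({"ellipse_angle", "feret_angle"})


@dataclass
class ObjectRecord:
    label: int
    area: float
    x_cm: float
    y_cm: float
    perimeter: float
    major_axis: float
    minor_axis: float
    ellipse_angle: float
    circularity: float
    feret: float
    feret_x: float
    feret_y: float
    feret_angle: float
    min_feret: float
    aspect_ratio: float
    roundness: float
    solidity: float
    feret_aspect_ratio: float
    compactness: float
    extent: float


_CORNER_OFFSETS = np.array([[-0.5, -0.5], [-0.5, 0.5],
                            [0.5, -0.5], [0.5, 0.5]])


def _pixel_corner_hull(coords: np.ndarray) -> np.ndarray:
    """Convex-hull vertices (row, col) of the pixel corner cloud."""
    corners = (coords[:, None, :] + _CORNER_OFFSETS[None, :, :]
               ).reshape(-1, 2)
    hull = ConvexHull(corners)
    return corners[hull.vertices]


def _feret_set(vertices: np.ndarray):
    """Max/min caliper diameters of a convex polygon (row, col vertices).

    The vertex count is small, so the max Feret uses all vertex pairs
    and the min Feret scans all edges (width = farthest vertex from the
    edge's supporting line).
    """
    d = cdist(vertices, vertices)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    feret = float(d[i, j])
    p, q = vertices[i], vertices[j]
    # start point: smaller column, then smaller row
    start, end = sorted((tuple(p), tuple(q)), key=lambda t: (t[1], t[0]))
    dy = -(end[0] - start[0])  # Y up
    dx = end[1] - start[1]
    feret_angle = float(np.degrees(np.arctan2(dy, dx)) % 180.0)
    min_feret = np.inf
    n = len(vertices)
    for e in range(n):
        a, b = vertices[e], vertices[(e + 1) % n]
        edge = b - a
        norm = np.hypot(*edge)
        if norm == 0:
            continue
        normal = np.array([-edge[1], edge[0]]) / norm
        width = np.abs((vertices - a) @ normal).max()
        min_feret = min(min_feret, float(width))
    return feret, float(start[1]), float(start[0]), feret_angle, min_feret


def measure_objects(labeled: LabeledMask | np.ndarray
                    ) -> list[ObjectRecord]:
    """Measure the 19 morphological parameters of every labeled object."""
    labels = labeled.labels if isinstance(labeled, LabeledMask) else labeled
    if labels.ndim != 2:
        raise ValueError("measure_objects is 2-D; see measure_objects_3d")
    records = []
    for prop in regionprops(labels):
        area = float(prop.area)
        perim = float(perimeter_crofton(prop.image, directions=4))
        major = float(prop.axis_major_length)
        minor = float(prop.axis_minor_length)
        circ = min(1.0, 4.0 * np.pi * area / perim ** 2) if perim > 0 else 1.0
        verts = _pixel_corner_hull(np.asarray(prop.coords, dtype=np.float64))
        feret, fx, fy, fangle, min_feret = _feret_set(verts)
        ellipse_angle = float(np.degrees(np.pi / 2 - prop.orientation)
                              % 180.0)
        eps = 1e-12
        records.append(ObjectRecord(
            label=int(prop.label), area=area,
            x_cm=float(prop.centroid[1]), y_cm=float(prop.centroid[0]),
            perimeter=perim, major_axis=major, minor_axis=minor,
            ellipse_angle=ellipse_angle, circularity=circ, feret=feret,
            feret_x=fx, feret_y=fy, feret_angle=fangle, min_feret=min_feret,
            aspect_ratio=major / max(minor, eps) if minor > 0 else np.nan,
            roundness=4.0 * area / (np.pi * major ** 2) if major > 0 else 1.0,
            solidity=float(prop.solidity),
            feret_aspect_ratio=feret / max(min_feret, eps),
            compactness=np.sqrt(4.0 * area / np.pi) / major if major > 0
            else 1.0,
            extent=float(prop.extent)))
    return records


def objects_frame(records: Sequence[ObjectRecord]) -> pd.DataFrame:
    """Object records as a tidy DataFrame (one row per object)."""
    cols = [f.name for f in fields(ObjectRecord)]
    return pd.DataFrame([[getattr(r, c) for c in cols] for r in records],
                        columns=cols)


def measure_objects_3d(labeled: LabeledMask | np.ndarray) -> pd.DataFrame:
    """Volume and centroid per 3-D object (for matching and Delta-V)."""
    labels = labeled.labels if isinstance(labeled, LabeledMask) else labeled
    rows = [{"label": int(p.label), "volume": float(p.area),
             "z_cm": float(p.centroid[0]), "y_cm": float(p.centroid[1]),
             "x_cm": float(p.centroid[2])} for p in regionprops(labels)]
    return pd.DataFrame(rows, columns=["label", "volume", "z_cm", "y_cm",
                                       "x_cm"])


@dataclass
class GlobalMetrics:
    """Whole-image segmentation summaries (the global chi parameters)."""

    n_tot: int
    a_tot: float | None = None   # 2-D total area, px
    v_tot: float | None = None   # 3-D total volume, voxels
    sa_tot: float | None = None  # 3-D total surface area

    def as_dict(self) -> dict[str, float]:
        out = {"n_tot": float(self.n_tot)}
        for k in ("a_tot", "v_tot", "sa_tot"):
            v = getattr(self, k)
            if v is not None:
                out[k] = float(v)
        return out


def global_metrics(labeled: LabeledMask | np.ndarray) -> GlobalMetrics:
    """N_tot and A_tot (2-D) or V_tot and SA_tot (3-D)."""
    labels = labeled.labels if isinstance(labeled, LabeledMask) else labeled
    n_tot = int(labels.max())
    fg = labels > 0
    if labels.ndim == 2:
        return GlobalMetrics(n_tot=n_tot, a_tot=float(fg.sum()))
    if not fg.any():
        return GlobalMetrics(n_tot=0, v_tot=0.0, sa_tot=0.0)
    padded = np.pad(fg, 1).astype(np.float64)
    verts, faces, _, _ = marching_cubes(padded, level=0.5)
    return GlobalMetrics(n_tot=n_tot, v_tot=float(fg.sum()),
                         sa_tot=float(mesh_surface_area(verts, faces)))


@dataclass
class MatchTable:
    """Raw-to-other object correspondence under the 3-pixel rule."""

    pairs: pd.DataFrame          # raw_label, other_label, distance, fallback
    unmatched: list[int]         # raw labels with no counterpart at all
    rejected: pd.DataFrame       # nearest neighbour farther than max_dist
    fallback_fraction: float     # retained pairs resolved by nearest-neighbor
    duplicate_other_labels: int  # other objects claimed by several raw ones


EXACT_MATCH_DIST = 0.5


def _centroids(objs) -> tuple[np.ndarray, np.ndarray]:
    df = objs if isinstance(objs, pd.DataFrame) else objects_frame(objs)
    cols = [c for c in ("z_cm", "y_cm", "x_cm") if c in df.columns]
    return df["label"].to_numpy(), df[cols].to_numpy(dtype=np.float64)


def match_objects(raw_objs, other_objs, max_dist: float = 3.0) -> MatchTable:
    """Match every raw object to its counterpart in another mask.

    An exact match (centroid distance < 0.5 px) wins when present;
    otherwise the nearest other-centroid is taken (ties broken by the
    smaller other label).  Pairs farther than ``max_dist`` pixels are
    rejected.  Matching is independent per raw object, so uniqueness of
    the other object is not enforced; duplicates are counted.
    """
    raw_labels, raw_xy = _centroids(raw_objs)
    other_labels, other_xy = _centroids(other_objs)
    if len(other_labels) == 0:
        return MatchTable(
            pairs=pd.DataFrame(columns=["raw_label", "other_label",
                                        "distance", "fallback"]),
            unmatched=list(map(int, raw_labels)),
            rejected=pd.DataFrame(columns=["raw_label", "other_label",
                                           "distance"]),
            fallback_fraction=0.0, duplicate_other_labels=0)
    d = cdist(raw_xy, other_xy)
    rows, rejected = [], []
    for i, rl in enumerate(raw_labels):
        di = d[i]
        exact = np.flatnonzero(di < EXACT_MATCH_DIST)
        if exact.size:
            j = exact[np.lexsort((other_labels[exact], di[exact]))[0]]
            fallback = False
        else:
            best = di.min()
            cands = np.flatnonzero(di == best)
            j = cands[np.argmin(other_labels[cands])]
            fallback = True
        rec = (int(rl), int(other_labels[j]), float(di[j]), fallback)
        if di[j] > max_dist:
            rejected.append(rec[:3])
        else:
            rows.append(rec)
    pairs = pd.DataFrame(rows, columns=["raw_label", "other_label",
                                        "distance", "fallback"])
    n_dup = 0 if pairs.empty else int(
        pairs["other_label"].duplicated().sum())
    frac = float(pairs["fallback"].mean()) if len(pairs) else 0.0
    return MatchTable(
        pairs=pairs, unmatched=[],
        rejected=pd.DataFrame(rejected, columns=["raw_label", "other_label",
                                                 "distance"]),
        fallback_fraction=frac, duplicate_other_labels=n_dup)


def wrap_angle_difference(delta):
    """Map a difference of 180-degree-periodic angles into [-90, 90)."""
    return (np.asarray(delta, dtype=np.float64) + 90.0) % 180.0 - 90.0


@dataclass
class DifferenceDistribution:
    """Per-pair Delta = raw - other for one parameter."""

    parameter: str
    deltas: np.ndarray
    mu: float
    sigma: float


def per_object_differences(matches: MatchTable, parameter: str,
                           raw_objs, other_objs) -> DifferenceDistribution:
    """Delta distribution of one parameter over the retained pairs."""
    if len(matches.pairs) == 0:
        raise InsufficientDataError("no retained matched pairs")
    raw_df = (raw_objs if isinstance(raw_objs, pd.DataFrame)
              else objects_frame(raw_objs)).set_index("label")
    other_df = (other_objs if isinstance(other_objs, pd.DataFrame)
                else objects_frame(other_objs)).set_index("label")
    a = raw_df.loc[matches.pairs["raw_label"], parameter].to_numpy()
    b = other_df.loc[matches.pairs["other_label"], parameter].to_numpy()
    delta = a - b
    if parameter in ANGLE_PARAMETERS:
        delta = wrap_angle_difference(delta)
    mu = float(np.nanmean(delta))
    sigma = float(np.nanstd(delta, ddof=1)) if delta.size > 1 else 0.0
    return DifferenceDistribution(parameter, delta, mu, sigma)
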