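"""End-to-end audit: calibrate -> replicate -> segment/measure -> score.

The audit protocol is strictly single-model: one random forest is
trained on the raw image alone, then applied unchanged to the raw
image, every raw-equivalent replica, and every decoded compressed
variant (8-bit and JPEG variants are upsampled back to 16 bit first).
The spread of predictions over the replicas is the raw predictive
uncertainty sigma_raw; predictions on variants are scored with
epsilon = (chi_raw - chi_c) / sigma_raw.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import NoiseModel, simulate_sensor
from .codecs import CompressionSpec, compress
from .exceptions import ConfigurationError
from .morphometry import (global_metrics, measure_objects,
                          measure_objects_3d, objects_frame,
                          per_object_differences, match_objects)
from .phantoms import (Sinogram, make_annotations, make_cell_scene,
                       make_microsphere_scene, make_nuclei_volume, project,
                       reconstruct)
from .replicas import RawImage, generate_raw_equivalent
from .scoring import (DistortionReport, global_parameter_report,
                      object_scores, operator_scores)
from .segmentation import (AnnotationSet, FeatureBank, LabeledMask,
                           compute_features, label_objects,
                           predict_probability, threshold_mask,
                           train_classifier, upsample_for_model)

PHANTOM_MAKERS = {"spheres": make_microsphere_scene,
                  "cells": make_cell_scene,
                  "nuclei": make_nuclei_volume}


@dataclass
class AuditConfig:
    """Declarative description of one audit run."""

    seed: int
    n_replicas: int = 10
    variants: list[CompressionSpec] = field(default_factory=list)
    phantom: dict = field(default_factory=lambda: {"kind": "spheres"})
    model: NoiseModel | None = None
    target_class: str | None = None
    threshold: float = 0.5
    annotation_fraction: float = 0.05
    compute_operator_scores: bool = False
    output_dir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "AuditConfig":
        d = dict(d)
        if "model" in d and isinstance(d["model"], dict):
            d["model"] = NoiseModel(**d["model"])
        elif "model" in d and isinstance(d["model"], str):
            d["model"] = NoiseModel.from_json(d["model"])
        if "variants" in d:
            d["variants"] = [CompressionSpec(**v) if isinstance(v, dict)
                             else v for v in d["variants"]]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AuditConfig":
        import yaml
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_model() -> NoiseModel:
    """The reference sensor used by all phantom studies.

    gain 2 ADU/e-, offset 100 ADU, read noise 3 ADU — a typical
    moderately amplified CMOS operating point.
    """
    return NoiseModel(gain=2.0, offset=100.0, read_noise=3.0,
                      valid_range=(100.0, 2100.0))


def normalize_volume(img: np.ndarray, clip: tuple[float, float] | None =
                     (0.1, 99.9)) -> np.ndarray:
    """Min-max normalize to the full 16-bit range, optional percentile clip."""
    arr = np.asarray(img, dtype=np.float64)
    if clip is not None:
        lo, hi = np.percentile(arr, clip)
    else:
        lo, hi = arr.min(), arr.max()
    if hi <= lo:
        warnings.warn("constant image; normalization is the identity",
                      stacklevel=2)
        return np.asarray(img).astype(np.uint16, copy=True)
    out = np.clip((arr - lo) / (hi - lo), 0.0, 1.0) * 65535.0
    return np.rint(out).astype(np.uint16)


def _segment(pixels: np.ndarray, classifier, bank: FeatureBank,
             target_class: str, threshold: float) -> LabeledMask:
    feats, _ = compute_features(pixels.astype(np.float64), bank)
    probs = predict_probability(classifier, feats)
    return label_objects(threshold_mask(probs, target_class, threshold))


def _measure(labeled: LabeledMask):
    if labeled.labels.ndim == 2:
        return objects_frame(measure_objects(labeled))
    return measure_objects_3d(labeled)


def audit_image(raw: RawImage, model: NoiseModel,
                annotations: AnnotationSet,
                variants: list[CompressionSpec],
                n_replicas: int = 10, seed: int = 0,
                target_class: str = "cell", threshold: float = 0.5,
                bank: FeatureBank | None = None,
                with_operator_scores: bool = False) -> DistortionReport:
    """Run the four-step audit on one raw image (2-D or 3-D)."""
    ndim = raw.pixels.ndim
    if bank is None:
        bank = FeatureBank.default_2d() if ndim == 2 \
            else FeatureBank.default_3d()

    feats, _ = compute_features(raw.pixels.astype(np.float64), bank)
    classifier = train_classifier(feats, annotations, seed=seed)
    probs = predict_probability(classifier, feats)
    raw_mask = label_objects(threshold_mask(probs, target_class, threshold))
    raw_table = _measure(raw_mask)
    raw_global = global_metrics(raw_mask)

    replicas = generate_raw_equivalent(raw, model, n=n_replicas, seed=seed)
    rep_masks = [_segment(r, classifier, bank, target_class, threshold)
                 for r in replicas]
    rep_tables = [_measure(m) for m in rep_masks]
    rep_globals = [global_metrics(m) for m in rep_masks]

    variant_masks, variant_tables, variant_globals = {}, {}, {}
    decoded_variants = {}
    for spec in variants:
        cv = compress(raw, spec, model)
        decoded = upsample_for_model(cv)
        decoded_variants[spec.name] = cv
        m = _segment(decoded.pixels, classifier, bank, target_class,
                     threshold)
        variant_masks[spec.name] = m
        variant_tables[spec.name] = _measure(m)
        variant_globals[spec.name] = global_metrics(m)

    glob = global_parameter_report(rep_globals, raw_global, variant_globals)

    eps, summary, n_dropped = object_scores(
        rep_tables, raw_table, variant_tables,
        min_replica_matches=min(5, n_replicas))

    size_param = "area" if ndim == 2 else "volume"
    deltas = {}
    for name, table in variant_tables.items():
        mt = match_objects(raw_table, table)
        if len(mt.pairs):
            dd = per_object_differences(mt, size_param, raw_table, table)
            deltas[name] = {"mu": dd.mu, "sigma": dd.sigma,
                            "parameter": size_param}
    for i, table in enumerate(rep_tables[:1]):
        mt = match_objects(raw_table, table)
        if len(mt.pairs):
            dd = per_object_differences(mt, size_param, raw_table, table)
            deltas["raw_equivalent"] = {"mu": dd.mu, "sigma": dd.sigma,
                                        "parameter": size_param}

    op_table = None
    if with_operator_scores:
        op_table = operator_scores(
            raw.pixels, list(replicas),
            {n: v.decoded_16bit for n, v in decoded_variants.items()},
            bank)

    return DistortionReport(
        global_scores=glob, object_summary=summary, object_epsilons=eps,
        delta_distributions=deltas, operator_table=op_table,
        n_dropped_objects=n_dropped,
        provenance={"seed": seed, "n_replicas": n_replicas,
                    "model_hash": model.content_hash(),
                    "classifier_hash": classifier.content_hash(),
                    "bank_hash": bank.content_hash(),
                    "variant_ratios": {n: v.achieved_ratio for n, v in
                                       decoded_variants.items()},
                    "connectivity": raw_mask.connectivity})


def replica_self_consistency(raw: RawImage, model: NoiseModel,
                             annotations: AnnotationSet,
                             n_replicas: int = 11, seed: int = 0,
                             target_class: str = "cell",
                             threshold: float = 0.5,
                             bank: FeatureBank | None = None) -> dict:
    """Score a held-out raw-equivalent replicate against the others.

    Generates ``n_replicas`` replicas, estimates per-object sigma_raw
    for the 19 parameters from all but the last, scores the held-out
    one with the standard score, and pools epsilon over objects and
    parameters.  By construction of the score the pooled distribution
    should have mean ~ 0 and SD ~ 1; this closes the loop on the whole
    audit machinery.
    """
    if bank is None:
        bank = FeatureBank.default_2d() if raw.pixels.ndim == 2 \
            else FeatureBank.default_3d()
    feats, _ = compute_features(raw.pixels.astype(np.float64), bank)
    classifier = train_classifier(feats, annotations, seed=seed)
    probs = predict_probability(classifier, feats)
    raw_table = _measure(
        label_objects(threshold_mask(probs, target_class, threshold)))
    replicas = generate_raw_equivalent(raw, model, n=n_replicas, seed=seed)
    tables = [_measure(_segment(r, classifier, bank, target_class,
                                threshold)) for r in replicas]
    eps, _, n_dropped = object_scores(
        tables[:-1], raw_table, {"held_out": tables[-1]},
        min_replica_matches=min(5, n_replicas - 1))
    vals = eps["epsilon"].dropna()
    return {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)),
            "n_scores": int(len(vals)),
            "n_objects": int(eps["raw_label"].nunique()),
            "n_dropped": n_dropped}


def phantom_audit(config: AuditConfig) -> DistortionReport:
    """Build the configured phantom, render it, and audit it."""
    model = config.model or default_model()
    kind = config.phantom.get("kind", "spheres")
    if kind not in PHANTOM_MAKERS:
        raise ConfigurationError(f"unknown phantom kind {kind!r}")
    params = {k: v for k, v in config.phantom.items() if k != "kind"}
    params.setdefault("seed", config.seed)
    scene = PHANTOM_MAKERS[kind](**params)
    raw = RawImage(simulate_sensor(scene.flux, model,
                                   seed=config.seed + 1_000_000),
                   provenance=f"phantom:{kind}")
    ann = make_annotations(scene, fraction=config.annotation_fraction,
                           seed=config.seed + 2)
    target = config.target_class or \
        ("cell" if kind in ("spheres", "cells") else "nuclei")
    report = audit_image(
        raw, model, ann, config.variants, n_replicas=config.n_replicas,
        seed=config.seed, target_class=target, threshold=config.threshold,
        with_operator_scores=config.compute_operator_scores)
    report.provenance["phantom"] = {**params, "kind": kind}
    return report


def run_audit(config: AuditConfig) -> DistortionReport:
    """Run an audit from a config, writing report files when requested."""
    t0 = time.time()
    report = phantom_audit(config)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "report.json")
        report.to_csv(out)
        manifest = {"config": {
            "seed": config.seed, "n_replicas": config.n_replicas,
            "phantom": config.phantom, "threshold": config.threshold,
            "variants": [{"method": v.method,
                          "target_ratio": v.target_ratio,
                          "seed": v.seed} for v in config.variants]},
            "provenance": report.provenance,
            "elapsed_s": round(time.time() - t0, 2)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=float))
    return report


def tomographic_operator_audit(slice_flux: np.ndarray, model: NoiseModel,
                               variants: list[CompressionSpec],
                               angles: np.ndarray, n_replicas: int = 10,
                               seed: int = 0,
                               bank: FeatureBank | None = None
                               ) -> pd.DataFrame:
    """Operator standard scores in projection and reconstruction space.

    The raw data are the *projections*: the scene slice is forward
    projected, the sinogram is rendered through the sensor model, and
    compression acts on the projection image.  Scores of each
    (operator, sigma) feature are then computed both on the projections
    and on the filtered-back-projection reconstructions.
    """
    bank = bank or FeatureBank.default_3d()  # the 4 smoothing-type operators
    sino = project(np.asarray(slice_flux, dtype=np.float64), angles)
    proj_flux = sino.projections / max(sino.projections.max(), 1e-12) * 100.0
    raw_proj = RawImage(simulate_sensor(proj_flux, model, seed=seed))
    reps = generate_raw_equivalent(raw_proj, model, n=n_replicas, seed=seed)

    def fbp(proj: np.ndarray) -> np.ndarray:
        return reconstruct(Sinogram(proj.astype(np.float64), angles))

    variant_projs = {}
    for spec in variants:
        cv = compress(raw_proj, spec, model)
        variant_projs[spec.name] = cv.decoded_16bit
    proj_bank = FeatureBank(bank.operators, bank.sigmas, ndim=2)
    table_p = operator_scores(raw_proj.pixels, list(reps), variant_projs,
                              proj_bank, space="projection")
    recon_raw = fbp(raw_proj.pixels)
    recon_reps = [fbp(r) for r in reps]
    recon_vars = {n: fbp(v) for n, v in variant_projs.items()}
    table_r = operator_scores(recon_raw, recon_reps, recon_vars, proj_bank,
                              space="reconstruction")
    return pd.concat([table_p, table_r], ignore_index=True)
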