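"""Standard scores: compression distortion in units of raw uncertainty.

For any prediction chi of a segmentation pipeline, the raw predictive
uncertainty sigma_raw is the spread of chi over statistically
raw-equivalent replicas.  A compressed variant's prediction chi_c is
scored with

    epsilon = (chi_raw - chi_c) / sigma_raw

and |epsilon| < 1 (strict) marks the distortion as tolerable: smaller
than the variability the sensor noise alone would produce.

Degenerate conventions when sigma_raw == 0: if the difference is also
zero the entry is "tolerable (degenerate)"; a nonzero difference over a
zero spread is "not tolerable (infinite score)".  Per-object scores use
only replicas in which the object was matched (at least 5 of 10 by
default); angle-valued parameters are compared on the 180-degree circle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ZeroUncertaintyError
from .morphometry import (ANGLE_PARAMETERS, PARAMETER_NAMES, GlobalMetrics,
                          match_objects, objects_frame,
                          wrap_angle_difference)
from .replicas import predictive_uncertainty
from .segmentation import FeatureBank, compute_features


def standard_score(chi_raw: float, chi_c: float, sigma_raw: float) -> float:
    """epsilon = (chi_raw - chi_c) / sigma_raw."""
    if sigma_raw == 0:
        raise ZeroUncertaintyError("sigma_raw is zero; score undefined")
    return (chi_raw - chi_c) / sigma_raw


def tolerability(epsilon: float) -> bool:
    """Tolerable iff |epsilon| < 1, strictly."""
    return bool(abs(epsilon) < 1.0)


def _scored_entry(chi_raw: float, chi_c: float, sigma_raw: float) -> dict:
    delta = chi_raw - chi_c
    if sigma_raw == 0:
        if delta == 0:
            return {"chi_c": chi_c, "epsilon": 0.0, "tolerable": True,
                    "degenerate": True}
        return {"chi_c": chi_c, "epsilon": None, "tolerable": False,
                "degenerate": True}
    eps = standard_score(chi_raw, chi_c, sigma_raw)
    return {"chi_c": chi_c, "epsilon": eps, "tolerable": tolerability(eps),
            "degenerate": False}


def global_parameter_report(replica_metrics: Sequence[GlobalMetrics],
                            raw: GlobalMetrics,
                            variants: Mapping[str, GlobalMetrics]) -> dict:
    """Score the whole-image parameters (N_tot, A_tot / V_tot, SA_tot)."""
    raw_d = raw.as_dict()
    rep_ds = [m.as_dict() for m in replica_metrics]
    out = {}
    for param, chi_raw in raw_d.items():
        center, sigma_raw = predictive_uncertainty(
            [d[param] for d in rep_ds])
        entry = {"chi_raw": chi_raw, "sigma_raw": sigma_raw,
                 "replica_mean": center, "variants": {}}
        for name, vm in variants.items():
            chi_c = vm.as_dict()[param]
            ve = _scored_entry(chi_raw, chi_c, sigma_raw)
            ve["normalized"] = chi_c / chi_raw if chi_raw != 0 else None
            entry["variants"][name] = ve
        out[param] = entry
    return out


def _value_matrix(raw_df: pd.DataFrame, tables: Sequence[pd.DataFrame],
                  max_dist: float, parameters: Sequence[str]
                  ) -> dict[str, np.ndarray]:
    """Per-parameter (n_raw_objects, n_tables) value matrix, NaN = unmatched."""
    raw_labels = raw_df["label"].to_numpy()
    pos = {int(l): i for i, l in enumerate(raw_labels)}
    mats = {p: np.full((len(raw_labels), len(tables)), np.nan)
            for p in parameters}
    for t, df in enumerate(tables):
        m = match_objects(raw_df, df, max_dist=max_dist)
        if len(m.pairs) == 0:
            continue
        dfi = df.set_index("label")
        vals = dfi.loc[m.pairs["other_label"]]
        rows = [pos[int(l)] for l in m.pairs["raw_label"]]
        for p in parameters:
            mats[p][rows, t] = vals[p].to_numpy()
    return mats


#: minimum number of distinct replica values for sigma_raw to count as
#: resolved.  Segmentation parameters live on a discrete lattice (areas
#: are integers, centroids are rational in the pixel count); when the 10
#: replicate values collapse onto one or two lattice points the sample SD
#: is not a dispersion estimate and the score is degenerate, exactly as
#: in the sigma_raw == 0 convention.
RESOLVED_MIN_DISTINCT = 3


def object_scores(replica_tables: Sequence, raw_table,
                  variant_tables: Mapping[str, object],
                  max_dist: float = 3.0, min_replica_matches: int = 5,
                  parameters: Sequence[str] = PARAMETER_NAMES,
                  min_distinct: int = RESOLVED_MIN_DISTINCT
                  ) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Per-object standard scores for every parameter and variant.

    Returns ``(epsilons, summary, n_dropped)`` where ``epsilons`` is a
    long table (raw_label, parameter, variant, epsilon, sigma_raw) and
    ``summary`` averages epsilon over objects per (parameter, variant).
    Objects matched in fewer than ``min_replica_matches`` replicas are
    dropped and counted; cells whose replicate sample does not resolve
    sigma_raw (fewer than ``min_distinct`` distinct values) carry a NaN
    epsilon and are excluded from the summary.
    """
    raw_df = (raw_table if isinstance(raw_table, pd.DataFrame)
              else objects_frame(raw_table))
    rep_dfs = [t if isinstance(t, pd.DataFrame) else objects_frame(t)
               for t in replica_tables]
    var_dfs = {k: (t if isinstance(t, pd.DataFrame) else objects_frame(t))
               for k, t in variant_tables.items()}
    parameters = [p for p in parameters if p in raw_df.columns]

    rep_mats = _value_matrix(raw_df, rep_dfs, max_dist, parameters)
    n_matched = np.isfinite(next(iter(rep_mats.values()))).sum(axis=1)
    keep = n_matched >= min_replica_matches
    n_dropped = int((~keep).sum())

    raw_vals = {p: raw_df[p].to_numpy(dtype=np.float64) for p in parameters}
    sigma_raw, resolved = {}, {}
    for p in parameters:
        mat = rep_mats[p]
        if p in ANGLE_PARAMETERS:
            mat = raw_vals[p][:, None] + wrap_angle_difference(
                mat - raw_vals[p][:, None])
        import warnings as _warnings
        with np.errstate(invalid="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            sd = np.nanstd(mat, axis=1, ddof=1)
            center = np.nanmean(mat, axis=1)
        # identical replica values must give sigma_raw == 0 exactly, not
        # the floating-point noise of the mean subtraction
        sd[sd < 1e-9 * (1.0 + np.abs(center))] = 0.0
        sigma_raw[p] = sd
        resolved[p] = np.array(
            [np.unique(row[np.isfinite(row)]).size >= min_distinct
             for row in mat])

    var_mats = {name: _value_matrix(raw_df, [df], max_dist, parameters)
                for name, df in var_dfs.items()}
    rows = []
    raw_labels = raw_df["label"].to_numpy()
    for name in var_dfs:
        for p in parameters:
            chi_c = var_mats[name][p][:, 0]
            delta = raw_vals[p] - chi_c
            if p in ANGLE_PARAMETERS:
                delta = wrap_angle_difference(delta)
            with np.errstate(divide="ignore", invalid="ignore"):
                eps = delta / sigma_raw[p]
            ok = sigma_raw[p] > 0
            for i in np.flatnonzero(keep & np.isfinite(chi_c)):
                good = ok[i] and resolved[p][i]
                rows.append((int(raw_labels[i]), p, name,
                             float(eps[i]) if good else np.nan,
                             float(sigma_raw[p][i]), float(delta[i])))
    epsilons = pd.DataFrame(rows, columns=["raw_label", "parameter",
                                           "variant", "epsilon",
                                           "sigma_raw", "delta"])
    grp = epsilons.dropna(subset=["epsilon"]).groupby(
        ["parameter", "variant"], sort=False)["epsilon"]
    summary = grp.agg(mean_epsilon="mean", sd_epsilon="std",
                      n_objects="count").reset_index()
    summary["tolerable"] = summary["mean_epsilon"].abs() < 1.0
    return epsilons, summary, n_dropped


def averaged_object_scores(replica_tables, raw_table, variant_tables,
                           max_dist: float = 3.0,
                           min_replica_matches: int = 5) -> pd.DataFrame:
    """Mean and SD of epsilon over objects, per parameter and variant."""
    _, summary, _ = object_scores(replica_tables, raw_table, variant_tables,
                                  max_dist, min_replica_matches)
    return summary


def operator_scores(raw_image: np.ndarray, replica_images: Sequence,
                    variant_images: Mapping[str, np.ndarray],
                    bank: FeatureBank, space: str = "projection"
                    ) -> pd.DataFrame:
    """Mean per-pixel standard score of each (operator, sigma) feature.

    sigma_raw is estimated pixel-wise from the replica feature planes;
    the mean runs over interior pixels (a border of four times the
    largest kernel sigma is excluded) with sigma_raw > 0.  Planes that
    belong to the same (operator, sigma) pair — e.g. the two Hessian
    eigenvalues — are averaged together.
    """
    if len(replica_images) < 2:
        raise ValueError("need >= 2 replicas for sigma_raw")
    raw_feat, names = compute_features(np.asarray(raw_image, np.float64),
                                       bank)
    rep_feats = np.stack([compute_features(
        np.asarray(r, np.float64), bank)[0] for r in replica_images])
    sigma = rep_feats.std(axis=0, ddof=1)
    border = int(np.ceil(4 * max(bank.sigmas)))
    core = tuple(slice(border, -border if border else None)
                 for _ in range(raw_feat.ndim - 1))
    rows = []
    for vname, vimg in variant_images.items():
        var_feat, _ = compute_features(np.asarray(vimg, np.float64), bank)
        for fi, fname in enumerate(names):
            if fname == "raw":
                continue
            s = sigma[core + (fi,)]
            d = raw_feat[core + (fi,)] - var_feat[core + (fi,)]
            ok = s > 0
            if not ok.any():
                mean_eps = np.nan
            else:
                mean_eps = float((d[ok] / s[ok]).mean())
            op, sig = fname.rsplit("_s", 1)
            op = op.split("_e")[0]  # merge hessian eigenvalue planes
            rows.append((space, vname, op, float(sig), mean_eps))
    df = pd.DataFrame(rows, columns=["space", "variant", "operator",
                                     "sigma", "mean_epsilon"])
    return (df.groupby(["space", "variant", "operator", "sigma"],
                       sort=False)["mean_epsilon"].mean().reset_index())


@dataclass
class DistortionReport:
    """Full audit result: global and per-object scores plus provenance."""

    global_scores: dict
    object_summary: pd.DataFrame | None = None
    object_epsilons: pd.DataFrame | None = None
    delta_distributions: dict = field(default_factory=dict)
    operator_table: pd.DataFrame | None = None
    n_dropped_objects: int = 0
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "global_scores": self.global_scores,
            "object_summary": (None if self.object_summary is None else
                               self.object_summary.to_dict("records")),
            "delta_distributions": {
                k: {"mu": v["mu"], "sigma": v["sigma"]}
                for k, v in self.delta_distributions.items()},
            "n_dropped_objects": self.n_dropped_objects,
            "provenance": self.provenance,
        }
        text = json.dumps(doc, indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        if self.object_summary is not None:
            self.object_summary.to_csv(directory / "object_summary.csv",
                                       index=False)
        if self.object_epsilons is not None:
            self.object_epsilons.to_csv(directory / "object_epsilons.csv",
                                        index=False)
        if self.operator_table is not None:
            self.operator_table.to_csv(directory / "operator_scores.csv",
                                       index=False)


def plot_object_scores(summary: pd.DataFrame, path: str | Path) -> None:
    """Dot-and-error-bar chart of mean epsilon per parameter and variant."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    params = [p for p in PARAMETER_NAMES
              if p in set(summary["parameter"])]
    x = np.arange(len(params))
    variants = list(dict.fromkeys(summary["variant"]))
    for off, vname in zip(np.linspace(-0.25, 0.25, max(len(variants), 2)),
                          variants):
        sub = summary[summary["variant"] == vname].set_index("parameter")
        means = [sub["mean_epsilon"].get(p, np.nan) for p in params]
        sds = [sub["sd_epsilon"].get(p, np.nan) for p in params]
        ax.errorbar(x + off, means, yerr=sds, fmt="o", ms=3, capsize=2,
                    label=vname)
    for y in (-1, 1):
        ax.axhline(y, color="red", ls=":", lw=1)
    ax.set_xticks(x, params, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel(r"standard score $\epsilon$")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
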