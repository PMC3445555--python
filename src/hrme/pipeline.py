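"""End-to-end orchestration: simulate -> QC -> preprocess -> segment ->
metrics -> diagnostics.

Used by the command-line interface and usable directly from Python.  All
stages are deterministic given the configuration and seed; outputs are plain
CSV/JSON tables.
"""

from __future__ import annotations

import dataclasses
import glob
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .frame import Frame, Movie, load_frames
from .synthetic import (CohortSimConfig, FiberBundleSpec, NoiseModel,
                        render_site, sample_cohort, simulate_cohort_to_disk)
from .qc import QCThresholds, qc_evaluate, select_frame
from .preprocess import ROIMask, default_median_radius, preprocess
from .segment import MAX_OBJECT_PX, MIN_OBJECT_PX, segment_frame
from .metrics import group_stats, nc_ratio
from .diagnostics import (ClassifierConfig, confusion, q_point, roc,
                          round_percent, sens_spec, youden_point)


@dataclass
class PipelineConfig:
    """Fully resolved run configuration; round-trippable to YAML."""

    bundle: FiberBundleSpec = field(default_factory=FiberBundleSpec)
    cohort: CohortSimConfig = field(default_factory=CohortSimConfig)
    noise: NoiseModel = field(default_factory=NoiseModel)
    qc: QCThresholds = field(default_factory=QCThresholds)
    clahe_tile_grid: tuple[int, int] = (8, 8)
    clahe_clip_limit: float = 0.01
    median_radius_px: int | None = None  # None -> derived from core spacing
    min_obj_px: int = MIN_OBJECT_PX
    max_obj_px: int = MAX_OBJECT_PX
    nc_cutoff: float = 0.163
    n_frames: int = 5
    seed: int = 0

    def resolved_median_radius(self) -> int:
        if self.median_radius_px is not None:
            return self.median_radius_px
        return default_median_radius(self.bundle.core_spacing_px)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["clahe_tile_grid"] = list(self.clahe_tile_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, typ in (("bundle", FiberBundleSpec), ("cohort", CohortSimConfig),
                         ("noise", NoiseModel), ("qc", QCThresholds)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        if "clahe_tile_grid" in d:
            d["clahe_tile_grid"] = tuple(d["clahe_tile_grid"])
        return cls(**d)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def analyze_movie(movie: Movie, config: PipelineConfig, *,
                  roi: ROIMask | None = None,
                  threshold_override: float | None = None) -> dict:
    """QC, preprocess, and segment one site's movie; returns one result row.

    Sites failing QC get ``qc_passed=False`` and no N/C ratio.
    """
    idx = select_frame(movie, config.qc)
    frame = movie[idx]
    report = qc_evaluate(frame, config.qc, movie=movie, frame_index=idx)
    row = {"site_id": movie.site_id, "selected_frame": idx,
           "qc_passed": report.passed,
           "out_of_focus_fraction": report.out_of_focus_fraction,
           "motion_score": report.motion_score,
           "debris_fraction": report.debris_fraction,
           "qc_reasons": ";".join(report.reasons)}
    if not report.passed:
        row.update({"nc_ratio": np.nan, "nuclear_area_px": np.nan,
                    "roi_area_px": np.nan, "threshold_used": np.nan})
        return row
    if roi is None:
        roi = ROIMask.full_fov(frame)
    proc, roi = preprocess(frame, roi, tile_grid=config.clahe_tile_grid,
                           clip_limit=config.clahe_clip_limit,
                           median_radius_px=config.resolved_median_radius())
    seg = segment_frame(proc, roi, threshold=threshold_override,
                        min_px=config.min_obj_px, max_px=config.max_obj_px)
    res = nc_ratio(seg, roi, site_id=movie.site_id)
    row.update({"nc_ratio": res.nc_ratio, "nuclear_area_px": res.nuclear_area_px,
                "roi_area_px": res.roi_area_px, "threshold_used": res.threshold_used})
    return row


def analyze_cohort(ledger: pd.DataFrame, config: PipelineConfig, *,
                   from_disk: bool = False,
                   threshold_overrides: dict[str, float] | None = None,
                   ) -> pd.DataFrame:
    """Run QC + analysis for every site in a ledger.

    With ``from_disk`` the ledger's ``movie_path`` column is read (a TIFF
    sequence directory or a single file per site); otherwise each site is
    re-rendered in memory from its ``render_seed``.
    """
    if ledger.empty:
        raise ValueError("empty ledger")
    overrides = threshold_overrides or {}
    rows = []
    for _, site in ledger.iterrows():
        if from_disk:
            path = site["movie_path"]
            paths = sorted(glob.glob(os.path.join(path, "*.tif"))) \
                if os.path.isdir(path) else [path]
            movie = load_frames(paths, pixel_size_um=float(site.get("pixel_size_um", 1.0)),
                                site_id=str(site["site_id"]))
        else:
            movie, _ = render_site(site, config.bundle, noise=config.noise,
                                   n_frames=config.n_frames)
        row = analyze_movie(movie, config,
                            threshold_override=overrides.get(str(site["site_id"])))
        for col in ("histopath_diagnosis", "category", "neoplastic", "true_nc"):
            if col in site:
                row[col] = site[col]
        rows.append(row)
    return pd.DataFrame(rows)


def evaluate_cohort(results: pd.DataFrame, config: PipelineConfig) -> dict:
    """Cohort-level statistics on QC-passing sites.

    Returns a dict with the analyzed-site count, per-category summary and
    pairwise t-test DataFrames, confusion counts at the fixed cutoff,
    sensitivity/specificity (full precision and rounded percent), the ROC
    curve, its AUC, and the Q-point/Youden operating points.
    """
    passed = results[results["qc_passed"]].copy()
    if passed.empty:
        raise ValueError("no QC-passing sites to evaluate")
    summary, pairwise = group_stats(passed)
    counts = confusion(passed, ClassifierConfig(config.nc_cutoff))
    sens, spec = sens_spec(counts)
    curve = roc(passed["nc_ratio"], passed["neoplastic"])
    qp = q_point(curve)
    yp = youden_point(curve)
    return {
        "n_sites_analyzed": int(len(passed)),
        "n_sites_excluded": int((~results["qc_passed"]).sum()),
        "group_summary": summary,
        "pairwise_tests": pairwise,
        "confusion": counts,
        "sensitivity_pct": sens,
        "specificity_pct": spec,
        "sensitivity_pct_rounded": round_percent(sens),
        "specificity_pct_rounded": round_percent(spec),
        "roc": curve,
        "auc": curve.auc,
        "q_point": qp,
        "youden_point": yp,
    }


def run_simulated_study(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a cohort, analyze it in memory, and evaluate it.

    Returns (ledger, per-site results, evaluation summary).
    """
    cohort = dataclasses.replace(config.cohort, seed=config.seed)
    ledger = sample_cohort(cohort)
    results = analyze_cohort(ledger, config)
    summary = evaluate_cohort(results, config)
    return ledger, results, summary


def summary_to_json(summary: dict, config: PipelineConfig) -> dict:
    """Flatten an evaluation summary into a JSON-serializable dict."""
    qp = summary["q_point"]
    return {
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_sites_analyzed": summary["n_sites_analyzed"],
        "n_sites_excluded": summary["n_sites_excluded"],
        "sensitivity_pct": summary["sensitivity_pct"],
        "specificity_pct": summary["specificity_pct"],
        "sensitivity_pct_rounded": summary["sensitivity_pct_rounded"],
        "specificity_pct_rounded": summary["specificity_pct_rounded"],
        "auc": summary["auc"],
        "q_point": {"cutoff": float(qp["cutoff"]),
                    "sensitivity": float(qp["sensitivity"]),
                    "specificity": float(qp["specificity"])},
        "group_means": {row["category"]: row["mean_nc"]
                        for _, row in summary["group_summary"].iterrows()},
        "pairwise_p": {f'{row["group_a"]} vs {row["group_b"]}': row["p"]
                       for _, row in summary["pairwise_tests"].iterrows()},
    }
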