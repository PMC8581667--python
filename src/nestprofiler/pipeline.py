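"""End-to-end runs: simulate -> segment -> quantify -> analyze -> report.

A :class:`RunConfig` names either input image paths or a simulation spec
(never both), plus morphology, gating, cutoff and survival settings; the
single seed drives every stochastic stage. :func:`run_pipeline` executes
the stages in order, writes every artifact under the output directory and
records a :class:`RunManifest` (config hash, per-stage parameters, file
list) so a run is auditable and exactly repeatable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as nio
from .cytometry import (
    GatingConfig,
    assign_region,
    classify_cells,
    compute_region_stats,
    detect_cells,
    polarization_class,
    quantify_markers,
    region_validation,
    th1_th2_ratio,
)
from .segmentation import MorphParams, segment_slide, select_rois
from .simulate import (
    CohortSimSpec,
    ImageSimSpec,
    default_image_spec,
    generate_cohort,
    generate_image_stack,
)
from .stats import CutoffRule, cox_fit, dichotomize, km_estimate, logrank_test

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "make_report", "demo_config"]

logger = logging.getLogger("nestprofiler")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    out_dir: str
    seed: int = 0
    image_sim: dict | None = None  # overrides for default_image_spec
    input_paths: dict | None = None  # tumor_marker, hematoxylin, [cd3], pixel_size_um
    cohort_sim: dict | None = None  # overrides for CohortSimSpec
    cohort_csv: str | None = None
    morphology: dict = field(default_factory=dict)
    gating: dict = field(default_factory=dict)  # panel_variant, thresholds
    cutoffs: dict = field(default_factory=dict)  # feature -> {kind, fixed_value}
    covariates: list = field(default_factory=list)
    n_rois: int = 3
    roi_window_mm: float = 2.5

    def validate(self) -> None:
        if (self.image_sim is not None) and (self.input_paths is not None):
            raise ValueError("provide either image_sim or input_paths, not both")
        if (self.cohort_sim is not None) and (self.cohort_csv is not None):
            raise ValueError("provide either cohort_sim or cohort_csv, not both")
        if self.input_paths is not None:
            for key in ("tumor_marker", "hematoxylin", "pixel_size_um"):
                if key not in self.input_paths:
                    raise ValueError(f"input_paths lacks {key!r}")
            for key in ("tumor_marker", "hematoxylin", "cd3"):
                if key in self.input_paths and not Path(self.input_paths[key]).exists():
                    raise ValueError(f"input file missing: {self.input_paths[key]}")
        if self.cohort_csv is not None and not Path(self.cohort_csv).exists():
            raise ValueError(f"cohort file missing: {self.cohort_csv}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**nio.read_yaml(path))

    def hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Audit record of one run: config hash, stages, parameters, files."""

    config_hash: str
    version: str
    seed: int
    out_dir: str
    stages: list = field(default_factory=list)
    files: list = field(default_factory=list)
    failed_stage: str | None = None

    def add_stage(self, name: str, params: dict, outputs: list, elapsed_s: float):
        self.stages.append(
            {
                "name": name,
                "params": params,
                "outputs": [str(o) for o in outputs],
                "elapsed_s": round(elapsed_s, 3),
            }
        )
        self.files.extend(str(o) for o in outputs)

    def write(self, path) -> Path:
        return nio.write_json(asdict(self), path)

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**nio.read_json(path))


def _morph_params(config: RunConfig) -> MorphParams:
    return MorphParams(**config.morphology) if config.morphology else MorphParams()


def _gating_config(config: RunConfig) -> GatingConfig:
    kwargs = dict(config.gating)
    return GatingConfig(**kwargs) if kwargs else GatingConfig()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages and write all artifacts plus manifest.

    Any stage failure aborts with :class:`StageError`; artifacts written so
    far are kept and the manifest marks the failure point.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.hash(),
        version=__version__,
        seed=config.seed,
        out_dir=str(out),
    )
    manifest_path = out / "manifest.json"
    nio.write_yaml(config.to_dict(), out / "config.yaml")
    manifest.files.append(str(out / "config.yaml"))

    state: dict = {}
    stage_plan = [
        ("simulate_images", _stage_images),
        ("select_rois", _stage_rois),
        ("segment", _stage_segment),
        ("cytometry", _stage_cytometry),
        ("cohort_stats", _stage_cohort),
    ]
    for name, fn in stage_plan:
        start = time.time()
        try:
            params, outputs = fn(config, state, out)
        except Exception as exc:
            manifest.failed_stage = name
            manifest.write(manifest_path)
            raise StageError(name, exc) from exc
        elapsed = time.time() - start
        if params is not None:
            manifest.add_stage(name, params, outputs, elapsed)
            logger.info("stage %s done in %.2fs", name, elapsed)
    manifest.write(manifest_path)
    return manifest


def _stage_images(config: RunConfig, state: dict, out: Path):
    if config.image_sim is not None:
        overrides = dict(config.image_sim)
        overrides.setdefault("seed", config.seed)
        spec = default_image_spec(**overrides)
        stack, truth = generate_image_stack(spec)
        state["stack"], state["truth"] = stack, truth
        outputs = [
            nio.write_stack_tiff(stack, out / "stack.tiff"),
            nio.write_mask_png(truth.nest_mask, out / "truth_nest.png"),
            nio.write_mask_png(truth.roi_mask, out / "truth_roi.png"),
        ]
        truth_csv = out / "truth_cells.csv"
        truth.cells.to_csv(truth_csv, index=False)
        outputs.append(truth_csv)
        meta = out / "simulation_meta.json"
        nio.write_json(
            {"seed": spec.seed, "pixel_size_um": spec.pixel_size_um,
             "n_cells": len(truth.cells)},
            meta,
        )
        outputs.append(meta)
        params = {"spec": {k: str(v) for k, v in overrides.items()}}
        return params, outputs
    if config.input_paths is not None:
        px = float(config.input_paths["pixel_size_um"])
        channels = {}
        for key, marker in (
            ("tumor_marker", "TumorMarker"),
            ("hematoxylin", "Hematoxylin"),
            ("cd3", "CD3"),
        ):
            if key in config.input_paths:
                img = nio.read_gray_image(config.input_paths[key], px)
                channels[marker] = np.clip(np.rint(img.pixels), 0, 255).astype(
                    np.uint8
                )
        from .simulate import MarkerImageStack

        state["stack"] = MarkerImageStack(channels, px)
        return {"inputs": dict(config.input_paths)}, []
    return None, []


def _stage_rois(config: RunConfig, state: dict, out: Path):
    stack = state.get("stack")
    if stack is None or "CD3" not in stack.channels:
        return None, []
    from .segmentation import compute_tissue_mask

    tissue = compute_tissue_mask(stack.channel("Hematoxylin"))
    boxes = select_rois(
        stack.channel("CD3"), tissue, k=config.n_rois, window_mm=config.roi_window_mm
    )
    state["roi_boxes"] = boxes
    path = out / "roi_boxes.json"
    nio.write_json(
        [
            {"x_px": b.x_px, "y_px": b.y_px, "width_px": b.width_px,
             "height_px": b.height_px, "area_mm2": b.area_mm2}
            for b in boxes
        ],
        path,
    )
    return {"k": config.n_rois, "window_mm": config.roi_window_mm}, [path]


def _stage_segment(config: RunConfig, state: dict, out: Path):
    stack = state.get("stack")
    if stack is None:
        return None, []
    morph = _morph_params(config)
    seg = segment_slide(
        stack.channel("TumorMarker"), stack.channel("Hematoxylin"), morph
    )
    state["seg"] = seg
    outputs = [
        nio.write_mask_png(seg.roi, out / "mask_roi.png"),
        nio.write_mask_png(seg.nest, out / "mask_nest.png"),
        nio.write_mask_png(seg.stroma, out / "mask_stroma.png"),
        nio.write_mask_png(seg.blank, out / "mask_blank.png"),
    ]
    report = out / "segmentation_report.json"
    nio.write_json(
        {
            "nest_threshold": seg.nest_threshold,
            "tissue_threshold": seg.roi.threshold,
            "areas_mm2": {
                "roi": seg.roi.area_mm2,
                "nest": seg.nest.area_mm2,
                "stroma": seg.stroma.area_mm2,
            },
            "morphology": asdict(morph),
        },
        report,
    )
    outputs.append(report)
    return {"morphology": asdict(morph)}, outputs


def _stage_cytometry(config: RunConfig, state: dict, out: Path):
    stack, seg = state.get("stack"), state.get("seg")
    if stack is None or seg is None:
        return None, []
    gating = _gating_config(config)
    detection = detect_cells(stack.channel("Hematoxylin"), seg.roi)
    cells = quantify_markers(detection, stack)
    markers_present = [m for m in gating.required_markers() if m in cells.columns]
    missing = set(gating.required_markers()) - set(markers_present)
    if missing:
        raise ValueError(f"stack lacks markers required by gating: {sorted(missing)}")
    labeled = assign_region(classify_cells(cells, gating), seg)
    state["cells"] = labeled
    stats = compute_region_stats(labeled, seg)
    state["region_stats"] = stats

    cells_csv = out / "cells.csv"
    labeled.to_csv(cells_csv, index=False)
    ratios = {
        region: (
            {"ratio": r.ratio, "excluded": r.excluded}
            if (r := th1_th2_ratio(stats, region))
            else None
        )
        for region in ("nest", "stroma")
    }
    polarization = {
        lin: polarization_class(
            stats.density(("nest"), lin), stats.density("stroma", lin)
        )
        for lin in sorted(set(stats.per_lineage["lineage"]))
    }
    stats_json = out / "region_stats.json"
    nio.write_json(
        {
            "per_lineage": stats.per_lineage.to_dict(orient="records"),
            "pd1_per_lineage": stats.pd1_per_lineage.to_dict(orient="records"),
            "percent_of_cd45": stats.percent_of_cd45.to_dict(orient="records"),
            "th_counts": stats.th_counts.to_dict(orient="records"),
            "th1_th2_ratio": ratios,
            "polarization_class": polarization,
            "region_validation": region_validation(labeled, seg, gating).to_dict(
                orient="records"
            ),
            "areas_mm2": stats.areas_mm2,
        },
        stats_json,
    )
    return (
        {"panel_variant": gating.panel_variant,
         "default_threshold": gating.default_threshold},
        [cells_csv, stats_json],
    )


def _stage_cohort(config: RunConfig, state: dict, out: Path):
    if config.cohort_sim is not None:
        overrides = dict(config.cohort_sim)
        overrides.setdefault("seed", config.seed)
        spec = CohortSimSpec(**overrides)
        cohort = generate_cohort(spec)
    elif config.cohort_csv is not None:
        cohort = pd.read_csv(config.cohort_csv)
    else:
        return None, []

    cohort_csv = out / "cohort.csv"
    cohort.to_csv(cohort_csv, index=False)
    outputs = [cohort_csv]

    cutoffs = config.cutoffs or _default_cutoffs(cohort)
    report: dict = {"features": {}, "cox": None}
    times = cohort["time_months"].to_numpy(float)
    events = cohort["event"].to_numpy(bool)
    group_cols: list[str] = []
    for feature, rule_spec in cutoffs.items():
        rule = CutoffRule(
            kind=rule_spec.get("kind", "mean"),
            fixed_value=rule_spec.get("fixed_value"),
        )
        split = dichotomize(cohort[feature].to_numpy(float), rule, events)
        high = split.high
        col = f"high_{feature}"
        cohort[col] = high
        group_cols.append(col)
        entry: dict = {"cutoff": split.cutoff, "rule": rule.kind,
                       "n_high": int(high.sum()), "n_low": int((~high).sum())}
        if high.any() and (~high).any():
            stat, p = logrank_test(times[high], events[high], times[~high],
                                   events[~high])
            entry["logrank"] = {"statistic": stat, "p": p}
            for label, sel in (("high", high), ("low", ~high)):
                curve = km_estimate(times[sel], events[sel])
                km_csv = out / f"km_{feature}_{label}.csv"
                pd.DataFrame(
                    {"time": curve.times, "survival": curve.survival,
                     "at_risk": curve.at_risk}
                ).to_csv(km_csv, index=False)
                outputs.append(km_csv)
        report["features"][feature] = entry

    covariates = list(config.covariates) if config.covariates else [
        c for c in ("hpv_negative", "male", "smoking_history", "stage_3_4")
        if c in cohort.columns
    ]
    covariates = group_cols + covariates
    usable = [c for c in covariates if cohort[c].nunique() > 1]
    if usable and events.sum() >= 2:
        cox = cox_fit(cohort, usable)
        report["cox"] = {
            "converged": cox.converged,
            "ties": cox.ties_method,
            "table": {
                cov: {
                    "hazard_ratio": cox.hazard_ratio(cov),
                    "ci_low": cox.ci(cov)[0],
                    "ci_high": cox.ci(cov)[1],
                    "p": cox.p_value(cov),
                }
                for cov in usable
            },
        }
    survival_json = out / "survival_report.json"
    nio.write_json(report, survival_json)
    outputs.append(survival_json)
    cohort.to_csv(cohort_csv, index=False)  # now includes the high/low columns
    return {"cutoffs": {f: dict(r) for f, r in cutoffs.items()},
            "covariates": usable}, outputs


def _default_cutoffs(cohort: pd.DataFrame) -> dict:
    features = [
        c
        for c in cohort.columns
        if c.endswith("_density") and pd.api.types.is_numeric_dtype(cohort[c])
    ]
    return {f: {"kind": "mean"} for f in features}


def make_report(manifest_path) -> Path:
    """Render a Markdown + PNG report from a completed run's artifacts.

    One KM plot per configured cutoff feature, a leukocyte composition bar
    chart per region, a nest-vs-stroma density scatter on log axes, and the
    Cox table. Report files are appended to the manifest.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    manifest_path = Path(manifest_path)
    manifest = RunManifest.read(manifest_path)
    out = Path(manifest.out_dir)
    report_dir = out / "report"
    report_dir.mkdir(exist_ok=True)
    lines = ["# nestprofiler run report", "",
             f"config hash: `{manifest.config_hash}`, seed {manifest.seed}", ""]
    new_files: list[Path] = []

    stats_path = out / "region_stats.json"
    if stats_path.exists():
        stats = nio.read_json(stats_path)
        per_lineage = pd.DataFrame(stats["per_lineage"])
        pct = pd.DataFrame(stats["percent_of_cd45"])
        if len(pct):
            fig, ax = plt.subplots(figsize=(7, 4))
            pivot = pct.pivot(index="lineage", columns="region", values="percent")
            pivot.plot.bar(ax=ax)
            ax.set_ylabel("% of CD45+ cells")
            fig.tight_layout()
            p = report_dir / "composition.png"
            fig.savefig(p)
            plt.close(fig)
            new_files.append(p)
            lines += ["## Leukocyte composition", "",
                      "![composition](report/composition.png)", ""]
        dens = per_lineage.pivot(index="lineage", columns="region", values="density")
        if {"nest", "stroma"} <= set(dens.columns):
            fig, ax = plt.subplots(figsize=(5, 5))
            ax.scatter(dens["stroma"] + 1e-3, dens["nest"] + 1e-3)
            for lin, row in dens.iterrows():
                ax.annotate(lin, (row["stroma"] + 1e-3, row["nest"] + 1e-3),
                            fontsize=6)
            ax.set_xscale("log")
            ax.set_yscale("log")
            lo = min(ax.get_xlim()[0], ax.get_ylim()[0])
            hi = max(ax.get_xlim()[1], ax.get_ylim()[1])
            ax.plot([lo, hi], [lo, hi], "k--", lw=0.5)
            ax.plot([lo, hi], [2 * lo, 2 * hi], "r:", lw=0.5)
            ax.plot([lo, hi], [0.5 * lo, 0.5 * hi], "b:", lw=0.5)
            ax.set_xlabel("stroma density (cells/mm2)")
            ax.set_ylabel("nest density (cells/mm2)")
            fig.tight_layout()
            p = report_dir / "polarization.png"
            fig.savefig(p)
            plt.close(fig)
            new_files.append(p)
            lines += ["## Nest vs stroma density (log-log)", "",
                      "![polarization](report/polarization.png)", ""]

    survival_path = out / "survival_report.json"
    if survival_path.exists():
        survival = nio.read_json(survival_path)
        lines += ["## Survival analysis", ""]
        for feature, entry in survival["features"].items():
            fig, ax = plt.subplots(figsize=(5, 4))
            plotted = False
            for label in ("high", "low"):
                km_csv = out / f"km_{feature}_{label}.csv"
                if km_csv.exists():
                    curve = pd.read_csv(km_csv)
                    ax.step(curve["time"], curve["survival"], where="post",
                            label=label)
                    plotted = True
            if plotted:
                ax.set_ylim(0, 1.05)
                ax.set_xlabel("months")
                ax.set_ylabel("overall survival")
                ax.legend(title=f"{feature}\n(cutoff={entry['cutoff']:.3g},"
                                f" {entry['rule']})")
                fig.tight_layout()
                p = report_dir / f"km_{feature}.png"
                fig.savefig(p)
                new_files.append(p)
                lr = entry.get("logrank")
                lines += [
                    f"### {feature}", "",
                    f"![km](report/km_{feature}.png)", "",
                    (f"log-rank chi2 = {lr['statistic']:.3f}, p = {lr['p']:.4g}"
                     if lr else "log-rank not computed (single group)"),
                    "",
                ]
            plt.close(fig)
        if survival.get("cox"):
            lines += ["### Cox proportional hazards", "",
                      "| covariate | HR | 95% CI | p |", "|---|---|---|---|"]
            for cov, row in survival["cox"]["table"].items():
                lines.append(
                    f"| {cov} | {row['hazard_ratio']:.2f} "
                    f"| ({row['ci_low']:.2f}-{row['ci_high']:.2f}) "
                    f"| {row['p']:.4g} |"
                )
            lines.append("")
    else:
        lines += ["## Survival analysis", "",
                  "_No cohort data in this run; survival panels omitted._", ""]

    report_md = report_dir / "report.md"
    report_md.write_text("\n".join(lines))
    new_files.append(report_md)
    manifest.files.extend(str(p) for p in new_files)
    manifest.write(manifest_path)
    return report_md


def demo_config(out_dir, seed: int = 0) -> RunConfig:
    """A small bundled demonstration run: one simulated slide plus a
    60-patient simulated cohort."""
    return RunConfig(
        out_dir=str(out_dir),
        seed=seed,
        image_sim={
            "width_px": 500,
            "height_px": 500,
            "n_nests": 2,
            "nest_radius_um_range": (100.0, 180.0),
            "blank_margin_px": 24,
        },
        cohort_sim={"n_patients": 60},
        cutoffs={"pd1_helper_t_nest_density": {"kind": "mean"}},
    )
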