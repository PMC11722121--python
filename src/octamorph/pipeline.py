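"""End-to-end orchestration: image chain, cohort chain, fixtures, config.

`run_image_pipeline` takes per-eye frame stacks (file manifests or
in-memory stacks) through averaging, segmentation, graphing and
morphometry, emitting one record per eye; a failure in one eye is logged
and does not stop the batch. `run_cohort_pipeline` executes the full
statistical chain on a cohort CSV. Every record carries provenance: the
parameter values used and the decision flags of reconstructed estimators.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import faz as faz_mod
from . import graph as graph_mod
from . import metrics as metrics_mod
from . import preprocess as pre_mod
from . import stats as stats_mod
from . import synth as synth_mod
from .containers import BinaryVesselMask, EnFaceImage, FrameStack

__all__ = [
    "PipelineConfig",
    "EyeResultRecord",
    "run_image_pipeline",
    "run_cohort_pipeline",
    "make_fixtures",
    "load_manifest",
]

log = logging.getLogger("octamorph")


@dataclass
class PipelineConfig:
    """All tunables of the two chains, JSON-serializable for provenance."""

    output_dir: str = "."
    averaging_mode: str = "mean"             # mean | max
    registration_stages: tuple[str, ...] = ("translation", "affine", "elastic")
    inhomogeneity_kernel_mm: float = 0.5
    min_spur_px: float = 6.0
    closing_radius_px: int = 5
    pd_exclusion: str = "both"               # both | numerator
    tortuosity_min_len_px: float = 10.0
    device_assumed_al_mm: float = faz_mod.DEVICE_ASSUMED_AL_MM
    screen_alpha: float = 0.10
    report_alpha: float = 0.05
    r_threshold: float = 0.9
    manual_exclusions: tuple[str, ...] = ("prp",)
    forced_retests: tuple[str, ...] = stats_mod.DEFAULT_FORCED_RETESTS
    loocv_unit: str = "eye"
    seed: int = 0

    def to_json(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = json.load(fh)
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("registration_stages", "manual_exclusions",
                    "forced_retests"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


@dataclass
class EyeResultRecord:
    eye_id: str
    vascular: dict[str, float]
    faz: dict[str, float]
    provenance: dict[str, Any] = field(default_factory=dict)

    def as_row(self) -> dict[str, Any]:
        row: dict[str, Any] = {"eye_id": self.eye_id}
        row.update(self.vascular)
        row.update({f"faz_{k}" if not k.startswith("faz") else k: v
                    for k, v in self.faz.items()})
        return row


def load_manifest(path: str | Path) -> list[dict[str, Any]]:
    """Stack manifest: list of eyes, each with frame paths and metadata."""
    with open(path) as fh:
        manifest = json.load(fh)
    if not isinstance(manifest, list):
        raise ValueError("manifest must be a list of eye entries")
    return manifest


def _load_stack(entry: dict[str, Any]) -> FrameStack:
    import imageio.v3 as iio

    frames = []
    pixel_size = float(entry["pixel_size_mm"])
    for item in entry["frames"]:
        px = np.asarray(iio.imread(item["path"]), dtype=float)
        meta = {k: v for k, v in item.items() if k != "path"}
        frames.append(EnFaceImage(px, pixel_size, meta, "raw"))
    return FrameStack(frames=frames)


def process_eye(stack: FrameStack, config: PipelineConfig,
                axial_length_mm: float | None = None,
                av_mask: BinaryVesselMask | None = None) -> EyeResultRecord:
    """One eye: average -> segment -> graph -> morphometry (+FAZ)."""
    averaged = pre_mod.preprocess_stack(
        stack, mode=config.averaging_mode, stages=config.registration_stages,
        kernel_mm=config.inhomogeneity_kernel_mm)
    graph, mask, skel = graph_mod.extract_vessel_graph(
        averaged, min_spur_px=config.min_spur_px, av_mask=av_mask)
    derived_av = av_mask if av_mask is not None \
        else graph_mod.av_mask_from_graph(graph)
    vascular = metrics_mod.compute_vascular_metrics(
        mask, skel, graph, derived_av, exclusion=config.pd_exclusion,
        min_len_px=config.tortuosity_min_len_px)
    region = faz_mod.segment_faz(mask, closing_radius=config.closing_radius_px)
    fz = faz_mod.faz_metrics(region)
    scale = 1.0
    if axial_length_mm is not None:
        scale = faz_mod.magnification_scale(faz_mod.MagnificationParams(
            axial_length_mm, config.device_assumed_al_mm))
        fz = faz_mod.apply_magnification(fz, scale)
    provenance = {
        "config": config.to_json(),
        "decision_flags": dict(metrics_mod.DECISION_FLAGS),
        "av_classification": graph.meta.get("av_classification"),
        "strahler_root_policy": graph.meta.get("root_policy"),
        "magnification_scale": scale,
    }
    faz_row = {
        "faz_area_mm2": fz.area_mm2, "faz_perimeter_mm": fz.perimeter_mm,
        "faz_eccentricity": fz.eccentricity, "faz_axis_ratio": fz.axis_ratio,
        "faz_acircularity": fz.acircularity_index,
        "faz_min_distance_mm": fz.min_feret_mm,
        "faz_max_distance_mm": fz.max_feret_mm,
    }
    return EyeResultRecord("", vascular.as_row(), faz_row, provenance)


def run_image_pipeline(config: PipelineConfig,
                       manifest: list[dict[str, Any]] | None = None,
                       stacks: dict[str, FrameStack] | None = None,
                       ) -> tuple[list[EyeResultRecord], list[dict[str, str]]]:
    """Process a batch of eyes; errors are isolated per eye and reported."""
    jobs: list[tuple[str, Any]] = []
    if manifest is not None:
        jobs += [(e.get("eye_id", f"eye{i}"), e) for i, e in enumerate(manifest)]
    if stacks is not None:
        jobs += list(stacks.items())
    records: list[EyeResultRecord] = []
    failures: list[dict[str, str]] = []
    for eye_id, job in jobs:
        t0 = time.time()
        try:
            if isinstance(job, FrameStack):
                stack, al = job, None
            else:
                stack = _load_stack(job)
                al = job.get("axial_length_mm")
            rec = process_eye(stack, config, axial_length_mm=al)
            rec.eye_id = eye_id
            records.append(rec)
            log.info("eye %s processed in %.1fs", eye_id, time.time() - t0)
        except Exception as exc:  # noqa: BLE001 - batch isolation by design
            failures.append({"eye_id": eye_id, "stage": "image_pipeline",
                             "error": str(exc)})
            log.warning("eye %s failed: %s", eye_id, exc)
    return records, failures


def write_records(records: list[EyeResultRecord], out_dir: str | Path,
                  config: PipelineConfig) -> tuple[Path, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = pd.DataFrame([r.as_row() for r in records])
    csv_path = out / "eye_metrics.csv"
    rows.to_csv(csv_path, index=False)
    json_path = out / "eye_metrics.json"
    with open(json_path, "w") as fh:
        json.dump({"config": config.to_json(),
                   "records": [dataclasses.asdict(r) for r in records]},
                  fh, indent=1, default=float)
    return csv_path, json_path


def run_cohort_pipeline(table: pd.DataFrame, config: PipelineConfig,
                        ) -> dict[str, Any]:
    """Impute -> screen -> mixed retests -> prune -> select -> LOOCV."""
    required = {stats_mod.PATIENT_COL, stats_mod.RESPONSE_COL}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValueError(f"cohort table lacks columns: {sorted(missing_cols)}")
    t0 = time.time()
    imputed = stats_mod.impute_rf(table, seed=config.seed)
    log.info("imputation done in %.1fs", time.time() - t0)

    screen = stats_mod.univariate_screen(
        imputed, alpha=config.screen_alpha,
        forced_retests=config.forced_retests)

    retests: dict[str, Any] = {}
    for res in screen:
        if not res.retest_requested:
            continue
        col = res.variable
        s = imputed[col]
        try:
            if not stats_mod._is_categorical(s):
                transformation = "none"
                fitres = stats_mod.fit_lmm(imputed, col,
                                           transformation=transformation)
                if fitres.shapiro_p is not None and fitres.shapiro_p < 0.05:
                    alt = stats_mod.fit_lmm(
                        imputed, col,
                        transformation="sqrt" if (s >= 0).all() else "power_1.05")
                    if (alt.shapiro_p or 0) > (fitres.shapiro_p or 0):
                        fitres = alt
            elif s.astype(str).nunique() == 2:
                fitres = stats_mod.fit_logistic_mixed(imputed, response=col,
                                                      fixed=[stats_mod.RESPONSE_COL])
            else:
                fitres = stats_mod.fit_multinomial_mixed(imputed, col)
            retests[col] = fitres
        except Exception as exc:  # noqa: BLE001 - reported, not fatal
            retests[col] = f"fit failed: {exc}"

    # the multivariate search starts from every feature (minus identifiers),
    # then correlation pruning and manual exclusions cut the candidate list
    candidates = [c for c in imputed.columns
                  if c not in (stats_mod.PATIENT_COL, "Eye",
                               stats_mod.RESPONSE_COL)]
    pruned, prune_report = stats_mod.correlation_prune(
        imputed, candidates, r_threshold=config.r_threshold,
        manual_exclusions=config.manual_exclusions)

    selection = stats_mod.backward_aic_select(imputed, pruned,
                                              significance_filter=config.report_alpha)
    auc = ci = None
    if selection.final_terms:
        auc, ci, _ = stats_mod.loocv_auc(imputed, selection.final_terms,
                                         unit=config.loocv_unit)
        selection.loocv_auc, selection.auc_ci = auc, ci

    strat_cols = {"perfusion_density", "faz_area_mm2"} <= set(imputed.columns)
    stratification = stats_mod.stratify_thresholds(imputed) if strat_cols else None

    return {
        "imputed": imputed,
        "univariate": screen,
        "mixed_retests": retests,
        "prune_report": prune_report,
        "selection": selection,
        "loocv_auc": auc,
        "auc_ci": ci,
        "stratification": stratification,
    }


def results_to_json(results: dict[str, Any], config: PipelineConfig) -> dict[str, Any]:
    """JSON-serializable summary of a cohort run."""
    sel = results["selection"]
    payload: dict[str, Any] = {
        "config": config.to_json(),
        "univariate": [dataclasses.asdict(r) for r in results["univariate"]],
        "mixed_retests": {
            k: (dataclasses.asdict(v) if not isinstance(v, str) else v)
            for k, v in results["mixed_retests"].items()},
        "prune_report": results["prune_report"],
        "selection": {
            "maximal_model_terms": sel.maximal_model_terms,
            "elimination_trace": sel.elimination_trace,
            "final_terms": sel.final_terms,
            "final_p_values": sel.final_p_values,
            "loocv_auc": sel.loocv_auc,
            "auc_ci": sel.auc_ci,
        },
    }
    if results["stratification"] is not None:
        payload["stratification"] = {
            k: (v.to_dict() if hasattr(v, "to_dict") else v)
            for k, v in results["stratification"].items()}
    return json.loads(json.dumps(payload, default=float))


def univariate_summary_tsv(results: dict[str, Any], path: str | Path) -> Path:
    """Tab-separated per-variable summary in the clinical-table layout:
    variable, test, screen p, and the mixed-model p where one was fitted."""
    rows = []
    retests = results["mixed_retests"]
    for r in results["univariate"]:
        mixed = retests.get(r.variable)
        mixed_p = ""
        if mixed is not None and not isinstance(mixed, str):
            mixed_p = "" if mixed.p_value is None else f"{mixed.p_value:.4g}"
        rows.append({
            "variable": r.variable, "test": r.test,
            "p_value": f"{r.p_value:.4g}" if r.p_value == r.p_value else "",
            "significant_10pct": "*" if r.significant_at_10pct else "",
            "mixed_model_p": mixed_p,
        })
    out = Path(path)
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    return out


def make_fixtures(kind: str, seed: int, out_dir: str | Path) -> list[Path]:
    """Write canonical small fixtures (phantom TIFF+truth, stack, cohort)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if kind == "phantom":
        spec = synth_mod.PhantomSpec(seed=seed)
        img, truth = synth_mod.generate_vessel_phantom(spec)
        tiff = out / f"phantom_seed{seed}.tiff"
        truth_path = out / f"phantom_seed{seed}_truth.json"
        synth_mod.save_phantom(img, truth, str(tiff), str(truth_path))
        written += [tiff, truth_path]
    elif kind == "stack":
        import tifffile

        spec = synth_mod.PhantomSpec(seed=seed)
        img, truth = synth_mod.generate_vessel_phantom(spec)
        stack = synth_mod.generate_frame_stack(img, 8, motion_sd=2.0,
                                               noise_sd=0.05, seed=seed,
                                               speckle_sd=0.15)
        manifest = []
        for i, frame in enumerate(stack.frames):
            p = out / f"stack_seed{seed}_frame{i}.tiff"
            top = frame.pixels.max() or 1.0
            tifffile.imwrite(p, (np.clip(frame.pixels, 0, None) / top
                                 * 65535).astype(np.uint16))
            manifest.append({"path": str(p), **frame.device_meta})
            written.append(p)
        mpath = out / f"stack_seed{seed}_manifest.json"
        with open(mpath, "w") as fh:
            json.dump([{"eye_id": f"synthetic_seed{seed}",
                        "pixel_size_mm": img.pixel_size_mm,
                        "frames": manifest,
                        "true_transforms": stack.true_transforms}], fh,
                      indent=1, default=float)
        written.append(mpath)
    elif kind == "cohort":
        table = synth_mod.generate_cohort(synth_mod.CohortSpec(seed=seed))
        p = out / f"cohort_seed{seed}.csv"
        table.to_csv(p, index=False, na_rep="")
        written.append(p)
    else:
        raise ValueError("kind must be phantom, stack or cohort")
    return written
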