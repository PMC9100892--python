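"""End-to-end orchestration: simulate -> stitch -> preprocess -> segment ->
measure, plus validation of reports against synthetic ground truth."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, phenotype, preprocess, segment, stitch, synth
from .config import MeasureConfig, PipelineConfig
from .frame import RGBDFrame, luma
from .phenotype import PhenotypeReport, PredictionModel

log = logging.getLogger("rootball")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_model(source: str) -> tuple[PredictionModel, PredictionModel]:
    if source == "paper":
        return phenotype.paper_surface_area_model(), phenotype.paper_length_model()
    d = json.loads(Path(source).read_text())
    return (PredictionModel(**d["surface_area"]), PredictionModel(**d["length"]))


def simulate_stage(cfg: PipelineConfig, out_dir: Path | None = None,
                   ) -> tuple[list[RGBDFrame], np.ndarray, synth.GroundTruth]:
    spec = cfg.synth
    panorama, gt = synth.generate_root_scene(spec)
    frames = synth.render_views(panorama, gt, spec=spec, seed=spec.seed)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, f in enumerate(frames):
            io.write_frame(out_dir, f"view{i}", f)
        io.write_color_png(out_dir / "panorama_color.png", panorama)
        io.write_mask_png(out_dir / "truth_root_mask.png", gt.root_mask)
        io.write_mask_png(out_dir / "truth_skeleton.png", gt.skeleton)
        io.write_homographies(out_dir / "truth_homographies.json",
                              gt.view_homographies)
        rows = [{"root": i, **r} for i, r in enumerate(gt.per_root)]
        pd.DataFrame(rows).to_csv(out_dir / "truth_roots.csv", index=False)
        truth = ground_truth_summary(gt)
        (out_dir / "truth_summary.json").write_text(json.dumps(truth, indent=2))
    return frames, panorama, gt


def ground_truth_summary(gt: synth.GroundTruth) -> dict:
    """Scalar phenotype truths derivable from a synthetic scene."""
    mask_n = int(gt.root_mask.sum())
    # encapsulation truth over the substrate band bounding the drawn roots
    return {
        "adtr_um": gt.mean_diameter,
        "sasr_cm2": gt.total_projected_area,
        "surface_length_cm": gt.total_length,
        "root_pixels": mask_n,
        "pixel_size_cm": gt.pixel_size_cm,
    }


def measure_frame(frame: RGBDFrame, cfg: PipelineConfig,
                  plant_id: str = "plant", out_dir: Path | None = None,
                  ) -> PhenotypeReport:
    """Preprocess, segment and measure one stitched + ROI-cropped frame."""
    pp = cfg.preprocess
    try:
        enhanced = preprocess.enhance(frame.color, pp.gain, pp.gamma)
        fg_mask, _ = preprocess.remove_background(
            (enhanced * 255).astype(np.uint8), pp)
        gray = luma(enhanced)
        flat = preprocess.homomorphic_filter(
            gray, pp.homomorphic_gamma_h, pp.homomorphic_gamma_l,
            pp.homomorphic_cutoff)
    except Exception as e:                                    # noqa: BLE001
        raise StageError("preprocess", e) from e

    try:
        vmap = segment.multiscale_vesselness(flat, cfg.segment)
        root_mask = segment.binarize_mask(vmap, foreground=fg_mask,
                                          min_area=cfg.measure.min_mask_area)
    except Exception as e:                                    # noqa: BLE001
        raise StageError("segment", e) from e

    report = measure_masks(root_mask, fg_mask, frame.depth, frame.intrinsics,
                           cfg.measure, plant_id=plant_id)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        io.write_mask_png(out_dir / f"{plant_id}_foreground.png", fg_mask)
        io.write_mask_png(out_dir / f"{plant_id}_root_mask.png", root_mask)
        io.write_float_png(out_dir / f"{plant_id}_vesselness.png", vmap.response)
    return report


def measure_masks(root_mask: np.ndarray, foreground: np.ndarray,
                  depth_mm: np.ndarray, intrinsics, mcfg: MeasureConfig,
                  plant_id: str = "plant", meta: dict | None = None,
                  ) -> PhenotypeReport:
    """Phenotype measurement from a root mask, foreground mask and depth."""
    try:
        cal = phenotype.calibrate(depth_mm, intrinsics, roi_mask=foreground)
        non_overlap = phenotype.extract_nonoverlapping(
            root_mask, erosion_r=mcfg.erosion_r, median_k=mcfg.median_k,
            dilation_r=mcfg.dilation_r)
        length_cm, _ = phenotype.skeleton_length(non_overlap, cal)
        diam = phenotype.average_diameter(non_overlap, length_cm, cal)
        enc = phenotype.encapsulation(root_mask, foreground, cal)
        sm, lm = _load_model(mcfg.model_source)
        return phenotype.assemble_report(diameter=diam, encaps=enc, cal=cal,
                                         surface_model=sm, length_model=lm,
                                         plant_id=plant_id, meta=meta)
    except StageError:
        raise
    except Exception as e:                                    # noqa: BLE001
        raise StageError("measure", e) from e


def run_pipeline(cfg: PipelineConfig, input_dir: str | Path | None = None,
                 out_dir: str | Path | None = None, plant_id: str = "plant",
                 ) -> tuple[PhenotypeReport, synth.GroundTruth | None]:
    """Full pipeline; ``input_dir=None`` simulates a scene from cfg.synth.

    Returns the report and, for simulated runs, the scene ground truth.
    """
    out = Path(out_dir) if out_dir is not None else None
    gt = None
    chash = cfg.config_hash()
    log.info("pipeline start (config %s)", chash)
    if input_dir is None:
        frames, _, gt = simulate_stage(cfg, out_dir=out)
        log.info("simulate: %d views, seed %d", len(frames), cfg.synth.seed)
    else:
        try:
            input_dir = Path(input_dir)
            frames = []
            i = 0
            while (input_dir / f"view{i}_color.png").exists():
                frames.append(io.read_frame(input_dir, f"view{i}"))
                i += 1
            if not frames:
                raise FileNotFoundError(f"no view*_color.png in {input_dir}")
        except Exception as e:                                # noqa: BLE001
            raise StageError("measure" if "depth" in str(e) else "load", e) from e

    try:
        stitched, homs = stitch.stitch_views(
            frames, reference_index=cfg.stitch.reference_index,
            reproj_tol_px=cfg.stitch.reproj_tol_px, seed=cfg.seed)
        log.info("stitch: canvas %s", stitched.shape)
        roi = cfg.roi
        if roi is None:
            h, w = stitched.shape
            roi = (0, int(0.22 * h), w, int(0.78 * h) - int(0.22 * h))
        roi_frame = stitch.extract_roi(stitched, roi)
    except StageError:
        raise
    except Exception as e:                                    # noqa: BLE001
        raise StageError("stitch", e) from e

    report = measure_frame(roi_frame, cfg, plant_id=plant_id, out_dir=out)
    report.meta.update({"config_hash": chash, "roi": list(roi)})
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        io.write_frame(out, "stitched", stitched)
        io.write_homographies(out / "estimated_homographies.json", homs)
        (out / f"{plant_id}_report.json").write_text(report.to_json())
        (out / f"{plant_id}_report.csv").write_text(
            PhenotypeReport.csv_header() + "\n" + report.csv_row() + "\n")
    log.info("report: ADTR=%.1f um, DSR=%.2f%%", report.adtr_um, report.dsr_pct)
    return report, gt


def run_batch(cfg: PipelineConfig, n_plants: int,
              out_dir: str | Path | None = None) -> pd.DataFrame:
    """Run ``n_plants`` simulated plants with per-plant seeds; CSV summary."""
    import dataclasses as _dc

    rows = []
    for i in range(n_plants):
        c = _dc.replace(cfg, synth=_dc.replace(cfg.synth, seed=cfg.synth.seed + i))
        rep, gt = run_pipeline(c, out_dir=None, plant_id=f"plant{i:03d}")
        row = rep.to_dict()
        row.pop("meta", None)
        if gt is not None:
            truth = ground_truth_summary(gt)
            row["true_adtr_um"] = truth["adtr_um"]
            row["true_sasr_cm2"] = truth["sasr_cm2"]
        rows.append(row)
    df = pd.DataFrame(rows)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        df.to_csv(Path(out_dir) / "batch_summary.csv", index=False)
    return df


def validate_against_truth(report: PhenotypeReport, truth: dict) -> pd.DataFrame:
    """Absolute and relative errors per phenotype, where truth is known.

    Mirrors the form of a scanner-comparison error table: one row per
    phenotype with estimate, reference, absolute error and relative error.
    """
    pairs = [("adtr_um", report.adtr_um, truth.get("adtr_um")),
             ("sasr_cm2", report.sasr_cm2, truth.get("sasr_cm2")),
             ("dsr_pct", report.dsr_pct, truth.get("dsr_pct"))]
    rows = []
    for name, est, ref in pairs:
        if ref is None:
            continue
        abs_err = est - ref
        rel_err = abs_err / ref if ref != 0 else np.nan
        rows.append({"phenotype": name, "estimate": est, "truth": ref,
                     "abs_error": abs_err, "rel_error": rel_err})
    return pd.DataFrame(rows)


def validate_batch(reports: list[PhenotypeReport], truths: list[dict],
                   ) -> pd.DataFrame:
    """Stack per-plant error tables and append median |relative error| rows."""
    tables = []
    for i, (rep, tr) in enumerate(zip(reports, truths)):
        t = validate_against_truth(rep, tr)
        t.insert(0, "plant", i)
        tables.append(t)
    df = pd.concat(tables, ignore_index=True)
    med = (df.assign(abs_rel_error=df.rel_error.abs())
             .groupby("phenotype")["abs_rel_error"].median()
             .rename("median_abs_rel_error").reset_index())
    return df.merge(med, on="phenotype", how="left")
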