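"""End-to-end pipeline: QC -> preprocess -> map -> metrics -> models.

Consumes a directory in the bundle layout written by the synthetic module
(or assembled from real exports in the same dialects) and produces the
analysis table, per-location model results, and the segmented breakpoint
report.  Every stage logs its parameters and input hashes for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, octa_preproc, sf_models, vf_data
from .config import TARGET_MM, TARGET_PX
from .focal_metrics import (
    MissingFocalValue,
    assemble_records,
    global_metrics,
    read_rnfl_csv,
    records_to_frame,
)
from .segmented_mixed import davies_test, fit_segmented_lmm, breakpoint_report
from .trajectory import (
    EyeGeometry,
    WedgeBuilder,
    fit_to_eye,
    load_default_params,
    load_params,
)
from .vf_data import check_reliability, mirror_to_right, read_vf_exam

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    input_dir: Path
    output_dir: Path
    trajectory_config: Path | None = None
    target_mm: float = TARGET_MM
    target_px: int = TARGET_PX
    alphas: tuple[float, ...] = (0.05, 0.001)
    exclusions: tuple[int, ...] = ()
    min_records_per_location: int = 10
    binarize_window_mm: float = octa_preproc.DEFAULT_BINARIZE_WINDOW_MM
    binarize_offset_frac: float = octa_preproc.DEFAULT_BINARIZE_OFFSET_FRAC
    vessel_scales_mm: tuple[float, ...] = octa_preproc.DEFAULT_VESSEL_SCALES_MM
    vesselness_threshold: float = octa_preproc.DEFAULT_VESSELNESS_THRESHOLD
    disc_mask_radius_deg: float = 2.0
    run_segmented: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("input_dir", "output_dir", "trajectory_config"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        for key in ("alphas", "exclusions", "vessel_scales_mm"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if not Path(self.input_dir).is_dir():
            raise PipelineError("config", f"input dir not found: {self.input_dir}")
        for a in self.alphas:
            if not (0 < a < 1):
                raise PipelineError("config", f"alpha {a} not in (0, 1)")
        manifest = Path(self.input_dir) / "manifest.json"
        if not manifest.exists():
            raise PipelineError("config", f"missing manifest: {manifest}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _norm_disc_xy(
    disc_xy: tuple[float, float],
    raw_shape: tuple[int, int],
    raw_mm_per_px: float,
    target_mm: float,
    target_px: int,
) -> tuple[float, float]:
    """Disc center re-expressed on the normalized (center-cropped) frame."""
    scale = raw_mm_per_px / (target_mm / target_px)
    cy, cx = raw_shape[0] / 2.0, raw_shape[1] / 2.0
    return (
        (disc_xy[0] - cx) * scale + target_px / 2.0,
        (disc_xy[1] - cy) * scale + target_px / 2.0,
    )


def run_pipeline(config: RunConfig) -> dict:
    config.validate()
    in_dir, out_dir = Path(config.input_dir), Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = (
        load_params(config.trajectory_config)
        if config.trajectory_config
        else load_default_params()
    )
    with open(in_dir / "manifest.json") as fh:
        subjects = json.load(fh)["subjects"]

    provenance: dict = {
        "version": __version__,
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "trajectory_atlas": params.name,
        "inputs": {},
        "stages": {},
    }

    grid = vf_data.build_grid("right")
    locations = vf_data.analysis_locations(grid, config.exclusions)

    # --- stage: ingest + QC -------------------------------------------------
    geometry_csv = in_dir / "geometry.csv"
    if not geometry_csv.exists():
        raise PipelineError("ingest", f"missing geometry file: {geometry_csv}")
    geo_df = pd.read_csv(geometry_csv)
    exams, qc_failures = {}, {}
    for sid in subjects:
        paths = {
            "vf_csv": in_dir / f"vf_{sid}.csv",
            "vf_meta": in_dir / f"vf_{sid}.json",
            "octa": in_dir / f"octa_{sid}.png",
            "octa_meta": in_dir / f"octa_{sid}.json",
            "rnfl": in_dir / f"rnfl_{sid}.csv",
        }
        for name, p in paths.items():
            if not p.exists():
                raise PipelineError("ingest", f"subject {sid}: missing {name}: {p}")
        provenance["inputs"][sid] = {k: _sha256(p) for k, p in paths.items()}
        exam = read_vf_exam(paths["vf_csv"], paths["vf_meta"])
        exam = mirror_to_right(exam)
        qc = check_reliability(exam)
        if not qc.passed:
            qc_failures[sid] = list(qc.reasons)
            log.warning("subject %s excluded by QC: %s", sid, qc.reasons)
            continue
        exams[sid] = exam
    provenance["stages"]["qc"] = {"excluded": qc_failures, "passed": sorted(exams)}
    if not exams:
        raise PipelineError("qc", "no subject passed reliability filtering")

    # --- stage: preprocess + map + metrics ----------------------------------
    pmaps, profiles, rois = {}, {}, {}
    per_subject_rows = []
    geo_by_sid = geo_df.set_index("subject_id")
    for sid, exam in exams.items():
        try:
            img = octa_preproc.read_octa_image(
                in_dir / f"octa_{sid}.png", in_dir / f"octa_{sid}.json"
            )
            pmap = octa_preproc.preprocess(
                img,
                scales_mm=config.vessel_scales_mm,
                vesselness_threshold=config.vesselness_threshold,
                window_mm=config.binarize_window_mm,
                offset_frac=config.binarize_offset_frac,
                target_mm=config.target_mm,
                target_px=config.target_px,
            )
            row = geo_by_sid.loc[sid]
            geom = EyeGeometry.from_pixels(
                (row["fovea_x_px"], row["fovea_y_px"]),
                (row["disc_x_px"], row["disc_y_px"]),
                mm_per_px=img.mm_per_px,
            )
            transform = fit_to_eye(params, geom)
            disc_n = _norm_disc_xy(
                geom.disc_xy, img.pixels.shape, img.mm_per_px,
                config.target_mm, config.target_px,
            )
            builder = WedgeBuilder(
                transform,
                (config.target_px, config.target_px),
                config.target_mm / config.target_px,
                disc_xy_px=disc_n,
                params=params,
            )
            rois[sid] = {loc.index: builder.wedge(loc) for loc in locations}
            pmaps[sid] = pmap
            profiles[sid] = read_rnfl_csv(in_dir / f"rnfl_{sid}.csv")

            yy, xx = np.mgrid[0 : config.target_px, 0 : config.target_px]
            r_px = np.hypot(xx - disc_n[0], yy - disc_n[1])
            disc_mask = r_px < config.disc_mask_radius_deg / (
                builder.mm_per_px / geom.mm_per_deg
            )
            gcd, grnflt = global_metrics(pmap, profiles[sid], disc_mask)
            per_subject_rows.append(
                {
                    "subject_id": sid,
                    "md_db": exam.md,
                    "global_cd": gcd,
                    "global_rnflt_um": grnflt,
                }
            )
        except (ValueError, MissingFocalValue) as exc:
            raise PipelineError("preprocess", f"subject {sid}: {exc}") from exc

    records = assemble_records(exams, pmaps, profiles, rois, locations)
    table = records_to_frame(records)
    table.to_csv(out_dir / "records.csv", index=False)
    per_subject = pd.DataFrame(per_subject_rows)
    per_subject.to_csv(out_dir / "per_subject.csv", index=False)
    provenance["stages"]["metrics"] = {"n_records": len(table)}

    # --- stage: per-location models ----------------------------------------
    fits, comps = sf_models.fit_all_locations(
        table, min_records=config.min_records_per_location
    )
    maps = sf_models.location_maps(fits, comps, alphas=config.alphas)
    maps["significance"].to_csv(out_dir / "location_fits.csv", index=False)
    maps["comparisons"].to_csv(out_dir / "model_comparisons.csv", index=False)
    glob = sf_models.global_fit(per_subject) if len(per_subject) >= 10 else None
    summary = {
        "focal": maps["summary"],
        "global": {mid: f.r_p for mid, f in glob.items()} if glob else None,
    }

    # --- stage: segmented mixed model ---------------------------------------
    seg_report = None
    if config.run_segmented:
        seg_results = {}
        for pid in ("fRNFLT", "fCD"):
            res = fit_segmented_lmm(table, pid)
            res = dataclasses.replace(
                res, davies_p=davies_test(table, pid)
            )
            seg_results[pid] = res
        seg_report = breakpoint_report(seg_results)
        seg_report.to_json(out_dir / "segmented.json", orient="records", indent=1)
        summary["segmented"] = json.loads(
            seg_report.to_json(orient="records")
        )

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1, default=str)
    return {
        "table": table,
        "per_subject": per_subject,
        "fits": fits,
        "comparisons": comps,
        "maps": maps,
        "global": glob,
        "segmented": seg_report,
        "summary": summary,
        "provenance": provenance,
    }
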