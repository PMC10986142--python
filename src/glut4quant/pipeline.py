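"""End-to-end orchestration: segment -> quantify -> analyze.

The pipeline consumes a directory of single-fibre TIFFs plus a design
table (subject, group, infusion, timepoint per image), runs membrane
segmentation and layer construction per image, pools the participant-wise
Otsu thresholds, measures every fibre, and fits the standard mixed models.
Per-image failures (blank fields, border-touching fibres, non-convergent
snakes) are recorded with a status and excluded from statistics with
counts reported — an explicit, rule-based version of the sample exclusions
a human analyst would otherwise make.  Runs are deterministic given the
inputs, and outputs are written atomically together with a config
snapshot so any result can be regenerated exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .core import FibreFieldImage, read_fibre_tiff
from .quantification import (
    fibre_type_cut,
    measure_fibre,
    participant_threshold,
    spots_to_frame,
)
from .segmentation import (
    LayerError,
    LayerMaskSet,
    MembraneContour,
    SegmentationError,
    build_layers,
    distance_map,
    segment_membrane,
)
from .stats import (
    ModelSpec,
    fit_mixed_model,
    posthoc_pairwise,
    summarize_study,
)

logger = logging.getLogger("glut4quant")

__all__ = ["PipelineResult", "segment_image", "run_quantification", "analyze_measurements", "run_pipeline"]


@dataclass
class PipelineResult:
    measurements: pd.DataFrame
    spots: pd.DataFrame
    statuses: pd.DataFrame
    thresholds: dict[str, float]
    contours: dict[str, MembraneContour] = field(default_factory=dict)


def segment_image(
    image: FibreFieldImage, config: PipelineConfig
) -> tuple[MembraneContour, LayerMaskSet]:
    """Membrane midline plus layer masks for one image."""
    contour = segment_membrane(
        image.channel("dystrophin"), config, image_id=image.image_id
    )
    dmap = distance_map(contour, image.shape)
    layers = build_layers(
        dmap,
        image.pixel_size_um,
        n_layers=config.n_layers,
        layer_width_um=config.layer_width_um,
        pm_thickness_px=config.pm_thickness_px,
        layer_origin=config.layer_origin,
    )
    return contour, layers


def run_quantification(
    images: list[FibreFieldImage],
    design_table: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Segment and measure a set of fibres with participant-pooled thresholds.

    Images are matched to the design table on ``image_id``; unmatched
    images or missing files yield per-image error statuses and the run
    continues.  The Otsu threshold is pooled across all of a participant's
    successfully segmented images; fibre typing uses the whole run as the
    MHC1 cohort context.
    """
    config = config or PipelineConfig()
    design = design_table.set_index("image_id")
    statuses: list[dict] = []
    segmented: dict[str, tuple[FibreFieldImage, LayerMaskSet, MembraneContour]] = {}

    for image in images:
        iid = image.image_id
        if iid not in design.index:
            statuses.append({"image_id": iid, "status": "error", "detail": "not in design table"})
            continue
        missing = [c for c in config.channel_order if c not in image.channel_names]
        if missing:
            statuses.append(
                {"image_id": iid, "status": "error", "detail": f"missing channel {missing}"}
            )
            continue
        try:
            contour, layers = segment_image(image, config)
        except SegmentationError as exc:
            status = (
                "excluded-border" if "border" in str(exc) else "segmentation-failed"
            )
            statuses.append({"image_id": iid, "status": status, "detail": str(exc)})
            logger.warning("%s: %s", iid, exc)
            continue
        except LayerError as exc:
            statuses.append({"image_id": iid, "status": "segmentation-failed", "detail": str(exc)})
            continue
        segmented[iid] = (image, layers, contour)
        statuses.append({"image_id": iid, "status": "ok", "detail": ""})

    # participant-pooled Otsu thresholds over fibre pixels
    thresholds: dict[str, float] = {}
    by_subject: dict[str, list[str]] = {}
    for iid in segmented:
        by_subject.setdefault(str(design.loc[iid, "subject_id"]), []).append(iid)
    for subject, iids in by_subject.items():
        thresholds[subject] = participant_threshold(
            [segmented[i][0].channel("glut4") for i in iids],
            [segmented[i][1].fibre_mask | segmented[i][1].pm_mask for i in iids],
        )

    # fibre typing: cohort context is the whole run's MHC1 fibre means
    mhc1_means = {
        iid: float(img.channel("mhc1")[layers.fibre_mask].mean())
        for iid, (img, layers, _) in segmented.items()
    }
    fibre_types: dict[str, str] = {}
    if mhc1_means:
        cut, _ = fibre_type_cut(
            np.array(list(mhc1_means.values())), config.fibre_type_fallback_cut
        )
        fibre_types = {iid: ("I" if m > cut else "II") for iid, m in mhc1_means.items()}

    rows = []
    spot_frames = []
    contours = {}
    for iid, (image, layers, contour) in segmented.items():
        subject = str(design.loc[iid, "subject_id"])
        measurement, spots = measure_fibre(
            image,
            layers,
            thresholds[subject],
            fibre_type=fibre_types.get(iid),
            min_area_px=config.spot_min_area_px,
            size_threshold_um=config.size_threshold_um,
            pcc_region=config.pcc_region,
        )
        measurement.subject_id = subject
        for col in ("group", "infusion", "timepoint_h"):
            if col in design.columns:
                setattr(measurement, col, design.loc[iid, col])
        rows.append(measurement.to_row())
        spot_frames.append(spots_to_frame(spots))
        contours[iid] = contour

    measurements = pd.DataFrame(rows).sort_values("image_id").reset_index(drop=True) if rows else pd.DataFrame()
    spots_df = (
        pd.concat(spot_frames, ignore_index=True).sort_values(["image_id", "label"]).reset_index(drop=True)
        if spot_frames
        else pd.DataFrame()
    )
    status_df = pd.DataFrame(statuses).sort_values("image_id").reset_index(drop=True)
    n_failed = int((status_df["status"] != "ok").sum()) if len(status_df) else 0
    if n_failed:
        logger.info("%d image(s) excluded from statistics", n_failed)
    return PipelineResult(
        measurements=measurements,
        spots=spots_df,
        statuses=status_df,
        thresholds=thresholds,
        contours=contours,
    )


#: the standard model battery: response -> (posthoc factor, extra fixed factors)
_STANDARD_MODELS: dict[str, dict] = {
    "pcc": {"fixed": ("group", "infusion", "timepoint_h"), "posthoc": "timepoint_h"},
    "total_intensity": {"fixed": ("group", "infusion", "timepoint_h", "fibre_type"), "posthoc": "timepoint_h"},
    "small_count": {"fixed": ("group", "infusion", "timepoint_h"), "posthoc": "timepoint_h", "per_layer": True},
    "large_count": {"fixed": ("group", "infusion", "timepoint_h"), "posthoc": "timepoint_h", "per_layer": True},
}


def analyze_measurements(
    measurements: pd.DataFrame, config: PipelineConfig | None = None
) -> dict:
    """Fit the standard mixed-model battery and post-hoc contrasts.

    Fixed factors with a single observed level are dropped (with a log
    message) rather than failing the run; per-layer count responses are
    fitted separately for the PM band and each intracellular layer, the
    granularity at which time contrasts are reported.
    """
    config = config or PipelineConfig()
    out: dict = {"models": {}, "contrasts": [], "summaries": summarize_study(measurements)}
    from .core import LAYER_NAMES

    for response, spec_kw in _STANDARD_MODELS.items():
        fixed = tuple(
            f
            for f in spec_kw["fixed"]
            if f in measurements.columns and measurements[f].nunique() >= 2
        )
        if not fixed:
            logger.info("skipping %s: no usable fixed factors", response)
            continue
        layers = list(LAYER_NAMES) if spec_kw.get("per_layer") else [None]
        for layer in layers:
            key = response if layer is None else f"{response}_{layer}"
            try:
                fit = fit_mixed_model(
                    measurements,
                    ModelSpec(
                        response=response,
                        fixed=fixed,
                        layer=layer,
                        count_transform=config.statistics.count_transform,
                    ),
                )
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning("model %s failed: %s", key, exc)
                continue
            out["models"][key] = fit
            factor = spec_kw["posthoc"]
            if factor in fixed:
                for c in posthoc_pairwise(
                    fit, factor, adjust=config.statistics.posthoc_adjust
                ):
                    out["contrasts"].append(
                        {
                            "model": key,
                            "factor": factor,
                            "comparison": c.comparison,
                            "estimate": c.estimate,
                            "std_error": c.std_error,
                            "statistic": c.statistic,
                            "df": c.df,
                            "p_value": c.p_value,
                            "p_adjusted": c.p_adjusted,
                            "significant": c.significant,
                        }
                    )
    out["contrasts"] = pd.DataFrame(out["contrasts"])
    return out


def _atomic_write_csv(df: pd.DataFrame, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, index=False)
    tmp.replace(path)


def run_pipeline(
    image_dir: str | Path,
    design_csv: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[PipelineResult, dict]:
    """Full run over a directory of TIFFs: quantify then analyze.

    Every image referenced by the design table is loaded (missing or
    unreadable files become per-image error entries; the run continues).
    Outputs — measurement, spot, status and contrast CSVs plus the config
    snapshot — are written atomically under ``out_dir``.

    Raises
    ------
    FileNotFoundError
        If the image directory contains no TIFF files at all.
    """
    config = config or PipelineConfig()
    image_dir = Path(image_dir)
    design = pd.read_csv(design_csv)
    tiffs = {p.stem: p for p in sorted(image_dir.glob("*.tif*"))}
    if not tiffs:
        raise FileNotFoundError(f"no TIFF images found in {image_dir}")

    images = []
    pre_statuses = []
    for iid in design["image_id"]:
        path = tiffs.get(str(iid))
        if path is None:
            pre_statuses.append(
                {"image_id": iid, "status": "error", "detail": "image file missing"}
            )
            continue
        try:
            images.append(read_fibre_tiff(path, image_id=str(iid)))
        except (ValueError, OSError) as exc:
            pre_statuses.append({"image_id": iid, "status": "error", "detail": str(exc)})

    result = run_quantification(images, design, config)
    if pre_statuses:
        result.statuses = (
            pd.concat([result.statuses, pd.DataFrame(pre_statuses)], ignore_index=True)
            .sort_values("image_id")
            .reset_index(drop=True)
        )

    analysis = analyze_measurements(result.measurements, config) if len(result.measurements) else {}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _atomic_write_csv(result.measurements, out / "measurements.csv")
        _atomic_write_csv(result.spots, out / "spots.csv")
        _atomic_write_csv(result.statuses, out / "statuses.csv")
        with open(out / "thresholds.json", "w") as fh:
            json.dump(result.thresholds, fh, indent=2, sort_keys=True)
        if analysis:
            _atomic_write_csv(analysis["contrasts"], out / "contrasts.csv")
            for name, table in analysis["summaries"].items():
                _atomic_write_csv(table, out / f"summary_{name}.csv")
        config.to_yaml(out / "config_snapshot.yaml")
    return result, analysis
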