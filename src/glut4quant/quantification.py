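"""GLUT4 spot detection, size classification, layer assignment, intensity
and colocalization measurement.

Spots are supra-threshold 8-connected components of the GLUT4 channel
within the membrane band and fibre interior.  The intensity threshold is a
single Otsu threshold per participant, computed on the pooled histogram of
all of that participant's fibre-mask pixels and applied identically to all
of their images.  Detected clusters are classified by area-equivalent
diameter — large strictly above 1 µm, small otherwise — and assigned to
the layer containing their centroid.  Colocalization of GLUT4 with the
dystrophin membrane stain is the pixel-wise Pearson correlation
coefficient over the fibre region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .core import LAYER_NAMES
from .segmentation import LayerMaskSet

__all__ = [
    "SpotRecord",
    "FibreMeasurement",
    "ThresholdError",
    "ColocalizationError",
    "participant_threshold",
    "detect_spots",
    "spots_to_frame",
    "layer_intensity",
    "colocalization_pcc",
    "classify_fibre_type",
    "fibre_type_cut",
    "measure_fibre",
]


class ThresholdError(ValueError):
    """Pooled histogram is degenerate (constant); no threshold exists."""


class ColocalizationError(ValueError):
    """PCC undefined: too few pixels or zero variance in a channel."""


@dataclass(frozen=True)
class SpotRecord:
    """One detected GLUT4 cluster."""

    image_id: str
    label: int
    area_um2: float
    equivalent_diameter_um: float
    size_class: str  # "small" | "large"
    centroid: tuple[float, float]  # (row, col), px
    layer: str  # "PM" | "L1".."L5" | "interior"


@dataclass
class FibreMeasurement:
    """Per-fibre analysis row: the unit of the downstream statistics."""

    image_id: str
    fibre_type: str | None
    total_intensity: float
    layer_intensities: dict[str, float]
    spot_counts: dict[str, dict[str, int]]  # layer -> {"small": n, "large": n}
    pcc: float
    subject_id: str | None = None
    group: str | None = None
    infusion: str | None = None
    timepoint_h: float | None = None
    extras: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "image_id": self.image_id,
            "subject_id": self.subject_id,
            "group": self.group,
            "infusion": self.infusion,
            "timepoint_h": self.timepoint_h,
            "fibre_type": self.fibre_type,
            "pcc": self.pcc,
            "total_intensity": self.total_intensity,
        }
        for layer in LAYER_NAMES:
            row[f"intensity_{layer}"] = self.layer_intensities.get(layer, np.nan)
            counts = self.spot_counts.get(layer, {})
            row[f"small_{layer}"] = counts.get("small", 0)
            row[f"large_{layer}"] = counts.get("large", 0)
        interior = self.spot_counts.get("interior", {})
        row["small_interior"] = interior.get("small", 0)
        row["large_interior"] = interior.get("large", 0)
        return row


def participant_threshold(
    glut4_rasters: list[np.ndarray],
    fibre_masks: list[np.ndarray],
) -> float:
    """Single Otsu threshold for one participant's pooled fibre pixels.

    Histograms are taken over fibre-mask pixels only, pooled across all of
    the participant's images, and the threshold maximises the between-class
    variance over every candidate integer intensity level (the first
    maximiser is taken on ties).  Float rasters are rounded to integer
    levels first.

    Raises
    ------
    ThresholdError
        If the pooled histogram is constant.
    """
    if len(glut4_rasters) == 0 or len(glut4_rasters) != len(fibre_masks):
        raise ValueError("need one fibre mask per raster, at least one image")
    pooled = np.concatenate(
        [np.asarray(img)[np.asarray(m, bool)].ravel() for img, m in zip(glut4_rasters, fibre_masks)]
    )
    if pooled.size == 0:
        raise ThresholdError("no fibre pixels to threshold")
    values = np.round(pooled).astype(np.int64)
    if values.min() == values.max():
        raise ThresholdError("pooled histogram is constant; input unthresholdable")
    counts = np.bincount(values - values.min())
    centers = np.arange(values.min(), values.max() + 1)
    return float(threshold_otsu(hist=(counts, centers)))


def _layer_of_component(
    layers: LayerMaskSet, centroid: tuple[float, float], coords: np.ndarray
) -> str:
    layer = layers.layer_of_point(centroid)
    if layer is not None:
        return layer
    # concave component whose centroid pixel falls outside every band:
    # fall back to the member pixel nearest the centroid
    d2 = ((coords - np.asarray(centroid)) ** 2).sum(axis=1)
    nearest = coords[np.argmin(d2)]
    return layers.layer_of_point((float(nearest[0]), float(nearest[1]))) or "PM"


def detect_spots(
    glut4: np.ndarray,
    threshold: float,
    layers: LayerMaskSet,
    pixel_size_um: float,
    *,
    image_id: str = "",
    min_area_px: int = 2,
    size_threshold_um: float = 1.0,
) -> list[SpotRecord]:
    """Detect GLUT4 clusters above the participant threshold.

    8-connected supra-threshold components within the membrane band plus
    fibre interior; components below the minimum-area floor are discarded.
    Equivalent diameter is the area-equivalent circle diameter
    ``2*sqrt(area/pi)``; a spot is large iff that diameter strictly exceeds
    the size threshold (1 µm), small otherwise.  Layer membership is by
    centroid.
    """
    region = layers.pm_mask | layers.interior_mask
    for m in layers.inner_masks:
        region = region | m
    mask = (np.asarray(glut4) > threshold) & region
    labelled = cc_label(mask, connectivity=2)
    records: list[SpotRecord] = []
    for prop in regionprops(labelled):
        if prop.area < min_area_px:
            continue
        area_um2 = float(prop.area) * pixel_size_um**2
        eqd = 2.0 * np.sqrt(area_um2 / np.pi)
        records.append(
            SpotRecord(
                image_id=image_id,
                label=int(prop.label),
                area_um2=area_um2,
                equivalent_diameter_um=float(eqd),
                size_class="large" if eqd > size_threshold_um else "small",
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                layer=_layer_of_component(layers, prop.centroid, prop.coords),
            )
        )
    return records


def spots_to_frame(spots: list[SpotRecord]) -> pd.DataFrame:
    cols = ["image_id", "label", "area_um2", "equivalent_diameter_um", "size_class",
            "centroid_row", "centroid_col", "layer"]
    rows = [
        (s.image_id, s.label, s.area_um2, s.equivalent_diameter_um, s.size_class,
         s.centroid[0], s.centroid[1], s.layer)
        for s in spots
    ]
    return pd.DataFrame(rows, columns=cols)


def layer_intensity(glut4: np.ndarray, layers: LayerMaskSet) -> tuple[dict[str, float], float]:
    """Mean raw GLUT4 intensity per layer plus the whole-fibre mean.

    An empty mask yields NaN (missing), never zero.
    """
    img = np.asarray(glut4, dtype=float)
    means: dict[str, float] = {}
    for name, mask in zip(LAYER_NAMES, [layers.pm_mask] + layers.inner_masks):
        means[name] = float(img[mask].mean()) if mask.any() else float("nan")
    total = float(img[layers.fibre_mask].mean()) if layers.fibre_mask.any() else float("nan")
    return means, total


def colocalization_pcc(
    glut4: np.ndarray, dystrophin: np.ndarray, region_mask: np.ndarray
) -> float:
    """Pearson correlation of the two channels over the region's pixels.

    Raises
    ------
    ColocalizationError
        If the region has fewer than 2 pixels or either channel has zero
        variance there (the coefficient is undefined).
    """
    m = np.asarray(region_mask, bool)
    x = np.asarray(glut4, float)[m]
    y = np.asarray(dystrophin, float)[m]
    if x.size < 2:
        raise ColocalizationError("region must contain at least 2 pixels")
    if x.std() == 0 or y.std() == 0:
        raise ColocalizationError("zero variance in a channel; PCC undefined")
    return float(np.corrcoef(x, y)[0, 1])


def fibre_type_cut(
    cohort_means: np.ndarray,
    fallback_cut: float,
    *,
    min_contrast: float = 2.0,
) -> tuple[float, bool]:
    """Data-driven MHC1 positivity cut for a cohort of fibre mean intensities.

    Otsu on the cohort's per-fibre means; if the cohort is too small or the
    split is not clearly bimodal (high-class mean less than ``min_contrast``
    times the low-class mean), the configured fallback cut is used with a
    warning.  Returns ``(cut, data_driven)``.
    """
    means = np.asarray(cohort_means, dtype=float)
    if means.size >= 2 and np.ptp(means) > 0:
        # exact Otsu criterion over the sorted means (no histogram binning,
        # which can return a cut inside the low class for small cohorts);
        # the cut is placed midway between the two classes
        x = np.sort(means)
        n = x.size
        csum = np.cumsum(x)
        i = np.arange(1, n)
        w0, w1 = i, n - i
        mu0 = csum[:-1] / w0
        mu1 = (csum[-1] - csum[:-1]) / w1
        split = int(np.argmax(w0 * w1 * (mu0 - mu1) ** 2)) + 1
        cut = float((x[split - 1] + x[split]) / 2.0)
        lo, hi = x[:split], x[split:]
        if hi.mean() >= min_contrast * max(lo.mean(), 1e-12):
            return cut, True
    warnings.warn(
        "MHC1 cohort distribution not clearly bimodal; using fallback positivity cut",
        stacklevel=2,
    )
    return float(fallback_cut), False


def classify_fibre_type(
    mhc1: np.ndarray,
    fibre_mask: np.ndarray,
    cohort_means: np.ndarray | None,
    *,
    fallback_cut: float = 1000.0,
) -> str:
    """Type the fibre by MHC1 positivity: above the cut is type I, else II."""
    mean = float(np.asarray(mhc1, float)[np.asarray(fibre_mask, bool)].mean())
    if cohort_means is None or len(cohort_means) < 2:
        warnings.warn("no cohort context; using fallback positivity cut", stacklevel=2)
        cut = fallback_cut
    else:
        cut, _ = fibre_type_cut(np.asarray(cohort_means), fallback_cut)
    return "I" if mean > cut else "II"


def measure_fibre(
    image,
    layers: LayerMaskSet,
    threshold: float,
    *,
    fibre_type: str | None = None,
    min_area_px: int = 2,
    size_threshold_um: float = 1.0,
    pcc_region: str = "whole_fibre",
) -> tuple[FibreMeasurement, list[SpotRecord]]:
    """Assemble the full per-fibre measurement row from one image.

    ``pcc_region`` selects the pixels for the colocalization coefficient:
    ``"whole_fibre"`` (fibre plus membrane band, the default) or
    ``"pm_band"`` (the 3-px membrane band only).
    """
    glut4 = image.channel("glut4")
    dystrophin = image.channel("dystrophin")
    spots = detect_spots(
        glut4,
        threshold,
        layers,
        image.pixel_size_um,
        image_id=image.image_id,
        min_area_px=min_area_px,
        size_threshold_um=size_threshold_um,
    )
    counts: dict[str, dict[str, int]] = {}
    for s in spots:
        counts.setdefault(s.layer, {"small": 0, "large": 0})[s.size_class] += 1
    means, total = layer_intensity(glut4, layers)
    region = layers.pm_mask if pcc_region == "pm_band" else (layers.fibre_mask | layers.pm_mask)
    pcc = colocalization_pcc(glut4, dystrophin, region)
    measurement = FibreMeasurement(
        image_id=image.image_id,
        fibre_type=fibre_type,
        total_intensity=total,
        layer_intensities=means,
        spot_counts=counts,
        pcc=pcc,
    )
    return measurement, spots
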