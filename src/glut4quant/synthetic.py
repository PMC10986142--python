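"""Synthetic fibre phantoms and whole study datasets with known ground truth.

Real validation images for this kind of assay are not publicly deposited,
so every pipeline stage is tested by parameter recovery on simulated data.
The generator emulates single-fibre confocal fields: a bright dystrophin
ring along the fibre boundary, punctate GLUT4 staining as small (< 1 µm)
and large (> 1 µm) clusters concentrated at and near the membrane, an MHC1
channel that is bimodal across fibres (type I bright, type II dark), and
Poisson photon noise plus Gaussian read noise.

Two levels of simulation are provided:

* **pixel level** — :func:`generate_fibre_phantom` / :func:`render_image` /
  :func:`generate_study` build scenes and render rasters, exercising
  segmentation and spot detection;
* **measurement level** — :func:`simulate_measurements` samples per-fibre
  measurement tables directly from the same condition rates (subject
  random intercepts on log-rates and log-intensities), exercising the
  mixed-model statistics at study scale without rendering thousands of
  images.

The planted effect structure follows the physiology being modelled: a
colocalization (PCC) rise from 0 h to 2 h of insulin infusion that is
maintained at 6 h, a decline in small membrane-proximal GLUT4 spots from
2 h to 6 h, training-status differences in the small/large composition of
membrane spots, and a type II > type I GLUT4 intensity excess.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import shapely
from scipy.special import erfc
from pydantic import BaseModel, Field, model_validator

from .core import ALL_REGIONS, LAYER_NAMES, FibreFieldImage
from .segmentation import MembraneContour, distance_map

__all__ = [
    "EffectSpec",
    "NoiseSpec",
    "Condition",
    "StudyDesign",
    "PlantedSpot",
    "FibrePhantom",
    "GroundTruth",
    "StudySimulation",
    "layer_label_from_distance",
    "generate_fibre_phantom",
    "render_image",
    "generate_study",
    "simulate_measurements",
]

GROUPS = ("trained", "sedentary")
INFUSIONS = ("lipid", "glycerol")
TIMEPOINTS = (0, 2, 6)


class NoiseSpec(BaseModel):
    """Confocal noise model: Poisson photon noise + additive Gaussian read noise."""

    background_mean: float = Field(100.0, ge=0, description="camera offset added to all channels")
    read_noise_sd: float = Field(10.0, ge=0)
    photon_scale: float = Field(1.0, ge=0, description="photons per intensity unit; 0 disables shot noise")


class EffectSpec(BaseModel):
    """All condition rates and effect sizes driving the simulation.

    Proportional effects are expressed as fractions (0.09 = +9%).  The
    per-layer spot rates are free parameters of the scene model (absolute
    counts per fibre are not a quantity the assay pins down); the effect
    sizes and spot-composition fractions are the study conditions being
    emulated.
    """

    # --- planted effects -------------------------------------------------
    pcc_baseline: dict[str, float] = Field(
        default_factory=lambda: {"trained": 0.50, "sedentary": 0.44},
        description="baseline GLUT4-dystrophin PCC by training status",
    )
    pcc_delta_0_to_2h: dict[str, float] = Field(
        default_factory=lambda: {
            "trained:lipid": 0.02,
            "trained:glycerol": 0.02,
            "sedentary:lipid": 0.09,
            "sedentary:glycerol": 0.04,
        },
        description="proportional PCC rise at 2 h (maintained at 6 h), keyed group:infusion",
    )
    small_spot_decline_2_to_6h: float = Field(
        0.20, ge=0, le=1, description="proportional 2->6 h drop in PM and L1 small-spot rate"
    )
    trained_small_fraction_pm: float = Field(0.99, ge=0, le=1)
    sedentary_small_fraction_pm: float = Field(0.95, ge=0, le=1)
    small_fraction_inner: float = Field(0.95, ge=0, le=1, description="small fraction in L1..L5 and interior")
    type2_intensity_excess: dict[str, float] = Field(
        default_factory=lambda: {"trained": 0.07, "sedentary": 0.12},
        description="proportional GLUT4 intensity excess of type II over type I fibres",
    )

    # --- scene model -----------------------------------------------------
    spot_rates: dict[str, float] = Field(
        default_factory=lambda: {
            "PM": 25.0, "L1": 8.0, "L2": 6.0, "L3": 5.0, "L4": 4.0, "L5": 3.0,
            "interior": 6.0,
        },
        description="mean total spots per fibre per layer (Poisson)",
    )
    # planted sizes keep clear of the 1 µm class boundary: within ~0.2 µm of
    # it, single-pixel area quantization plus the membrane-background lift
    # makes the class of a detected spot ill-defined at this pixel size
    small_diameter_um: tuple[float, float] = (0.4, 0.8)
    large_diameter_um: tuple[float, float] = (1.3, 2.0)
    psf_sigma_um: float = Field(0.1, gt=0, description="Gaussian PSF sigma blurring spot edges")
    spot_peak: float = Field(3000.0, gt=0)
    spot_peak_log_sd: float = Field(0.15, ge=0)
    glut4_diffuse: float = Field(200.0, ge=0, description="diffuse GLUT4 level inside the fibre")
    dystrophin_peak: float = Field(2500.0, gt=0)
    mhc1_type1_level: float = Field(3000.0, gt=0)
    mhc1_type2_level: float = Field(150.0, ge=0)
    p_type1: float = Field(0.5, ge=0, le=1)

    # --- geometry --------------------------------------------------------
    field_size_um: float = Field(51.2, gt=0)
    pixel_size_um: float = Field(0.2, gt=0)
    fibre_radius_um: tuple[float, float] = (13.0, 16.0)
    membrane_thickness_px: float = Field(3.0, gt=0)
    layer_width_um: float = Field(1.0, gt=0)
    n_layers: int = Field(5, ge=1)
    bit_depth: int = Field(16, ge=8, le=16)

    # --- between-fibre / between-subject variation ------------------------
    subject_sd_log: float = Field(0.15, ge=0, description="SD of subject intercepts on log rates/intensities")
    pcc_subject_sd: float = Field(0.04, ge=0)
    pcc_residual_sd: float = Field(0.08, ge=0)
    intensity_cv: float = Field(0.10, ge=0, description="lognormal CV of per-fibre intensities")
    layer_intensity_means: dict[str, float] = Field(
        default_factory=lambda: {
            "PM": 800.0, "L1": 320.0, "L2": 300.0, "L3": 290.0, "L4": 285.0, "L5": 280.0,
        },
        description="mean GLUT4 intensity per layer (measurement-level sampler)",
    )
    total_intensity_mean: float = Field(300.0, gt=0)
    noise: NoiseSpec = Field(default_factory=NoiseSpec)
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "EffectSpec":
        for key, val in {**self.pcc_baseline, **self.pcc_delta_0_to_2h}.items():
            if not 0 <= val <= 1:
                raise ValueError(f"proportion {key}={val} outside [0, 1]")
        if any(r < 0 for r in self.spot_rates.values()):
            raise ValueError("spot rates must be nonnegative")
        if any(v < 0 for v in self.type2_intensity_excess.values()):
            raise ValueError("intensity excess must be nonnegative")
        for lo, hi in (self.small_diameter_um, self.large_diameter_um, self.fibre_radius_um):
            if not 0 < lo <= hi:
                raise ValueError("ranges must be positive and ordered")
        return self

    # -- condition rates ---------------------------------------------------
    def small_fraction(self, layer: str, group: str) -> float:
        if layer == "PM":
            return (
                self.trained_small_fraction_pm
                if group == "trained"
                else self.sedentary_small_fraction_pm
            )
        return self.small_fraction_inner

    def time_multiplier(self, layer: str, size_class: str, timepoint_h: float) -> float:
        """Small-spot rate multiplier: the 2->6 h decline at PM and layer 1."""
        if size_class == "small" and layer in ("PM", "L1") and timepoint_h >= 6:
            return 1.0 - self.small_spot_decline_2_to_6h
        return 1.0

    def pcc_mean(self, group: str, infusion: str, timepoint_h: float) -> float:
        base = self.pcc_baseline[group]
        if timepoint_h >= 2:
            base *= 1.0 + self.pcc_delta_0_to_2h[f"{group}:{infusion}"]
        return base

    def condition_rates(self, condition: "Condition") -> dict[str, float]:
        """True per-layer small/large spot means and PCC mean for one design cell."""
        out: dict[str, float] = {"pcc_mean": self.pcc_mean(condition.group, condition.infusion, condition.timepoint_h)}
        for layer in ALL_REGIONS:
            rate = self.spot_rates.get(layer, 0.0)
            frac = self.small_fraction(layer, condition.group)
            out[f"small_{layer}"] = rate * frac * self.time_multiplier(layer, "small", condition.timepoint_h)
            out[f"large_{layer}"] = rate * (1.0 - frac)
        return out


@dataclass(frozen=True)
class Condition:
    """One design cell: group x infusion x timepoint x fibre type."""

    group: str
    infusion: str
    timepoint_h: float
    fibre_type: str = "I"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.infusion not in INFUSIONS:
            raise ValueError(f"unknown infusion {self.infusion!r}")
        if self.fibre_type not in ("I", "II"):
            raise ValueError(f"fibre_type must be 'I' or 'II', got {self.fibre_type!r}")


@dataclass(frozen=True)
class PlantedSpot:
    center_um: tuple[float, float]  # (row, col), µm
    diameter_um: float
    peak_intensity: float
    layer: str
    size_class: str


@dataclass
class FibrePhantom:
    """Ground-truth scene for one fibre image."""

    boundary_um: np.ndarray  # (n, 2) closed (row, col) curve, µm
    membrane_thickness_um: float
    planted_spots: list[PlantedSpot]
    fibre_type: str
    mhc1_level: float
    glut4_diffuse: float
    field_size_um: float
    intensity_multiplier: float = 1.0
    #: target noiseless GLUT4-dystrophin PCC; None leaves colocalization
    #: to whatever the spot scene produces
    pcc_target: float | None = None


@dataclass
class GroundTruth:
    """Everything the generator knew: one entry per generated image."""

    phantoms: dict[str, FibrePhantom] = dc_field(default_factory=dict)
    subject_effects: dict[str, dict[str, float]] = dc_field(default_factory=dict)
    condition_rates: dict[str, dict[str, float]] = dc_field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "subject_effects": self.subject_effects,
            "condition_rates": self.condition_rates,
            "images": {
                iid: {
                    "boundary_um": ph.boundary_um.tolist(),
                    "fibre_type": ph.fibre_type,
                    "mhc1_level": ph.mhc1_level,
                    "spots": [
                        {
                            "center_um": list(s.center_um),
                            "diameter_um": s.diameter_um,
                            "peak_intensity": s.peak_intensity,
                            "layer": s.layer,
                            "size_class": s.size_class,
                        }
                        for s in ph.planted_spots
                    ],
                }
                for iid, ph in self.phantoms.items()
            },
        }


@dataclass
class StudySimulation:
    images: list[FibreFieldImage]
    design_table: pd.DataFrame
    ground_truth: GroundTruth


class StudyDesign(BaseModel):
    """Study layout: between-subject group x infusion, within-subject time.

    Defaults mirror the emulated study: two training-status groups by two
    infusion arms with repeated biopsies at 0, 2 and 6 h and at least 30
    images per participant per timepoint.
    """

    subjects_per_cell: int = Field(5, ge=1)
    images_per_timepoint: int = Field(30, ge=1)
    timepoints: tuple[float, ...] = TIMEPOINTS
    groups: tuple[str, ...] = GROUPS
    infusions: tuple[str, ...] = INFUSIONS

    @property
    def n_subjects(self) -> int:
        return self.subjects_per_cell * len(self.groups) * len(self.infusions)

    def subject_rows(self) -> list[tuple[str, str, str]]:
        rows = []
        i = 0
        for group, infusion in itertools.product(self.groups, self.infusions):
            for _ in range(self.subjects_per_cell):
                i += 1
                rows.append((f"S{i:02d}", group, infusion))
        return rows


def layer_label_from_distance(
    d_um: float,
    pixel_size_um: float,
    *,
    pm_thickness_px: float = 3.0,
    layer_width_um: float = 1.0,
    n_layers: int = 5,
) -> str | None:
    """Layer name for a signed inward distance (µm) to the membrane midline.

    Applies the same band rules as the segmentation layer builder: the PM
    band is ``|d| <= h`` with ``h`` the half-thickness in µm; layer k is
    ``(h + (k-1)w, h + kw]``; deeper is ``interior``; outside the PM band's
    outer edge is ``None``.
    """
    half = pm_thickness_px / 2.0 * pixel_size_um
    if abs(d_um) <= half:
        return "PM"
    if d_um < -half:
        return None
    k = math.ceil((d_um - half) / layer_width_um - 1e-12)
    return f"L{k}" if k <= n_layers else "interior"


def _random_boundary(spec: EffectSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth star-shaped closed boundary with >= 2 µm field margin.

    Radius as a low-order Fourier series in angle gives a simple closed
    curve with bounded curvature — non-circular, so the snake and distance
    map are exercised on realistic geometry.
    """
    r0 = rng.uniform(*spec.fibre_radius_um)
    amps = rng.uniform(0.0, 0.05, size=3)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    centre = spec.field_size_um / 2 + rng.uniform(-1.5, 1.5, size=2)
    theta = np.linspace(0, 2 * np.pi, 400, endpoint=False)
    radius = r0 * (1 + sum(a * np.cos((k + 1) * theta + p) for k, (a, p) in enumerate(zip(amps, phases))))
    margin = spec.field_size_um / 2 - np.abs(centre - spec.field_size_um / 2).max()
    if radius.max() > margin - 2.0:  # pragma: no cover - radii ranges keep this safe
        radius *= (margin - 2.0) / radius.max()
    return np.column_stack([centre[0] + radius * np.sin(theta), centre[1] + radius * np.cos(theta)])


def _layer_band_um(layer: str, spec: EffectSpec) -> tuple[float, float]:
    """Signed-distance band (lo, hi] in µm for one layer under the spec geometry."""
    half = spec.membrane_thickness_px / 2.0 * spec.pixel_size_um
    w = spec.layer_width_um
    if layer == "PM":
        return (-half, half)
    if layer == "interior":
        return (half + spec.n_layers * w, np.inf)
    k = int(layer[1:])
    return (half + (k - 1) * w, half + k * w)


def generate_fibre_phantom(
    spec: EffectSpec,
    condition: Condition,
    rng: np.random.Generator,
    *,
    rate_multiplier: float = 1.0,
    intensity_multiplier: float = 1.0,
    pcc_shift: float = 0.0,
    plant_pcc: bool = True,
) -> FibrePhantom:
    """Build one ground-truth fibre scene for a design cell.

    Per-layer spot counts are Poisson with the cell's rates; size classes
    are Bernoulli with the cell's small fraction; radial placement is
    uniform within the layer's distance band, inset by one pixel from each
    band edge so the true layer label is stable under sub-pixel centroid
    error, with a minimum centre separation so planted clusters remain
    resolvable objects.  Every spot is labelled with its true layer,
    verified against the exact signed distance to the boundary.

    Raises
    ------
    ValueError
        If the spec's spot diameters exceed the fibre diameter, or a valid
        placement cannot be found (over-packed scene).
    """
    if spec.large_diameter_um[1] >= 2 * spec.fibre_radius_um[0]:
        raise ValueError("spot diameters exceed fibre diameter")
    boundary = _random_boundary(spec, rng)
    ring = shapely.LinearRing(np.asarray(boundary, dtype=float))
    inset = spec.pixel_size_um  # 1 px

    fibre_type = condition.fibre_type
    intensity_mult = intensity_multiplier * (
        1.0 + (spec.type2_intensity_excess[condition.group] if fibre_type == "II" else 0.0)
    )

    rates = spec.condition_rates(condition)
    placed: list[PlantedSpot] = []

    polygon = shapely.Polygon(ring)
    centre = boundary.mean(axis=0)

    def _try_place(layer: str, diameter: float) -> tuple[float, float] | None:
        lo, hi = _layer_band_um(layer, spec)
        # inset 1 px from each band edge so the true label survives sub-pixel
        # centroid error; PM centres stay inside (or on) the boundary
        lo_t = max(lo + inset, 0.0)
        hi_t = hi - inset if np.isfinite(hi) else hi
        for _ in range(500):
            if layer == "interior":
                cand = centre + rng.uniform(-1, 1, 2) * spec.fibre_radius_um[1]
            else:
                target_d = rng.uniform(lo_t, hi_t)
                b = boundary[rng.integers(0, len(boundary))]
                inward = centre - b
                inward /= np.linalg.norm(inward)
                cand = b + target_d * inward
            point = shapely.Point(cand)
            d_act = shapely.distance(point, ring)
            if not polygon.contains(point):
                d_act = -d_act
            if layer == "interior":
                if d_act <= lo + inset:
                    continue
            elif not (lo_t <= d_act <= hi_t):
                continue
            ok = all(
                np.hypot(cand[0] - s.center_um[0], cand[1] - s.center_um[1])
                >= (diameter + s.diameter_um) / 2 + 3 * spec.pixel_size_um
                for s in placed
            )
            if ok:
                return float(cand[0]), float(cand[1])
        return None

    # place large spots first (harder to pack), then small
    for size_class, diam_range in (("large", spec.large_diameter_um), ("small", spec.small_diameter_um)):
        for layer in ALL_REGIONS:
            mean = rates[f"{size_class}_{layer}"] * rate_multiplier
            n = rng.poisson(mean) if mean > 0 else 0
            for _ in range(n):
                diameter = rng.uniform(*diam_range)
                centre_um = _try_place(layer, diameter)
                if centre_um is None:
                    raise ValueError(
                        f"could not place a {size_class} spot in {layer}: scene over-packed"
                    )
                peak = spec.spot_peak * intensity_mult
                if spec.spot_peak_log_sd > 0:
                    peak *= float(rng.lognormal(0.0, spec.spot_peak_log_sd))
                placed.append(
                    PlantedSpot(
                        center_um=centre_um,
                        diameter_um=diameter,
                        peak_intensity=peak,
                        layer=layer,
                        size_class=size_class,
                    )
                )

    mhc1 = spec.mhc1_type1_level if fibre_type == "I" else spec.mhc1_type2_level
    pcc_target = None
    if plant_pcc:
        pcc_target = float(
            np.clip(
                spec.pcc_mean(condition.group, condition.infusion, condition.timepoint_h)
                + pcc_shift,
                0.05,
                0.95,
            )
        )
    return FibrePhantom(
        boundary_um=boundary,
        membrane_thickness_um=spec.membrane_thickness_px * spec.pixel_size_um,
        planted_spots=placed,
        fibre_type=fibre_type,
        mhc1_level=mhc1 * float(rng.lognormal(0.0, 0.05)),
        glut4_diffuse=spec.glut4_diffuse * intensity_mult,
        field_size_um=spec.field_size_um,
        intensity_multiplier=intensity_mult,
        pcc_target=pcc_target,
    )


def _solve_membrane_amplitude(
    glut4: np.ndarray,
    dystrophin: np.ndarray,
    profile: np.ndarray,
    region: np.ndarray,
    target: float,
) -> float:
    """Amplitude c >= 0 such that corr(glut4 + c*profile, dystrophin) = target.

    The correlation over the region increases monotonically towards 1 as c
    grows (the profile is the dystrophin shape itself), so a bracketed
    root-find suffices; if the scene already correlates above the target,
    no membrane component is added.
    """
    g = glut4[region].astype(float)
    d = dystrophin[region].astype(float)
    p = profile[region].astype(float)

    def corr(c: float) -> float:
        return float(np.corrcoef(g + c * p, d)[0, 1])

    if corr(0.0) >= target:
        return 0.0
    hi = max(1.0, float(np.ptp(g)))
    while corr(hi) < target:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover - unreachable for sane targets
            return hi
    from scipy.optimize import brentq

    return float(brentq(lambda c: corr(c) - target, 0.0, hi, xtol=1e-3))


def render_image(
    phantom: FibrePhantom,
    spec: EffectSpec,
    rng: np.random.Generator,
    *,
    image_id: str = "",
) -> FibreFieldImage:
    """Forward optics model: phantom scene -> noisy 3-channel raster.

    The dystrophin channel is a ridge of Gaussian cross-profile along the
    boundary with FWHM equal to the membrane thickness; the GLUT4 channel
    is the diffuse intracellular level plus a sum of isotropic 2-D
    Gaussian spots whose FWHM equals the planted diameter; the MHC1
    channel is uniform at the fibre's MHC1 level inside the boundary.
    Poisson photon noise and Gaussian read noise are applied last and the
    result is clipped to the declared bit depth.
    """
    ps = spec.pixel_size_um
    n = int(round(phantom.field_size_um / ps))
    if n < 64:
        raise ValueError("rendered field must be at least 64x64 px")
    boundary_px = phantom.boundary_um / ps
    contour = MembraneContour(vertices=boundary_px, image_id=image_id)
    d_um = distance_map(contour, (n, n)) * ps
    inside = d_um > 0

    s_mem = phantom.membrane_thickness_um / 2.355  # FWHM -> sigma
    dystrophin = spec.dystrophin_peak * np.exp(-(d_um**2) / (2 * s_mem**2))

    glut4 = np.where(inside, phantom.glut4_diffuse, 0.0)
    psf_px = spec.psf_sigma_um / ps
    for spot in phantom.planted_spots:
        # uniform disk of the planted diameter convolved with the Gaussian
        # PSF: the radial profile peak*erfc((r - D/2)/(sqrt(2)*psf))/2 has
        # its half-maximum exactly at r = D/2, so the FWHM equals the
        # planted diameter while the size read off at any sane threshold
        # stays close to it
        radius_px = spot.diameter_um / 2.0 / ps
        r0, c0 = spot.center_um[0] / ps, spot.center_um[1] / ps
        half_w = int(math.ceil(radius_px + 4 * psf_px)) + 1
        r_lo, r_hi = max(0, int(r0) - half_w), min(n, int(r0) + half_w + 1)
        c_lo, c_hi = max(0, int(c0) - half_w), min(n, int(c0) + half_w + 1)
        rr = np.arange(r_lo, r_hi)[:, None] - r0
        cc = np.arange(c_lo, c_hi)[None, :] - c0
        r = np.hypot(rr, cc)
        glut4[r_lo:r_hi, c_lo:c_hi] += spot.peak_intensity * 0.5 * erfc(
            (r - radius_px) / (math.sqrt(2.0) * psf_px)
        )

    mhc1 = np.where(inside, phantom.mhc1_level, 0.0)

    if phantom.pcc_target is not None:
        # insulin-stimulated membrane-inserted GLUT4: a component sharing
        # the dystrophin ridge profile, with its amplitude solved so the
        # noiseless GLUT4-dystrophin correlation over the analysed region
        # (membrane band + interior) equals the condition's target PCC
        half_um = spec.membrane_thickness_px / 2.0 * ps
        region = d_um >= -half_um
        profile = np.exp(-(d_um**2) / (2 * s_mem**2))
        glut4 += _solve_membrane_amplitude(
            glut4, dystrophin, profile, region, phantom.pcc_target
        ) * profile

    noise = spec.noise
    out = []
    max_val = 2**spec.bit_depth - 1
    for clean in (dystrophin, glut4, mhc1):
        img = clean + noise.background_mean
        if noise.photon_scale > 0:
            img = rng.poisson(np.clip(img, 0, None) * noise.photon_scale) / noise.photon_scale
        if noise.read_noise_sd > 0:
            img = img + rng.normal(0.0, noise.read_noise_sd, img.shape)
        out.append(np.clip(np.round(img), 0, max_val).astype(np.uint16))

    return FibreFieldImage(
        channels=np.stack(out),
        pixel_size_um=ps,
        image_id=image_id,
        metadata={"fibre_type_true": phantom.fibre_type},
    )


def generate_study(
    design: StudyDesign,
    spec: EffectSpec,
    rng: np.random.Generator,
) -> StudySimulation:
    """Render a full synthetic study: images, design table, and ground truth.

    Between-subject variation enters as subject-level random intercepts on
    the log spot rates and log intensities.  The design table lists every
    image with its subject, group, infusion and timepoint; the ground
    truth records every phantom and the per-condition rates used by the
    sampler.

    Raises
    ------
    ValueError
        If the design has a single subject overall (the subject random
        intercept would be unidentifiable downstream).
    """
    if design.n_subjects < 2:
        raise ValueError("study needs at least 2 subjects for a subject random intercept")
    truth = GroundTruth()
    rows = []
    images: list[FibreFieldImage] = []
    for subject_id, group, infusion in design.subject_rows():
        effects = {
            "rate_multiplier": float(np.exp(rng.normal(0.0, spec.subject_sd_log))),
            "intensity_multiplier": float(np.exp(rng.normal(0.0, spec.subject_sd_log))),
            "pcc_shift": float(rng.normal(0.0, spec.pcc_subject_sd)),
        }
        truth.subject_effects[subject_id] = effects
        for tp in design.timepoints:
            for i in range(design.images_per_timepoint):
                fibre_type = "I" if rng.random() < spec.p_type1 else "II"
                condition = Condition(group, infusion, tp, fibre_type)
                ckey = f"{group}:{infusion}:{tp}:{fibre_type}"
                if ckey not in truth.condition_rates:
                    truth.condition_rates[ckey] = spec.condition_rates(condition)
                image_id = f"{subject_id}_t{tp:g}_{i:03d}"
                phantom = generate_fibre_phantom(
                    spec,
                    condition,
                    rng,
                    rate_multiplier=effects["rate_multiplier"],
                    intensity_multiplier=effects["intensity_multiplier"],
                    pcc_shift=effects["pcc_shift"],
                )
                images.append(render_image(phantom, spec, rng, image_id=image_id))
                truth.phantoms[image_id] = phantom
                rows.append(
                    {
                        "image_id": image_id,
                        "subject_id": subject_id,
                        "group": group,
                        "infusion": infusion,
                        "timepoint_h": tp,
                        "fibre_type_true": fibre_type,
                    }
                )
    table = pd.DataFrame(rows)
    return StudySimulation(images=images, design_table=table, ground_truth=truth)


def simulate_measurements(
    design: StudyDesign,
    spec: EffectSpec,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Sample a per-fibre measurement table directly from the effect model.

    Produces the same columns the image pipeline measures (PCC, total and
    per-layer intensity, per-layer small/large spot counts) from the same
    condition rates, with subject random intercepts on log rates and log
    intensities and an additive subject shift on PCC.  This is the fast
    path for validating the mixed-model statistics at full study scale.
    """
    if design.n_subjects < 2:
        raise ValueError("study needs at least 2 subjects for a subject random intercept")
    truth = GroundTruth()
    rows = []
    for subject_id, group, infusion in design.subject_rows():
        u_rate = float(np.exp(rng.normal(0.0, spec.subject_sd_log)))
        u_int = float(np.exp(rng.normal(0.0, spec.subject_sd_log)))
        u_pcc = float(rng.normal(0.0, spec.pcc_subject_sd))
        truth.subject_effects[subject_id] = {
            "rate_multiplier": u_rate,
            "intensity_multiplier": u_int,
            "pcc_shift": u_pcc,
        }
        for tp in design.timepoints:
            for i in range(design.images_per_timepoint):
                fibre_type = "I" if rng.random() < spec.p_type1 else "II"
                condition = Condition(group, infusion, tp, fibre_type)
                ckey = f"{group}:{infusion}:{tp}:{fibre_type}"
                if ckey not in truth.condition_rates:
                    truth.condition_rates[ckey] = spec.condition_rates(condition)
                rates = truth.condition_rates[ckey]
                type_mult = 1.0 + (
                    spec.type2_intensity_excess[group] if fibre_type == "II" else 0.0
                )
                row: dict = {
                    "image_id": f"{subject_id}_t{tp:g}_{i:03d}",
                    "subject_id": subject_id,
                    "group": group,
                    "infusion": infusion,
                    "timepoint_h": tp,
                    "fibre_type": fibre_type,
                }
                pcc = rates["pcc_mean"] + u_pcc + rng.normal(0.0, spec.pcc_residual_sd)
                row["pcc"] = float(np.clip(pcc, -1.0, 1.0))
                row["total_intensity"] = spec.total_intensity_mean * type_mult * u_int * float(
                    rng.lognormal(0.0, spec.intensity_cv)
                )
                for layer in LAYER_NAMES:
                    row[f"intensity_{layer}"] = (
                        spec.layer_intensity_means[layer]
                        * type_mult
                        * u_int
                        * float(rng.lognormal(0.0, spec.intensity_cv))
                    )
                    row[f"small_{layer}"] = int(rng.poisson(rates[f"small_{layer}"] * u_rate))
                    row[f"large_{layer}"] = int(rng.poisson(rates[f"large_{layer}"] * u_rate))
                rows.append(row)
    return pd.DataFrame(rows), truth
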