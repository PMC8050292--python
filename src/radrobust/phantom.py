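"""Synthetic phantom cohorts: paired thick/thin CT reconstructions and
planted-dependency feature tables.

Each subject is built from a single high-resolution latent volume — a
spatially correlated Hounsfield-unit texture (Gaussian random field obtained
by smoothing white noise) superimposed on ellipsoidal "tumour" and "muscle"
compartments — which is then reconstructed at two slice thicknesses by
partial-volume averaging along z (a box filter over the slice extent).  Both
reconstructions share the subject's in-plane pixel spacing; ROI masks are
voxelised analytically on each grid, so thin and thick masks of one subject
describe the same underlying ellipsoid.

The generator's defaults emulate the cohort conditions the analysis assumes:
tumour volumes 0.4-38 cm^3 and muscle 0.4-27 cm^3 (drawn jointly so both
tissues have comparable size per subject), in-plane pixel spacing 0.57-0.92
mm, 2.0 mm and 5.0 mm reconstructions, soft-tissue HU levels (tumour ~70,
muscle ~50) with ~10 HU textured noise and narrow inter-subject variation.
All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .extraction import ExtractionConfig, extract_subject_features, rows_to_table
from .volume_correction import FIT_FORMS
from .volumes import ROIMask, VolumeImage

__all__ = [
    "PhantomCohortSpec",
    "PlantedDependencySpec",
    "PhantomSubject",
    "Ellipsoid",
    "generate_phantom_pair",
    "generate_planted_feature_table",
    "generate_cohort_feature_tables",
]


@dataclass(frozen=True)
class PhantomCohortSpec:
    """Generative parameters of a paired thick/thin phantom cohort."""

    n_subjects: int = 43
    tumour_volume_range: tuple[float, float] = (0.4, 38.0)  # cm^3
    muscle_volume_range: tuple[float, float] = (0.4, 27.0)  # cm^3
    pixel_spacing_range: tuple[float, float] = (0.57, 0.92)  # mm, in-plane
    thin_thickness: float = 2.0  # mm
    thick_thickness: float = 5.0  # mm
    hu_background: float = 30.0  # HU
    hu_tumour: float = 70.0  # HU
    hu_muscle: float = 50.0  # HU
    texture_correlation_length: float = 1.5  # mm, fine local texture
    noise_sd: float = 3.0  # HU, fine-texture amplitude
    heterogeneity_correlation_length: float = 8.0  # mm, large-scale structure
    heterogeneity_sd: float = 18.0  # HU, large-scale amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tumour_volume_range", "muscle_volume_range", "pixel_spacing_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive interval, got {(lo, hi)}")
        if not (0 < self.thin_thickness < self.thick_thickness):
            raise ValueError("require 0 < thin_thickness < thick_thickness")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


@dataclass(frozen=True)
class PlantedDependencySpec:
    """Ground truth for a feature table with a planted voxel-count dependency."""

    form_id: int
    p0: float
    p1: float
    noise_sd: float = 0.0
    voxel_count_range: tuple[float, float] = (300.0, 53141.0)
    n_points: int = 43
    seed: int = 0

    def __post_init__(self) -> None:
        if self.form_id not in FIT_FORMS:
            raise ValueError(f"form_id must be in 1..8, got {self.form_id}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.voxel_count_range
        if not (0 < lo <= hi):
            raise ValueError("voxel_count_range must be strictly positive")
        if self.form_id == 8 and lo <= 1:
            raise ValueError("form 8 (1/log x) needs voxel counts > 1")
        if self.n_points < 8:
            raise ValueError("need n_points >= 8")


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: centre (mm) and semi-axes (mm)."""

    centre: tuple[float, float, float]
    radii: tuple[float, float, float]

    @property
    def volume_mm3(self) -> float:
        a, b, c = self.radii
        return 4.0 / 3.0 * math.pi * a * b * c

    def contains(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        cx, cy, cz = self.centre
        a, b, c = self.radii
        return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0


@dataclass
class PhantomSubject:
    """One subject's paired reconstructions, masks and ground truth."""

    subject_id: str
    thin_image: VolumeImage
    thick_image: VolumeImage
    thin_masks: dict[str, ROIMask]
    thick_masks: dict[str, ROIMask]
    ellipsoids: dict[str, Ellipsoid] = field(default_factory=dict)
    pixel_spacing: float = 0.0


def _latent_z_spacing(thin: float, thick: float) -> float:
    """A z step that divides both slice thicknesses (to 0.1 mm resolution)."""
    g = math.gcd(round(thin * 10), round(thick * 10)) / 10.0
    step = g
    while step > 1.0:
        step /= 2.0
    return step / 2.0 if step > 0.5 else step


def _draw_ellipsoid(rng: np.random.Generator, volume_cm3: float, centre) -> Ellipsoid:
    r = (3.0 * volume_cm3 * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    ja, jb = np.exp(rng.normal(0.0, 0.15, size=2))
    a, b = r * ja, r * jb
    c = volume_cm3 * 1000.0 * 3.0 / (4.0 * math.pi * a * b)
    return Ellipsoid(tuple(float(v) for v in centre), (float(a), float(b), float(c)))


def _grid_centres(n: int, step: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * step


def _voxelise(ell: Ellipsoid, shape, spacing, label: str) -> ROIMask:
    x = _grid_centres(shape[0], spacing[0])[:, None, None]
    y = _grid_centres(shape[1], spacing[1])[None, :, None]
    z = _grid_centres(shape[2], spacing[2])[None, None, :]
    values = ell.contains(x, y, z)
    origin = (0.5 * spacing[0], 0.5 * spacing[1], 0.5 * spacing[2])
    return ROIMask(values, tuple(spacing), origin, label)


def generate_phantom_pair(spec: PhantomCohortSpec, subject_index: int) -> PhantomSubject:
    """Generate one subject's thin and thick reconstructions with ROI masks.

    Deterministic in (spec.seed, subject_index).  Raises if the thick-grid
    voxelisation of either ROI is empty (degenerate spec).
    """
    if not 0 <= subject_index < spec.n_subjects:
        raise ValueError(f"subject_index must be in [0, {spec.n_subjects}), got {subject_index}")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, subject_index]))

    s_xy = float(rng.uniform(*spec.pixel_spacing_range))
    z_lat = _latent_z_spacing(spec.thin_thickness, spec.thick_thickness)
    m_thin = round(spec.thin_thickness / z_lat)
    m_thick = round(spec.thick_thickness / z_lat)

    lo, hi = spec.tumour_volume_range
    v_tum = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    mlo, mhi = spec.muscle_volume_range
    v_mus = float(np.clip(v_tum * rng.uniform(0.6, 1.1), mlo, mhi))

    # provisional radii to size the grid before the ellipsoids are placed
    r_t = (3.0 * v_tum * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    r_m = (3.0 * v_mus * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    margin = 4.0 * max(s_xy, spec.thick_thickness)
    rmax = 1.7 * max(r_t, r_m)  # head-room for anisotropy jitter
    extent_x = 2 * rmax + 2 * margin
    extent_y = 2 * 1.7 * (r_t + r_m) + 3 * margin
    extent_z = 2 * rmax + 2 * margin

    tumour = _draw_ellipsoid(rng, v_tum, (extent_x / 2, margin + 1.7 * r_t, extent_z / 2))
    muscle = _draw_ellipsoid(
        rng, v_mus, (extent_x / 2, extent_y - margin - 1.7 * r_m, extent_z / 2)
    )

    nx = int(np.ceil(extent_x / s_xy))
    ny = int(np.ceil(extent_y / s_xy))
    n_blocks = int(np.ceil(extent_z / (z_lat * m_thin * m_thick)))
    nz = n_blocks * m_thin * m_thick

    spacing_lat = (s_xy, s_xy, z_lat)
    x = _grid_centres(nx, s_xy)[:, None, None]
    y = _grid_centres(ny, s_xy)[None, :, None]
    z = _grid_centres(nz, z_lat)[None, None, :]

    latent = np.full((nx, ny, nz), spec.hu_background, dtype=np.float64)
    latent[np.broadcast_to(tumour.contains(x, y, z), latent.shape)] = spec.hu_tumour
    latent[np.broadcast_to(muscle.contains(x, y, z), latent.shape)] = spec.hu_muscle

    # two-scale Hounsfield texture: large-scale heterogeneity (enhancement
    # structure, tens of HU over ~1 cm) plus fine local texture (a few HU at
    # ~1.5 mm).  Coarse grey-level binning resolves only the former; fine
    # binning resolves both.  Amplitudes and correlation lengths are jittered
    # per subject to create inter-subject texture variance.
    # the fine amplitude spread across subjects is wide (x0.25..x1.75): the
    # cohort mixes near-smooth and strongly textured lesions, which is what
    # mid-range grey-level settings resolve and extreme settings do not
    components = (
        (spec.heterogeneity_correlation_length, spec.heterogeneity_sd, (0.75, 1.25)),
        (spec.texture_correlation_length, spec.noise_sd, (0.25, 1.75)),
    )
    for corr_len, amp0, amp_jitter in components:
        if amp0 <= 0:
            continue
        corr = corr_len * float(rng.uniform(0.7, 1.3))
        amp = amp0 * float(rng.uniform(*amp_jitter))
        sigma_vox = [max(corr / s, 1e-6) for s in spacing_lat]
        field_ = ndimage.gaussian_filter(rng.standard_normal(latent.shape), sigma_vox)
        sd = field_.std()
        if sd > 0:
            latent += amp * field_ / sd
    if spec.noise_sd > 0 or spec.heterogeneity_sd > 0:
        # texture redistributes intensity within a lesion without changing
        # its mean enhancement: re-centre each ROI on its nominal HU so
        # inter-subject intensity levels vary narrowly (cohorts of this kind
        # have near-uniform acquisition and contrast timing)
        for ell, nominal in ((tumour, spec.hu_tumour), (muscle, spec.hu_muscle)):
            inside = np.broadcast_to(ell.contains(x, y, z), latent.shape)
            latent[inside] -= latent[inside].mean() - nominal
        latent += float(rng.normal(0.0, 3.0))  # narrow inter-subject HU shift

    def reconstruct(m: int, thickness: float) -> VolumeImage:
        avg = latent.reshape(nx, ny, nz // m, m).mean(axis=3)
        return VolumeImage(
            avg, (s_xy, s_xy, thickness), (0.5 * s_xy, 0.5 * s_xy, 0.5 * thickness)
        )

    thin_img = reconstruct(m_thin, spec.thin_thickness)
    thick_img = reconstruct(m_thick, spec.thick_thickness)

    masks: dict[str, dict[str, ROIMask]] = {"thin": {}, "thick": {}}
    for label, ell in (("tumour", tumour), ("muscle", muscle)):
        for key, img in (("thin", thin_img), ("thick", thick_img)):
            m = _voxelise(ell, img.shape, img.spacing, label)
            if m.n_voxels == 0:
                raise ValueError(
                    f"degenerate spec: ROI '{label}' (volume {ell.volume_mm3 / 1000:.3f} cm^3) "
                    f"voxelises to zero voxels on the {key} grid"
                )
            masks[key][label] = m

    return PhantomSubject(
        subject_id=f"subj{subject_index:03d}",
        thin_image=thin_img,
        thick_image=thick_img,
        thin_masks=masks["thin"],
        thick_masks=masks["thick"],
        ellipsoids={"tumour": tumour, "muscle": muscle},
        pixel_spacing=s_xy,
    )


def generate_planted_feature_table(spec: PlantedDependencySpec) -> pd.DataFrame:
    """Feature measurements with a known functional voxel-count dependency.

    This is a validation harness for the fit engine, so voxel counts are
    drawn to give every candidate shape leverage: 75% log-uniformly (dense
    coverage of the small-count regime where the decaying forms live) and
    25% reflected-log-uniformly (dense coverage of the large-count end where
    the growing powers separate).  The response is
    ``p1 * g(x) + p0 + Normal(0, noise_sd)``; ground truth is recorded in
    ``DataFrame.attrs``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.voxel_count_range
    n_log = int(round(0.75 * spec.n_points))
    x_low = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_log))
    x_high = hi + lo - np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_points - n_log))
    x = np.concatenate([x_low, x_high])
    g = FIT_FORMS[spec.form_id][1]
    y = spec.p1 * np.asarray(g(x), dtype=float) + spec.p0
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=spec.n_points)
    table = pd.DataFrame({"n_voxels": x, "value": y})
    table.attrs.update(
        {"form_id": spec.form_id, "p0": spec.p0, "p1": spec.p1, "noise_sd": spec.noise_sd}
    )
    return table


def generate_cohort_feature_tables(
    spec: PhantomCohortSpec,
    configs: list[ExtractionConfig],
    subjects: list[PhantomSubject] | None = None,
    on_error: str = "raise",
) -> pd.DataFrame:
    """Extract feature tables for a whole phantom cohort.

    Runs every extraction config over every subject's (tissue, thickness)
    pair and returns one tidy FeatureTable with identification columns
    subject_id, tissue, thickness_mm, config_id, n_voxels.  With
    ``on_error='collect'`` per-subject failures are isolated and listed in
    ``table.attrs['failures']`` instead of aborting the run.
    """
    if subjects is None:
        subjects = [generate_phantom_pair(spec, i) for i in range(spec.n_subjects)]
    rows: list[dict] = []
    failures: list[str] = []
    for subj in subjects:
        for thickness, image, masks in (
            (spec.thin_thickness, subj.thin_image, subj.thin_masks),
            (spec.thick_thickness, subj.thick_image, subj.thick_masks),
        ):
            for config in configs:
                try:
                    rows.extend(
                        extract_subject_features(
                            subj.subject_id, image, masks, config, thickness_mm=thickness
                        )
                    )
                except (ValueError, RuntimeError) as exc:
                    if on_error == "raise":
                        raise
                    failures.append(str(exc))
    table = rows_to_table(rows)
    table.attrs["failures"] = failures
    return table
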