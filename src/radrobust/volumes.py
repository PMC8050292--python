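"""Volume/mask containers, NIfTI IO, resampling and volume-agreement statistics.

Images are held as ``(x, y, z)``-indexed arrays with anisotropic spacing in mm,
matching the NIfTI convention used by :mod:`nibabel` (the affine is diagonal in
spacing with a translation to the origin).  Resampling is delegated to
SimpleITK; three interpolation kernels are supported for images (linear, cubic
B-spline and Welch windowed sinc with kernel radius 3) while masks are always
resampled with nearest neighbour so labels stay binary.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import SimpleITK as sitk

__all__ = [
    "VolumeImage",
    "ROIMask",
    "ResamplingConfig",
    "VolumeAgreement",
    "enumerate_resampling_configs",
    "resample_image",
    "resample_mask",
    "compute_roi_volume",
    "volume_agreement",
    "lin_ccc",
    "read_nifti",
    "write_nifti",
]

_INTERPOLATORS = {
    "linear": sitk.sitkLinear,
    "bspline": sitk.sitkBSpline,
    "welch_sinc": sitk.sitkWelchWindowedSinc,
}


@dataclass
class VolumeImage:
    """A 3D scalar volume (HU) on a regular anisotropic grid."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("values must be a non-empty 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def to_sitk(self) -> sitk.Image:
        # SimpleITK array layout is (z, y, x)
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.values.T.astype(np.float64)))
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "VolumeImage":
        arr = sitk.GetArrayFromImage(img).T
        return cls(arr, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


@dataclass
class ROIMask:
    """Binary region-of-interest mask on the same grid as its companion image."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str = "tumour"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("mask must be a non-empty 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.values.T.astype(np.uint8)))
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        return img


@dataclass(frozen=True)
class ResamplingConfig:
    """One extraction grid: a target spacing and an interpolation kernel.

    ``target_spacing`` is either the string ``"original"`` (identity), or a
    triple of spacings in mm where the z entry may be ``None`` meaning "keep
    the z spacing of the input image" (the in-plane-only option).
    """

    target_spacing: object = "original"
    interpolator: str | None = None
    name: str = "original"

    def __post_init__(self) -> None:
        if self.target_spacing == "original":
            if self.interpolator is not None:
                raise ValueError("'original' spacing admits no interpolator choice")
            return
        sp = tuple(self.target_spacing)  # type: ignore[arg-type]
        if len(sp) != 3:
            raise ValueError("target_spacing must be a 3-tuple or 'original'")
        for s in sp[:2]:
            if s is None or s <= 0:
                raise ValueError("in-plane target spacing must be positive")
        if sp[2] is not None and sp[2] <= 0:
            raise ValueError("z target spacing must be positive or None")
        if self.interpolator not in _INTERPOLATORS:
            raise ValueError(
                f"interpolator must be one of {sorted(_INTERPOLATORS)}, got {self.interpolator!r}"
            )

    @property
    def is_original(self) -> bool:
        return self.target_spacing == "original"

    def resolve_spacing(self, image_spacing: Sequence[float]) -> tuple[float, float, float]:
        if self.is_original:
            return tuple(image_spacing)  # type: ignore[return-value]
        sx, sy, sz = self.target_spacing  # type: ignore[misc]
        return (float(sx), float(sy), float(image_spacing[2] if sz is None else sz))


def enumerate_resampling_configs(
    mu_xy: float | None = None,
    mu_z: float | None = None,
    isotropic_only: bool = False,
    interpolators: Iterable[str] = ("linear", "bspline", "welch_sinc"),
) -> list[ResamplingConfig]:
    """Enumerate the extraction-grid variations used throughout the analysis.

    The full grid is the original voxel size plus 7 resampled voxel sizes
    (five isotropic choices, in-plane-mean with original z, and the full mean
    voxel size) crossed with 3 interpolation kernels: 22 configurations.

    Parameters
    ----------
    mu_xy : cohort mean in-plane pixel width in mm (required unless
        ``isotropic_only``).
    mu_z : cohort mean slice thickness in mm (e.g. 3.5 for thicknesses
        {2.0, 5.0}).
    isotropic_only : drop the two cohort-mean-dependent voxel sizes.
    """
    interpolators = tuple(interpolators)
    spacings: list[tuple[str, tuple[float | None, float | None, float | None]]] = [
        ("iso0.5", (0.5, 0.5, 0.5)),
        ("iso1.0", (1.0, 1.0, 1.0)),
        ("iso1.25", (1.25, 1.25, 1.25)),
        ("iso1.75", (1.75, 1.75, 1.75)),
        ("iso2.0", (2.0, 2.0, 2.0)),
    ]
    if not isotropic_only:
        if mu_xy is None or mu_z is None:
            raise ValueError("mu_xy and mu_z are required for the cohort-mean voxel sizes")
        spacings.append(("muxy-zorig", (mu_xy, mu_xy, None)))
        spacings.append(("muxyz", (mu_xy, mu_xy, mu_z)))
    configs = [ResamplingConfig()]
    for label, sp in spacings:
        for interp in interpolators:
            configs.append(ResamplingConfig(sp, interp, name=f"{label}-{interp}"))
    return configs


def mean_slice_thickness(thicknesses: Iterable[float]) -> float:
    """Arithmetic mean of the reconstructed slice thicknesses (mm)."""
    t = np.asarray(list(thicknesses), dtype=float)
    return float(t.mean())


def _resample(img: sitk.Image, spacing: tuple[float, float, float], interp: int) -> sitk.Image:
    old_spacing = np.asarray(img.GetSpacing())
    old_size = np.asarray(img.GetSize())
    new_spacing = np.asarray(spacing, dtype=float)
    # the largest grid whose voxel centres stay inside the source centre
    # span, centred within it: no output voxel ever samples outside the
    # image, so the physical extent is preserved to within one voxel at each
    # boundary and interpolation never mixes in the out-of-volume default
    span = (old_size - 1) * old_spacing
    new_size = np.maximum(1, np.floor(span / new_spacing + 1e-9).astype(int) + 1)
    new_origin = np.asarray(img.GetOrigin()) + 0.5 * (span - (new_size - 1) * new_spacing)
    res = sitk.ResampleImageFilter()
    res.SetOutputSpacing(tuple(new_spacing))
    res.SetSize([int(n) for n in new_size])
    res.SetOutputOrigin(tuple(new_origin))
    res.SetOutputDirection(img.GetDirection())
    res.SetInterpolator(interp)
    res.SetDefaultPixelValue(0)
    return res.Execute(img)


def resample_image(image: VolumeImage, config: ResamplingConfig) -> VolumeImage:
    """Resample a volume to the grid requested by ``config``."""
    if config.is_original:
        return image
    spacing = config.resolve_spacing(image.spacing)
    out = _resample(image.to_sitk(), spacing, _INTERPOLATORS[config.interpolator])
    return VolumeImage.from_sitk(out)


def resample_mask(mask: ROIMask, config: ResamplingConfig) -> ROIMask:
    """Resample a binary mask with nearest-neighbour interpolation."""
    if config.is_original:
        return mask
    spacing = config.resolve_spacing(mask.spacing)
    out = _resample(mask.to_sitk(), spacing, sitk.sitkNearestNeighbor)
    values = sitk.GetArrayFromImage(out).T.astype(bool)
    if not values.any():
        warnings.warn(
            f"mask '{mask.label}' is empty after resampling to {spacing}; "
            "target spacing exceeds the ROI extent",
            RuntimeWarning,
            stacklevel=2,
        )
    return ROIMask(values, tuple(out.GetSpacing()), tuple(out.GetOrigin()), mask.label)


def crop_to_roi(
    image: VolumeImage, mask: ROIMask, margin: int = 6
) -> tuple[VolumeImage, ROIMask]:
    """Crop image and mask to the ROI bounding box plus a voxel margin.

    Texture features depend only on the ROI neighbourhood, so cropping before
    resampling preserves results while keeping interpolation tractable; the
    margin leaves room for wide kernels (windowed sinc radius 3) and the
    origin is shifted so physical coordinates are unchanged.
    """
    if image.values.shape != mask.values.shape:
        raise ValueError("image and mask grids differ")
    idx = np.argwhere(mask.values)
    if idx.size == 0:
        raise ValueError("cannot crop to an empty mask")
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, mask.values.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    origin = tuple(np.asarray(image.origin) + lo * np.asarray(image.spacing))
    return (
        VolumeImage(image.values[sl], image.spacing, origin),
        ROIMask(mask.values[sl], mask.spacing, origin, mask.label),
    )


def compute_roi_volume(mask: ROIMask) -> tuple[int, float]:
    """Return (number of voxels, physical volume in cm^3) of a mask.

    1 cm^3 = 1000 mm^3; the conversion is exact.
    """
    n = mask.n_voxels
    if n == 0:
        raise ValueError("empty mask has no volume")
    return n, n * mask.voxel_volume_mm3 / 1000.0


def lin_ccc(x: Sequence[float], y: Sequence[float]) -> float:
    """Lin's concordance correlation coefficient between two paired sequences.

    CCC = 2*cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2), with
    population (1/n) moments.  Undefined (ValueError) when both sequences are
    constant and equal-mean, i.e. the denominator vanishes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length 1D sequences with >= 2 pairs")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        raise ValueError("CCC undefined: both sequences constant with equal means")
    return float(2 * cov / denom)


@dataclass
class VolumeAgreement:
    """Bland–Altman and concordance summary of paired thin/thick ROI volumes."""

    vol_thin: np.ndarray
    vol_thick: np.ndarray
    bias: float
    loa_low: float
    loa_high: float
    ccc: float

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["vol_thin"] = list(self.vol_thin)
        d["vol_thick"] = list(self.vol_thick)
        return d


def volume_agreement(
    vol_thin: Sequence[float], vol_thick: Sequence[float]
) -> VolumeAgreement:
    """Quantify thin-vs-thick ROI volume agreement over a cohort.

    Bland–Altman bias is mean(thick - thin); the limits of agreement are
    bias +/- 1.96 * sd(differences) (sample sd).  Concordance is Lin's CCC.
    """
    thin = np.asarray(vol_thin, dtype=float)
    thick = np.asarray(vol_thick, dtype=float)
    if thin.size < 2 or thin.shape != thick.shape:
        raise ValueError("need >= 2 paired volumes")
    diff = thick - thin
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return VolumeAgreement(
        vol_thin=thin,
        vol_thick=thick,
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        ccc=lin_ccc(thin, thick),
    )


def write_nifti(obj: VolumeImage | ROIMask, path) -> None:
    """Write an image or mask to NIfTI with a diagonal affine in mm."""
    affine = np.diag(list(obj.spacing) + [1.0])
    affine[:3, 3] = obj.origin
    data = obj.values.astype(np.uint8) if isinstance(obj, ROIMask) else obj.values.astype(np.float32)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_nifti(path, as_mask: bool = False, label: str = "tumour") -> VolumeImage | ROIMask:
    """Read a NIfTI volume; spacing is taken from the affine column norms."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI volume, got shape {data.shape}")
    affine = img.affine
    spacing = tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))
    origin = tuple(float(v) for v in affine[:3, 3])
    if as_mask:
        return ROIMask(data > 0, spacing, origin, label)
    return VolumeImage(data.astype(np.float64), spacing, origin)
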