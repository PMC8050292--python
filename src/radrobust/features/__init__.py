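"""The 107-feature radiomic catalogue: shape (14), first-order (18), GLCM
(24), GLDM (14), GLRLM (16), GLSZM (16) and NGTDM (5), computed in 3D with no
image filters.

:func:`extract_features` is the single entry point: it quantises the ROI,
builds the five grey-level matrices and returns one flat ``{name: value}``
mapping with family-prefixed names (``firstorder_Energy``, ``glcm_Contrast``,
...) that is stable across runs.
"""

from __future__ import annotations

import numpy as np

from ..volumes import ROIMask, VolumeImage
from .firstorder import FIRST_ORDER_NAMES, first_order_features
from .quantise import QuantisationConfig, quantise_roi, quantise_values
from .shape import SHAPE_NAMES, shape_features
from .texture import (
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    glcm_features,
    glcm_matrices,
    gldm_features,
    gldm_matrix,
    glrlm_features,
    glrlm_matrices,
    glszm_features,
    glszm_matrix,
    ngtdm_features,
    ngtdm_table,
)

__all__ = [
    "QuantisationConfig",
    "quantise_roi",
    "quantise_values",
    "extract_features",
    "feature_catalogue",
    "FAMILY_COUNTS",
    "SHAPE_FEATURE_NAMES",
]

FAMILY_COUNTS = {
    "shape": 14,
    "firstorder": 18,
    "glcm": 24,
    "gldm": 14,
    "glrlm": 16,
    "glszm": 16,
    "ngtdm": 5,
}

_FAMILY_NAMES = {
    "shape": SHAPE_NAMES,
    "firstorder": FIRST_ORDER_NAMES,
    "glcm": GLCM_NAMES,
    "gldm": GLDM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "ngtdm": NGTDM_NAMES,
}


def feature_catalogue() -> list[str]:
    """Ordered list of the 107 feature names (family-prefixed)."""
    return [f"{fam}_{name}" for fam, names in _FAMILY_NAMES.items() for name in names]


SHAPE_FEATURE_NAMES = [f"shape_{n}" for n in SHAPE_NAMES]


def extract_features(
    image: VolumeImage,
    mask: ROIMask,
    quantisation: QuantisationConfig | None = None,
    families: tuple[str, ...] = tuple(FAMILY_COUNTS),
) -> dict[str, float]:
    """Extract the radiomic feature catalogue from one image/mask pair.

    Texture families are computed on grey levels quantised per ``quantisation``
    (default: 40 fixed bins over the ROI's own range).  Degenerate ROIs
    (single voxel, constant intensity) yield the defined limiting values where
    the catalogue defines them and NaN elsewhere, never an exception, so that
    cohort sweeps survive extreme extraction grids.
    """
    quantisation = quantisation or QuantisationConfig()
    if image.values.shape != mask.values.shape:
        raise ValueError("image and mask grids differ")
    n_voxels = mask.n_voxels
    if n_voxels == 0:
        raise ValueError("empty mask")

    gl_volume, _, _ = quantise_roi(image, mask, quantisation)
    raw = image.values[mask.values]
    gl_flat = gl_volume[mask.values]
    ng = int(gl_flat.max())

    out: dict[str, float] = {}
    if "shape" in families:
        for k, v in shape_features(mask.values, mask.spacing).items():
            out[f"shape_{k}"] = v
    if "firstorder" in families:
        for k, v in first_order_features(raw, gl_flat, image.voxel_volume_mm3).items():
            out[f"firstorder_{k}"] = v

    def _guard(fam: str, names: list[str], fn):
        try:
            vals = fn()
        except ValueError:
            vals = {k: np.nan for k in names}
        for k, v in vals.items():
            out[f"{fam}_{k}"] = v

    if "glcm" in families:
        _guard("glcm", GLCM_NAMES, lambda: glcm_features(glcm_matrices(gl_volume, ng)))
    if "gldm" in families:
        _guard("gldm", GLDM_NAMES, lambda: gldm_features(gldm_matrix(gl_volume, 0, ng)))
    if "glrlm" in families:
        _guard(
            "glrlm", GLRLM_NAMES, lambda: glrlm_features(glrlm_matrices(gl_volume, ng), n_voxels)
        )
    if "glszm" in families:
        _guard("glszm", GLSZM_NAMES, lambda: glszm_features(glszm_matrix(gl_volume, ng), n_voxels))
    if "ngtdm" in families:
        _guard("ngtdm", NGTDM_NAMES, lambda: ngtdm_features(ngtdm_table(gl_volume, ng)))
    return out
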