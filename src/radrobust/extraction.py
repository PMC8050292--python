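"""Cohort-level feature extraction: one grid+quantisation config at a time.

An :class:`ExtractionConfig` pairs a resampling grid with a grey-level
quantisation; :func:`extract_subject_features` applies it to one subject's
image and ROI masks and returns tidy rows (one per tissue) carrying the
post-resampling voxel count alongside the 107 feature values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .features import QuantisationConfig, extract_features
from .volumes import (
    ResamplingConfig,
    ROIMask,
    VolumeImage,
    crop_to_roi,
    resample_image,
    resample_mask,
)

__all__ = ["ExtractionConfig", "extract_subject_features", "rows_to_table"]


@dataclass(frozen=True)
class ExtractionConfig:
    """A named (resampling grid, grey-level quantisation) extraction setting."""

    config_id: str
    resampling: ResamplingConfig = field(default_factory=ResamplingConfig)
    quantisation: QuantisationConfig = field(default_factory=QuantisationConfig)


def extract_subject_features(
    subject_id: str,
    image: VolumeImage,
    masks: dict[str, ROIMask],
    config: ExtractionConfig,
    thickness_mm: float | None = None,
) -> list[dict]:
    """Extract the full catalogue for one subject under one config.

    Returns one row dict per tissue with identification columns
    (subject_id, tissue, thickness_mm, config_id, n_voxels) followed by the
    feature values.  Failures are re-raised with subject/config context.
    """
    rows = []
    for tissue, mask in masks.items():
        cimg, cmask = crop_to_roi(image, mask)
        resampled = resample_image(cimg, config.resampling)
        rmask = resample_mask(cmask, config.resampling)
        if rmask.n_voxels == 0:
            raise ValueError(
                f"subject {subject_id!r}, config {config.config_id!r}: "
                f"ROI '{tissue}' empty after resampling"
            )
        try:
            feats = extract_features(resampled, rmask, config.quantisation)
        except Exception as exc:  # identify the failing unit for the manifest
            raise RuntimeError(
                f"feature extraction failed for subject {subject_id!r}, "
                f"tissue {tissue!r}, config {config.config_id!r}: {exc}"
            ) from exc
        row = {
            "subject_id": subject_id,
            "tissue": tissue,
            "thickness_mm": thickness_mm,
            "config_id": config.config_id,
            "n_voxels": rmask.n_voxels,
        }
        row.update(feats)
        rows.append(row)
    return rows


def rows_to_table(rows: list[dict]) -> pd.DataFrame:
    """Stack extraction rows into a FeatureTable DataFrame."""
    return pd.DataFrame(rows)
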