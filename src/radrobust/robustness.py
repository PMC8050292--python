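"""Cross-thickness robustness of radiomic features, and the end-to-end
pipeline.

The central metric is the relative cross-thickness difference per subject,
``delta_r = |f_thick - f_thin| / |f_thin|`` (the thin reconstruction is the
reference by design — the arguments are not interchangeable).  Features whose
cohort-median delta_r at the original voxel sizes exceeds 0.5 and that carry
a viable voxel-count fit are corrected by fit-and-invert before the final
comparison.  An alternative route normalises texture features by the
matched healthy-muscle ROI, ``rho = f_tumour / f_muscle``, and compares
``delta_rho = |rho_thick - rho_thin| / |rho_thin|`` (shape features keep
delta_r).  A feature is robust when its cohort median is below 0.5 and
highly robust below 0.25.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .extraction import ExtractionConfig
from .features import (
    FAMILY_COUNTS,
    QuantisationConfig,
    extract_features,
    feature_catalogue,
)
from .gl_analysis import (
    DEFAULT_GL_SETTINGS,
    GLSweepResult,
    classify_gl_dependent,
    freedman_diaconis_bins,
    summarise_gl_sweep,
)
from .phantom import PhantomCohortSpec, PhantomSubject, generate_phantom_pair
from .volume_correction import VolumeDependencyCorrector, classify_volume_dependent, spearman_rs
from .volumes import (
    ResamplingConfig,
    compute_roi_volume,
    crop_to_roi,
    enumerate_resampling_configs,
    mean_slice_thickness,
    resample_image,
    resample_mask,
    volume_agreement,
)

__all__ = [
    "delta_r",
    "rho",
    "delta_rho",
    "median_metric",
    "decide_correction",
    "count_robust",
    "PipelineConfig",
    "run_pipeline",
]


def delta_r(f_thin, f_thick) -> np.ndarray:
    """Relative cross-thickness difference |f_thick - f_thin| / |f_thin|.

    The thin-slice value is the reference denominator; zero references yield
    NaN (excluded from medians downstream with an exclusion count).
    """
    thin = np.asarray(f_thin, dtype=float)
    thick = np.asarray(f_thick, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.abs(thick - thin) / np.abs(thin)
    return np.where(thin == 0, np.nan, out)


def rho(f_tumour, f_muscle) -> np.ndarray:
    """Tumour-to-muscle feature ratio; zero muscle values yield NaN."""
    t = np.asarray(f_tumour, dtype=float)
    m = np.asarray(f_muscle, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = t / m
    return np.where(m == 0, np.nan, out)


def delta_rho(rho_thin, rho_thick) -> np.ndarray:
    """Relative cross-thickness difference of tumour/muscle ratios."""
    return delta_r(rho_thin, rho_thick)


def median_metric(values, max_excluded_frac: float = 0.2) -> tuple[float, int, bool]:
    """Cohort median of a per-subject metric with exclusion accounting.

    Returns ``(median, n_excluded, reliable)``; the median is flagged
    unreliable when more than ``max_excluded_frac`` of subjects were excluded
    for undefined values (zero denominators).
    """
    v = np.asarray(values, dtype=float)
    n_total = v.size
    finite = v[np.isfinite(v)]
    n_excluded = n_total - finite.size
    if finite.size == 0:
        return np.nan, n_excluded, False
    reliable = n_excluded <= max_excluded_frac * n_total
    return float(np.median(finite)), n_excluded, reliable


def decide_correction(
    median_delta_r: pd.Series,
    voxel_dependent: pd.Series | None = None,
    threshold: float = 0.5,
) -> list[str]:
    """Select features to volume-correct: median delta_r above threshold at
    the original voxel sizes, restricted to voxel-count-dependent texture
    features.  Shape features are never selected."""
    selected = []
    for name, med in median_delta_r.items():
        if str(name).startswith("shape_"):
            continue
        if voxel_dependent is not None and not bool(voxel_dependent.get(name, False)):
            continue
        if np.isfinite(med) and med > threshold:
            selected.append(name)
    return selected


def count_robust(
    medians: pd.Series,
    robust_threshold: float = 0.5,
    highly_robust_threshold: float = 0.25,
    ensemble_size: int | None = None,
) -> dict:
    """Counts and percentages of robust / highly robust features.

    Percentages are over the full catalogue (``ensemble_size``, default the
    number of features given); NaN medians count as not robust.
    """
    total = ensemble_size or len(medians)
    vals = medians.to_numpy(dtype=float)
    n_rob = int(np.nansum(vals < robust_threshold))
    n_high = int(np.nansum(vals < highly_robust_threshold))
    assert n_high <= n_rob
    return {
        "n_features": total,
        "n_robust": n_rob,
        "n_highly_robust": n_high,
        "pct_robust": 100.0 * n_rob / total,
        "pct_highly_robust": 100.0 * n_high / total,
    }


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Thresholds and extraction grids for the full analysis.

    Defaults are the analysis' standard operating points: ICC stability 0.9,
    Spearman dependence 0.5, correction trigger delta_r > 0.5, robustness
    0.5 / 0.25, variance collapse sigma_n < 0.1.
    """

    gl_settings: tuple[int, ...] = DEFAULT_GL_SETTINGS
    icc_threshold: float = 0.9
    rs_threshold: float = 0.5
    correction_delta_r: float = 0.5
    robust_threshold: float = 0.5
    highly_robust_threshold: float = 0.25
    sigma_threshold: float = 0.1
    max_excluded_frac: float = 0.2
    # None -> the full 22-config enumeration from cohort metadata
    resampling_configs: list[ResamplingConfig] | None = None
    gl_reference_resampling: ResamplingConfig = field(
        default_factory=lambda: ResamplingConfig((1.0, 1.0, 1.0), "bspline", name="iso1.0-bspline")
    )


def _paired_pivot(table: pd.DataFrame, feature_cols, tissue, thin_mm, thick_mm, config_id):
    """(thin, thick) value frames indexed by subject for one tissue+config."""
    sel = table[(table["tissue"] == tissue) & (table["config_id"] == config_id)]
    thin = sel[sel["thickness_mm"] == thin_mm].set_index("subject_id")[feature_cols]
    thick = sel[sel["thickness_mm"] == thick_mm].set_index("subject_id")[feature_cols]
    common = thin.index.intersection(thick.index)
    return thin.loc[common], thick.loc[common]


def run_pipeline(
    spec: PhantomCohortSpec,
    config: PipelineConfig | None = None,
    subjects: list[PhantomSubject] | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Execute the full robustness analysis on a phantom cohort.

    Stages: thin/thick ROI volume agreement; Freedman-Diaconis bin choice on
    the reference (1 mm isotropic) grid; grey-level sweep with ICC screening
    and variance-collapse summary; extraction over the voxel-size grid at the
    chosen bin count; voxel-count dependence screen, fit and inversion
    correction triggered by delta_r; robust / highly-robust counts for the
    corrected-delta_r route and the muscle-normalisation route.

    Returns a report bundle (dict of DataFrames/scalars); when ``outdir`` is
    given all tables are written as CSV together with a JSON manifest.
    """
    config = config or PipelineConfig()
    catalogue = feature_catalogue()
    texture_cols = [c for c in catalogue if not c.startswith("shape_")]

    if subjects is None:
        subjects = [generate_phantom_pair(spec, i) for i in range(spec.n_subjects)]

    # --- stage 1: volume agreement ---------------------------------------
    vols_thin = []
    vols_thick = []
    for s in subjects:
        vols_thin.append(compute_roi_volume(s.thin_masks["tumour"])[1])
        vols_thick.append(compute_roi_volume(s.thick_masks["tumour"])[1])
    agreement = volume_agreement(vols_thin, vols_thick)

    # --- stage 2: FD rule + GL sweep on the reference grid ----------------
    ref = config.gl_reference_resampling
    resampled: dict[tuple[str, float, str], tuple] = {}
    for s in subjects:
        for thickness, img, masks in (
            (spec.thin_thickness, s.thin_image, s.thin_masks),
            (spec.thick_thickness, s.thick_image, s.thick_masks),
        ):
            for tissue, mask in masks.items():
                cimg, cmask = crop_to_roi(img, mask)
                rimg = resample_image(cimg, ref)
                rmask = resample_mask(cmask, ref)
                resampled[(s.subject_id, thickness, tissue)] = (rimg, rmask)

    fd_rows = []
    for (sid, thickness, tissue), (rimg, rmask) in resampled.items():
        if rmask.n_voxels < 4:
            continue
        try:
            nb = freedman_diaconis_bins(rimg.values[rmask.values])
        except ValueError:
            continue
        fd_rows.append(
            {"subject_id": sid, "thickness_mm": thickness, "tissue": tissue, "fd_bins": nb}
        )
    fd_table = pd.DataFrame(fd_rows)
    thin_tum = fd_table[
        (fd_table["thickness_mm"] == spec.thin_thickness) & (fd_table["tissue"] == "tumour")
    ]
    fd_bins = int(round(float(thin_tum["fd_bins"].median())))
    gl_settings = tuple(sorted(set(config.gl_settings) | {fd_bins}))

    sweep_rows: dict[tuple[str, float, int], dict[str, dict]] = {}
    for n_bins in gl_settings:
        quant = QuantisationConfig("fixed_bin_count", n_bins=n_bins)
        for (sid, thickness, tissue), (rimg, rmask) in resampled.items():
            feats = extract_features(rimg, rmask, quant)
            sweep_rows.setdefault((tissue, thickness, n_bins), {})[sid] = feats
    sweep_tables = {
        key: pd.DataFrame.from_dict(rows, orient="index").astype(float)
        for key, rows in sweep_rows.items()
    }

    gl_dependent_frames = []
    sweep_summaries = []
    for tissue in ("tumour", "muscle"):
        for thickness in (spec.thin_thickness, spec.thick_thickness):
            values = {
                name: np.column_stack(
                    [sweep_tables[(tissue, thickness, nb)][name].to_numpy() for nb in gl_settings]
                )
                for name in texture_cols
            }
            sweep = GLSweepResult(gl_settings, values).compute_icc()
            flags = classify_gl_dependent(sweep, config.icc_threshold)
            gl_dependent_frames.append(
                pd.DataFrame(
                    {
                        "tissue": tissue,
                        "thickness_mm": thickness,
                        "feature": list(flags),
                        "icc": [sweep.icc[f] for f in flags],
                        "gl_dependent": list(flags.values()),
                    }
                )
            )
            dependent = [f for f, v in flags.items() if v]
            dr_medians = {}
            per_setting = {}
            for nb in gl_settings:
                thin_t = sweep_tables[(tissue, spec.thin_thickness, nb)]
                thick_t = sweep_tables[(tissue, spec.thick_thickness, nb)]
                common = thin_t.index.intersection(thick_t.index)
                dr = pd.DataFrame(
                    delta_r(thin_t.loc[common, dependent], thick_t.loc[common, dependent]),
                    columns=dependent,
                )
                dr_medians[nb] = dr.median(skipna=True)
                per_setting[nb] = sweep_tables[(tissue, thickness, nb)][dependent]
            summary = summarise_gl_sweep(
                per_setting, dr_medians, sigma_threshold=config.sigma_threshold
            )
            summary.insert(0, "tissue", tissue)
            summary.insert(1, "thickness_mm", thickness)
            sweep_summaries.append(summary)
    gl_dependent_table = pd.concat(gl_dependent_frames, ignore_index=True)
    gl_sweep_summary = pd.concat(sweep_summaries, ignore_index=True)

    # --- stage 3: extraction over the voxel-size grid at the FD bins ------
    if config.resampling_configs is None:
        mu_xy = float(np.mean([s.pixel_spacing for s in subjects]))
        mu_z = mean_slice_thickness([spec.thin_thickness, spec.thick_thickness])
        res_configs = enumerate_resampling_configs(mu_xy, mu_z)
    else:
        res_configs = config.resampling_configs
    quant = QuantisationConfig("fixed_bin_count", n_bins=fd_bins)
    extraction_configs = [ExtractionConfig(rc.name, rc, quant) for rc in res_configs]

    from .phantom import generate_cohort_feature_tables

    table = generate_cohort_feature_tables(
        spec, extraction_configs, subjects=subjects, on_error="collect"
    )

    # --- stage 4: voxel-count dependence screen ----------------------------
    rs_rows = {}
    thin_table = table[
        (table["thickness_mm"] == spec.thin_thickness) & (table["tissue"] == "tumour")
    ]
    for config_id, grp in thin_table.groupby("config_id"):
        x = grp["n_voxels"].to_numpy(dtype=float)
        row = {}
        for col in texture_cols:
            yv = grp[col].to_numpy(dtype=float)
            ok = np.isfinite(yv)
            try:
                row[col], _ = spearman_rs(x[ok], yv[ok])
            except ValueError:
                row[col] = np.nan
        rs_rows[config_id] = row
    rs_by_config = pd.DataFrame(rs_rows).T
    voxel_dependent = classify_volume_dependent(rs_by_config, config.rs_threshold)
    # shape features are structurally exempt
    voxel_dependent = voxel_dependent.reindex(catalogue, fill_value=False)

    # --- stage 5: delta_r at original voxel sizes decides the correction --
    orig_id = "original"
    thin0, thick0 = _paired_pivot(
        table, catalogue, "tumour", spec.thin_thickness, spec.thick_thickness, orig_id
    )
    dr0 = pd.DataFrame(
        delta_r(thin0, thick0), index=thin0.index, columns=catalogue
    )
    med0 = dr0.median(skipna=True)
    to_correct = decide_correction(med0, voxel_dependent, config.correction_delta_r)

    # --- stage 6: per-config correction and robustness (delta_r route) ----
    config_ids = [ec.config_id for ec in extraction_configs]
    dr_reports = []
    dr_medians_by_config = {}
    fit_report_rows = []
    for config_id in config_ids:
        medians = {}
        for tissue in ("tumour",):
            thin_f, thick_f = _paired_pivot(
                table, catalogue, tissue, spec.thin_thickness, spec.thick_thickness, config_id
            )
            sel = table[(table["tissue"] == tissue) & (table["config_id"] == config_id)]
            nthin = (
                sel[sel["thickness_mm"] == spec.thin_thickness]
                .set_index("subject_id")["n_voxels"]
                .loc[thin_f.index]
            )
            nthick = (
                sel[sel["thickness_mm"] == spec.thick_thickness]
                .set_index("subject_id")["n_voxels"]
                .loc[thick_f.index]
            )
            corrector = VolumeDependencyCorrector(
                rs_threshold=0.0, features=to_correct
            )  # screen already done; fit only the decided features
            fit_frame = thin_f.copy()
            fit_frame["n_voxels"] = nthin
            corrector.fit(fit_frame)
            thick_frame = thick_f.copy()
            thick_frame["n_voxels"] = nthick
            thin_corr = corrector.transform(fit_frame)[catalogue]
            thick_corr = corrector.transform(thick_frame)[catalogue]
            for feat, fit in corrector.fits_.items():
                fit_report_rows.append(
                    {
                        "config_id": config_id,
                        "tissue": tissue,
                        "feature": feat,
                        "form_id": fit.form_id,
                        "form": fit.label,
                        "p0": fit.p0,
                        "p1": fit.p1,
                        "reduced_chi2": fit.reduced_chi2,
                    }
                )
            dr = pd.DataFrame(
                delta_r(thin_corr, thick_corr), index=thin_corr.index, columns=catalogue
            )
            for feat in catalogue:
                med, _, reliable = median_metric(dr[feat], config.max_excluded_frac)
                medians[feat] = med if reliable else np.nan
        med_series = pd.Series(medians).reindex(catalogue)
        dr_medians_by_config[config_id] = med_series
        rep = count_robust(
            med_series,
            config.robust_threshold,
            config.highly_robust_threshold,
            ensemble_size=len(catalogue),
        )
        rep["config_id"] = config_id
        dr_reports.append(rep)
    delta_r_report = pd.DataFrame(dr_reports)[
        ["config_id", "n_features", "n_robust", "n_highly_robust", "pct_robust", "pct_highly_robust"]
    ]

    # --- stage 7: muscle-normalisation route (delta_rho) -------------------
    rho_reports = []
    rho_medians_by_config = {}
    for config_id in config_ids:
        tum_thin, tum_thick = _paired_pivot(
            table, catalogue, "tumour", spec.thin_thickness, spec.thick_thickness, config_id
        )
        mus_thin, mus_thick = _paired_pivot(
            table, catalogue, "muscle", spec.thin_thickness, spec.thick_thickness, config_id
        )
        common = tum_thin.index.intersection(mus_thin.index)
        medians = {}
        for feat in catalogue:
            if feat.startswith("shape_"):
                vals = delta_r(tum_thin.loc[common, feat], tum_thick.loc[common, feat])
            else:
                r_thin = rho(tum_thin.loc[common, feat], mus_thin.loc[common, feat])
                r_thick = rho(tum_thick.loc[common, feat], mus_thick.loc[common, feat])
                vals = delta_rho(r_thin, r_thick)
            med, _, reliable = median_metric(vals, config.max_excluded_frac)
            medians[feat] = med if reliable else np.nan
        med_series = pd.Series(medians).reindex(catalogue)
        rho_medians_by_config[config_id] = med_series
        rep = count_robust(
            med_series,
            config.robust_threshold,
            config.highly_robust_threshold,
            ensemble_size=len(catalogue),
        )
        rep["config_id"] = config_id
        rho_reports.append(rep)
    delta_rho_report = pd.DataFrame(rho_reports)[
        ["config_id", "n_features", "n_robust", "n_highly_robust", "pct_robust", "pct_highly_robust"]
    ]

    spec_dict = asdict(spec)
    manifest = {
        "seed": spec.seed,
        "n_subjects": spec.n_subjects,
        "fd_bins": fd_bins,
        "gl_settings": list(gl_settings),
        "config_ids": config_ids,
        "catalogue_size": len(catalogue),
        "family_counts": dict(FAMILY_COUNTS),
        "spec": spec_dict,
        "config_hash": hashlib.sha256(
            json.dumps(spec_dict, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "version": __version__,
        "failures": table.attrs.get("failures", []),
    }

    bundle = {
        "volume_agreement": agreement,
        "fd_table": fd_table,
        "fd_bins": fd_bins,
        "gl_settings": gl_settings,
        "sweep_tables": sweep_tables,
        "gl_sweep_summary": gl_sweep_summary,
        "gl_dependent": gl_dependent_table,
        "features": table,
        "rs_by_config": rs_by_config,
        "voxel_dependent": voxel_dependent,
        "median_delta_r_original": med0,
        "corrected_features": to_correct,
        "fit_report": pd.DataFrame(fit_report_rows),
        "delta_r_medians": pd.DataFrame(dr_medians_by_config),
        "delta_r_report": delta_r_report,
        "delta_rho_medians": pd.DataFrame(rho_medians_by_config),
        "delta_rho_report": delta_rho_report,
        "manifest": manifest,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for key, value in bundle.items():
            if isinstance(value, pd.DataFrame):
                value.to_csv(outdir / f"{key}.csv")
            elif isinstance(value, pd.Series):
                value.to_csv(outdir / f"{key}.csv", header=["value"])
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        with open(outdir / "volume_agreement.json", "w") as fh:
            json.dump(agreement.as_dict(), fh, indent=2)
    return bundle
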