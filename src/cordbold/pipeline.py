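"""End-to-end orchestration over synthetic data.

A single configured run: generate a cohort of cord phantoms and BOLD runs
whose ground truth is driven by one latent severity per subject, then run
morphometry, rater reliability, the GLM with cluster correction, ROI
extraction, and finally the correlation battery.  Each stage writes its
tables plus a JSON sidecar (parameters, seed, package version); a
top-level manifest links every output.

The latent-severity coupling makes the demo scientifically coherent: more
severe subjects get deeper cord compressions, larger true percent signal
in the motor ROIs, and lower mJOA — so the downstream battery recovers
positive compression–activation and negative mJOA–activation correlations
from fully synthetic imaging.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from cordbold import __version__, synth
from cordbold.glm import HRFParams, build_design_matrix, cluster_threshold, fit_glm, smooth_volume
from cordbold.morphometry import analyze_mask, total_compression_volume
from cordbold.reliability import icc_inter, icc_intra
from cordbold.roi import extract_all, metrics_to_frame
from cordbold.association import correlation_battery, default_battery_pairs

__all__ = ["PipelineConfig", "run_pipeline", "DEMO_CONFIG"]


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters for one pipeline run."""

    out_dir: str = "out"
    seed: int = 0
    n_subjects: int = 8
    hands: tuple[str, ...] = ("left", "right")

    # cord phantoms / morphometry
    n_slices: int = 40
    cord_voxel_dims: tuple[float, float, float] = (0.125, 0.125, 0.9)
    baseline_radius_mm: float = 4.0
    surface_noise_sd_mm: float = 0.05
    smoothing_window: int = 3
    slope_threshold: float = 0.05
    min_extent: int = 3

    # rater simulation / reliability
    n_raters: int = 2
    n_repeats: int = 3
    rater_bias_sd: float = 8.0
    rater_residual_sd: float = 12.0

    # BOLD phantom / GLM
    bold_shape: tuple[int, int, int] = (16, 16, 10)
    bold_voxel_dims: tuple[float, float, float] = (2.3, 2.3, 2.3)
    tr: float = 1.0
    n_segments: int = 11
    segment_duration: float = 10.0
    noise_sd: float = 8.0
    baseline_intensity: float = 1000.0
    smoothing_fwhm_mm: float = 6.0
    smoothing_mode: str = "inplane"
    z_threshold: float = 3.1
    alpha: float = 0.05
    correction: str = "permutation"
    n_permutations: int = 200
    write_volumes: bool = False

    @classmethod
    def from_toml(cls, path: str) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        cfg = cls(**raw)
        for key in ("hands", "cord_voxel_dims", "bold_shape", "bold_voxel_dims"):
            object.__setattr__(cfg, key, tuple(getattr(cfg, key)))
        return cfg


DEMO_CONFIG = PipelineConfig()


def _write_sidecar(path: Path, stage: str, params: dict, inputs: list[str]) -> None:
    payload = {
        "stage": stage,
        "package_version": __version__,
        "parameters": params,
        "inputs": inputs,
    }
    path.write_text(json.dumps(payload, indent=2, default=str))


def _severity(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.uniform(0.0, 1.0, n)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order; returns the run manifest."""
    out = Path(config.out_dir)
    stages = {name: out / name for name in ("morphometry", "reliability", "glm", "roi", "association")}
    for p in stages.values():
        p.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    severity = _severity(rng, config.n_subjects)
    manifest: dict = {"config": asdict(config), "package_version": __version__, "outputs": {}}

    # ---- morphometry over per-subject cord phantoms -------------------
    morph_rows = []
    profiles = []
    for i, s in enumerate(severity):
        subject = f"S{i + 1:03d}"
        spec = synth.CordPhantomSpec(
            n_slices=config.n_slices,
            voxel_dims=config.cord_voxel_dims,
            baseline_radius=config.baseline_radius_mm,
            compressions=(
                synth.CompressionSpec(
                    center_slice=config.n_slices // 2,
                    extent_slices=5 + int(round(4 * s)),
                    max_area_reduction=0.15 + 0.45 * s,
                    shape="gaussian",
                ),
            ),
            surface_noise_sd=config.surface_noise_sd_mm,
            seed=int(rng.integers(2**31)),
        )
        mask, _truth = synth.make_cord_phantom(spec)
        profile, regions = analyze_mask(
            mask,
            window=config.smoothing_window,
            slope_threshold=config.slope_threshold,
            min_extent=config.min_extent,
            source_id=subject,
        )
        volume, deficit = total_compression_volume(regions)
        morph_rows.append(
            {
                "subject": subject,
                "n_regions": len(regions),
                "compression_volume": volume,
                "volume_deficit": deficit,
            }
        )
        profiles.append(
            pd.DataFrame(
                {
                    "subject": subject,
                    "slice_index": np.arange(len(profile)),
                    "area_mm2": profile.areas,
                    "smoothed_area_mm2": profile.smoothed_areas,
                }
            )
        )
    morph_df = pd.DataFrame(morph_rows)
    morph_df.to_csv(stages["morphometry"] / "compression_volumes.csv", index=False)
    pd.concat(profiles).to_csv(stages["morphometry"] / "area_profiles.csv", index=False)
    _write_sidecar(
        stages["morphometry"] / "sidecar.json",
        "morphometry",
        {
            "window": config.smoothing_window,
            "slope_threshold": config.slope_threshold,
            "min_extent": config.min_extent,
            "seed": config.seed,
        },
        [],
    )
    manifest["outputs"]["morphometry"] = [
        "morphometry/compression_volumes.csv",
        "morphometry/area_profiles.csv",
    ]

    # ---- rater reliability on the measured compression volumes -------
    rater_spec = synth.RaterSimSpec(
        true_values=tuple(morph_df["compression_volume"]),
        n_raters=config.n_raters,
        n_repeats=config.n_repeats,
        rater_bias_sd=config.rater_bias_sd,
        residual_sd=config.rater_residual_sd,
        seed=int(rng.integers(2**31)),
    )
    raters = synth.make_rater_table(rater_spec)
    raters.to_csv(stages["reliability"] / "raters.csv", index=False)
    inter = icc_inter(raters)
    intras = {r: icc_intra(raters, r) for r in sorted(raters["rater_id"].unique())}
    icc_payload = {
        "inter": {"icc": inter.icc, "model": inter.model_label},
        "intra": {r: {"icc": res.icc, "model": res.model_label} for r, res in intras.items()},
    }
    (stages["reliability"] / "icc.json").write_text(json.dumps(icc_payload, indent=2))
    _write_sidecar(
        stages["reliability"] / "sidecar.json",
        "reliability",
        {
            "n_raters": config.n_raters,
            "n_repeats": config.n_repeats,
            "rater_bias_sd": config.rater_bias_sd,
            "residual_sd": config.rater_residual_sd,
        },
        ["morphometry/compression_volumes.csv"],
    )
    manifest["outputs"]["reliability"] = ["reliability/raters.csv", "reliability/icc.json"]

    # ---- BOLD GLM + ROI metrics per subject and hand ------------------
    rois = synth.make_synthetic_roiset(config.bold_shape)
    roi_frames = []
    for i, s in enumerate(severity):
        subject = f"S{i + 1:03d}"
        for hand in config.hands:
            contra = "right" if hand == "left" else "left"
            active = tuple(
                (rois.masks[f"{name}_{contra}"], psc)
                for name, psc in (("M1", 0.3 + 1.3 * s), ("S1", 0.2 + 1.0 * s))
            ) + ((rois.masks["cerebellum"], 0.2 + 0.8 * s),)
            spec = synth.BoldPhantomSpec(
                volume_shape=config.bold_shape,
                voxel_dims=config.bold_voxel_dims,
                tr=config.tr,
                n_segments=config.n_segments,
                segment_duration=config.segment_duration,
                active_rois=active,
                baseline_intensity=config.baseline_intensity,
                noise_sd=config.noise_sd,
                seed=int(rng.integers(2**31)),
            )
            run = synth.make_bold_phantom(spec)
            data = smooth_volume(
                run.data, config.smoothing_fwhm_mm, run.voxel_dims, mode=config.smoothing_mode
            )
            design = build_design_matrix(run.paradigm, motion=run.motion)
            stat = fit_glm(data, design, voxel_dims=run.voxel_dims)
            clusters = cluster_threshold(
                stat,
                z_threshold=config.z_threshold,
                alpha=config.alpha,
                method=config.correction,
                n_permutations=config.n_permutations,
                rng=np.random.default_rng(int(rng.integers(2**31))),
            )
            if config.write_volumes:
                from cordbold.io import save_volume

                for name, vol in (("z", stat.z), ("psc", stat.percent_signal)):
                    save_volume(vol, run.voxel_dims, stages["glm"] / f"{subject}_{hand}_{name}.nii.gz")
            roi_frames.append(
                metrics_to_frame(extract_all(stat, clusters, rois, hand=hand), subject=subject)
            )
    roi_df = pd.concat(roi_frames, ignore_index=True)
    roi_df.to_csv(stages["roi"] / "roi_metrics.csv", index=False)
    _write_sidecar(
        stages["glm"] / "sidecar.json",
        "glm",
        {
            "z_threshold": config.z_threshold,
            "alpha": config.alpha,
            "correction": config.correction,
            "n_permutations": config.n_permutations,
            "fwhm_mm": config.smoothing_fwhm_mm,
            "smoothing_mode": config.smoothing_mode,
            "hrf": asdict(HRFParams()),
        },
        [],
    )
    manifest["outputs"]["roi"] = ["roi/roi_metrics.csv"]

    # ---- merge cohort table and run the battery -----------------------
    mjoa = np.clip(np.round(14.5 - 6.0 * severity + rng.normal(0, 1.2, severity.size)), 0, 18)
    cohort = morph_df[["subject", "compression_volume"]].copy()
    cohort["mjoa_total"] = mjoa.astype(int)
    for hand in config.hands:
        sub = roi_df[roi_df["hand"] == hand]
        for roi_name in ("M1", "S1", "cerebellum"):
            sel = sub[sub["roi_name"] == roi_name].set_index("subject")
            cohort[f"{roi_name}_percent_bold_{hand}"] = cohort["subject"].map(sel["percent_bold"])
            cohort[f"{roi_name}_voa_{hand}"] = cohort["subject"].map(sel["voa_mm3"])
    cohort.to_csv(stages["association"] / "cohort.csv", index=False)
    battery = correlation_battery(cohort, default_battery_pairs(cohort.columns))
    battery.to_csv(stages["association"] / "battery.csv", index=False)
    _write_sidecar(
        stages["association"] / "sidecar.json",
        "association",
        {"pairs": len(battery)},
        ["roi/roi_metrics.csv", "morphometry/compression_volumes.csv"],
    )
    manifest["outputs"]["association"] = ["association/cohort.csv", "association/battery.csv"]

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
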