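"""Synthetic inputs with known ground truth.

Four generators cover every input the analysis consumes:

* cord phantoms — stacks of digital disks whose per-slice area follows a
  baseline with localized, analytically-known reductions (the compressed
  cords the morphometry stage measures);
* BOLD phantoms — block-paradigm runs with a chosen true percent signal
  change inside chosen ROIs, plus motion nuisance traces;
* rater tables — repeated measurements with specified rater bias and
  residual error variance, for reliability analysis;
* cohorts — multivariate-Gaussian cohorts with a target correlation
  structure over compression volume, percent BOLD, volume of activation
  and mJOA.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cordbold.glm import (
    HRFParams,
    Paradigm,
    build_paradigm_boxcar,
    convolve_task,
    double_gamma_hrf,
)
from cordbold.morphometry import CompressionRegion, CordMask

__all__ = [
    "CompressionSpec",
    "CordPhantomSpec",
    "BoldPhantomSpec",
    "RaterSimSpec",
    "CohortSimSpec",
    "make_cord_phantom",
    "make_bold_phantom",
    "make_rater_table",
    "make_cohort",
    "make_synthetic_roiset",
    "BoldPhantom",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class CompressionSpec:
    """One localized compression on the cord phantom.

    ``extent_slices`` is the full width of the notch (for ``gaussian``
    shape, the FWHM of the area-reduction profile);
    ``max_area_reduction`` is the peak fractional area loss.
    """

    center_slice: int
    extent_slices: int
    max_area_reduction: float
    shape: str = "box"

    def __post_init__(self) -> None:
        if self.extent_slices < 1:
            raise ValueError("extent_slices must be >= 1")
        if not 0 <= self.max_area_reduction < 1:
            raise ValueError("max_area_reduction must be in [0, 1)")
        if self.shape not in ("box", "gaussian"):
            raise ValueError(f"shape must be 'box' or 'gaussian', got {self.shape!r}")

    @property
    def z_lo(self) -> int:
        return self.center_slice - (self.extent_slices - 1) // 2

    @property
    def z_hi(self) -> int:
        return self.z_lo + self.extent_slices - 1


@dataclass(frozen=True)
class CordPhantomSpec:
    n_slices: int = 40
    voxel_dims: tuple[float, float, float] = (0.125, 0.125, 0.9)
    baseline_radius: float = 4.0
    compressions: tuple[CompressionSpec, ...] = ()
    surface_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.baseline_radius <= 0:
            raise ValueError("baseline_radius must be positive")
        if self.surface_noise_sd < 0:
            raise ValueError("surface_noise_sd must be >= 0")
        object.__setattr__(self, "compressions", tuple(self.compressions))
        spans = sorted((c.z_lo, c.z_hi) for c in self.compressions)
        for (_, hi_prev), (lo, _) in zip(spans, spans[1:]):
            if lo <= hi_prev:
                raise ValueError(
                    f"compressions overlap: slice ranges {spans} are not disjoint"
                )


def _reduction_profile(spec: CordPhantomSpec) -> np.ndarray:
    """Fractional area reduction per slice from all compressions."""
    red = np.zeros(spec.n_slices)
    z = np.arange(spec.n_slices)
    for c in spec.compressions:
        if c.shape == "box":
            red[max(c.z_lo, 0) : c.z_hi + 1] += c.max_area_reduction
        else:
            sigma = c.extent_slices * _FWHM_TO_SIGMA
            red += c.max_area_reduction * np.exp(-0.5 * ((z - c.center_slice) / sigma) ** 2)
    return np.clip(red, 0.0, 0.999)


def make_cord_phantom(spec: CordPhantomSpec) -> tuple[CordMask, list[CompressionRegion]]:
    """Rasterized cord phantom plus analytic ground truth per compression.

    Each axial slice is a digital disk: voxel centres with
    ``x² + y² ≤ r(z)²`` (physical mm coordinates) are set, where
    ``r(z) = r₀ √(1 − reduction(z))`` so the *area* reduction is the
    specified fraction.  Ground truth uses the analytic area ``π r₀²``:
    per compression, the deficit is ``Σ reduction(z) · π r₀² · dz`` over
    its slice interval and the remaining cord volume is
    ``Σ (1 − reduction(z)) · π r₀² · dz``.
    """
    dx, dy, dz = spec.voxel_dims
    rng = np.random.default_rng(spec.seed)
    red = _reduction_profile(spec)
    radii = spec.baseline_radius * np.sqrt(1.0 - red)

    half_x = int(np.ceil((spec.baseline_radius + 5 * spec.surface_noise_sd) / dx)) + 2
    half_y = int(np.ceil((spec.baseline_radius + 5 * spec.surface_noise_sd) / dy)) + 2
    xs = (np.arange(-half_x, half_x + 1) * dx)[:, None]
    ys = (np.arange(-half_y, half_y + 1) * dy)[None, :]
    dist = np.sqrt(xs**2 + ys**2)
    vol = np.zeros((xs.size, ys.size, spec.n_slices), dtype=bool)
    for z in range(spec.n_slices):
        if spec.surface_noise_sd > 0:
            # per-voxel boundary roughness (mm), emulating segmentation jitter
            eps = rng.normal(0.0, spec.surface_noise_sd, dist.shape)
            vol[:, :, z] = dist <= radii[z] + eps
        else:
            vol[:, :, z] = dist <= radii[z]

    base_area = np.pi * spec.baseline_radius**2
    truth = []
    for c in spec.compressions:
        lo, hi = max(c.z_lo, 0), min(c.z_hi, spec.n_slices - 1)
        seg = red[lo : hi + 1]
        truth.append(
            CompressionRegion(
                z_lo=lo,
                z_hi=hi,
                baseline_area=base_area,
                cord_volume_in_region=float(((1 - seg) * base_area * dz).sum()),
                volume_deficit=float((seg * base_area * dz).sum()),
                detection_params={"ground_truth": True, "shape": c.shape},
            )
        )
    return CordMask(voxels=vol, voxel_dims=spec.voxel_dims), truth


@dataclass(frozen=True)
class BoldPhantomSpec:
    """Block-design BOLD phantom.

    ``active_rois`` maps each ROI mask to its true percent signal change,
    defined as the plateau-to-rest-baseline signal swing in percent of the
    rest baseline.  Defaults reproduce the study paradigm: 11 segments of
    30 s at TR 1 s → a 330-volume run.
    """

    volume_shape: tuple[int, int, int] = (16, 16, 10)
    voxel_dims: tuple[float, float, float] = (2.3, 2.3, 2.3)
    tr: float = 1.0
    n_segments: int = 11
    segment_duration: float = 30.0
    start_state: str = "rest"
    active_rois: tuple[tuple[np.ndarray, float], ...] = ()
    baseline_intensity: float = 1000.0
    noise_sd: float = 10.0
    motion_amplitude: float = 0.2
    hrf: HRFParams = field(default_factory=HRFParams)
    seed: int = 0

    def __post_init__(self) -> None:
        ratio = self.segment_duration / self.tr
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("segment_duration must be an integer multiple of tr")
        for mask, psc in self.active_rois:
            if psc < 0:
                raise ValueError("true_percent_signal must be >= 0")
            if np.asarray(mask).shape != tuple(self.volume_shape):
                raise ValueError("ROI mask shape must match volume_shape")

    @property
    def paradigm(self) -> Paradigm:
        return Paradigm(
            n_segments=self.n_segments,
            segment_duration=self.segment_duration,
            tr=self.tr,
            start_state=self.start_state,
        )


@dataclass(frozen=True)
class BoldPhantom:
    """Generated run plus everything needed to analyse it."""

    data: np.ndarray  # (x, y, z, t)
    motion: np.ndarray  # (t, 6): translations mm, rotations rad
    tr: float
    voxel_dims: tuple[float, float, float]
    paradigm: Paradigm
    truth_percent_signal: tuple[tuple[np.ndarray, float], ...]


def _motion_traces(n_t: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Slow sinusoidal drifts plus white jitter, per motion parameter."""
    t = np.arange(n_t)
    traces = np.empty((n_t, 6))
    for j in range(6):
        scale = amplitude if j < 3 else amplitude * 0.01  # radians are small
        freq = rng.uniform(0.002, 0.01)
        phase = rng.uniform(0, 2 * np.pi)
        drift = scale * rng.uniform(0.3, 1.0) * np.sin(2 * np.pi * freq * t + phase)
        traces[:, j] = drift + rng.normal(0.0, 0.05 * scale, n_t)
    return traces


def make_bold_phantom(spec: BoldPhantomSpec) -> BoldPhantom:
    """Simulate a block-design run with known per-ROI percent signal.

    The task time course is the paradigm boxcar convolved with the
    double-gamma HRF, rescaled to [0, 1] over the run (rest baseline → 0,
    plateau → 1).  Inside each active ROI the noiseless signal is
    ``baseline × (1 + psc/100 × timecourse)``; Gaussian noise of
    ``noise_sd`` is added everywhere.
    """
    rng = np.random.default_rng(spec.seed)
    paradigm = spec.paradigm
    boxcar = build_paradigm_boxcar(paradigm)
    x = convolve_task(boxcar, double_gamma_hrf(spec.tr, spec.hrf))
    u = (x - x.min()) / np.ptp(x)

    n_t = u.size
    shape = tuple(spec.volume_shape)
    psc_map = np.zeros(shape)
    for mask, psc in spec.active_rois:
        psc_map[np.asarray(mask, dtype=bool)] = psc

    signal = spec.baseline_intensity * (
        1.0 + psc_map[..., None] / 100.0 * u[None, None, None, :]
    )
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, signal.shape)
    motion = (
        _motion_traces(n_t, spec.motion_amplitude, rng)
        if spec.motion_amplitude > 0
        else np.zeros((n_t, 6))
    )
    return BoldPhantom(
        data=signal,
        motion=motion,
        tr=spec.tr,
        voxel_dims=spec.voxel_dims,
        paradigm=paradigm,
        truth_percent_signal=tuple(
            (np.asarray(m, dtype=bool), p) for m, p in spec.active_rois
        ),
    )


@dataclass(frozen=True)
class RaterSimSpec:
    """Repeated-measurement design: value = truth + rater bias + residual."""

    true_values: tuple[float, ...]
    n_raters: int = 2
    n_repeats: int = 3
    rater_bias_sd: float = 0.0
    residual_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_raters < 1 or self.n_repeats < 1:
            raise ValueError("n_raters and n_repeats must be >= 1")
        if len(self.true_values) < 1:
            raise ValueError("true_values must be non-empty")
        object.__setattr__(self, "true_values", tuple(float(v) for v in self.true_values))


def make_rater_table(spec: RaterSimSpec) -> pd.DataFrame:
    """Balanced subject × rater × repeat table of measurements (mm³).

    Each rater draws one additive bias ~ N(0, rater_bias_sd²); each
    individual measurement adds residual noise ~ N(0, residual_sd²).
    """
    rng = np.random.default_rng(spec.seed)
    biases = rng.normal(0.0, spec.rater_bias_sd, spec.n_raters) if spec.rater_bias_sd > 0 else np.zeros(spec.n_raters)
    rows = []
    for s, truth in enumerate(spec.true_values, start=1):
        for r in range(spec.n_raters):
            for k in range(spec.n_repeats):
                noise = rng.normal(0.0, spec.residual_sd) if spec.residual_sd > 0 else 0.0
                rows.append(
                    {
                        "subject_id": f"S{s:03d}",
                        "rater_id": f"R{r + 1}",
                        "repeat": k + 1,
                        "value_mm3": truth + biases[r] + noise,
                    }
                )
    return pd.DataFrame(rows)


_DEFAULT_COHORT_VARS = ("compression_volume", "percent_bold", "voa", "mjoa")

# Default targets follow the printed effect sizes of the study this package
# emulates: compression–%BOLD 0.56, compression–VOA 0.55, mJOA–compression
# −0.36, mJOA–%BOLD −0.50; %BOLD–VOA set to 0.6 (both index activation).
_DEFAULT_COHORT_CORR = np.array(
    [
        [1.00, 0.56, 0.55, -0.36],
        [0.56, 1.00, 0.60, -0.50],
        [0.55, 0.60, 1.00, -0.30],
        [-0.36, -0.50, -0.30, 1.00],
    ]
)

_DEFAULT_MARGINALS = {
    "compression_volume": (700.0, 250.0),  # mm³
    "percent_bold": (1.5, 0.6),  # %
    "voa": (4000.0, 1500.0),  # mm³
    "mjoa": (9.9, 2.1),  # 18-point scale
}


@dataclass(frozen=True)
class CohortSimSpec:
    """Gaussian cohort with a target correlation structure.

    Marginals are (mean, SD) pairs; the mJOA column is rounded and clipped
    to its 0–18 integer scale after the Gaussian draw.
    """

    n_subjects: int = 23
    variables: tuple[str, ...] = _DEFAULT_COHORT_VARS
    target_correlation: np.ndarray = field(default_factory=lambda: _DEFAULT_COHORT_CORR.copy())
    marginal_means_sds: dict = field(default_factory=lambda: dict(_DEFAULT_MARGINALS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        C = np.asarray(self.target_correlation, dtype=float)
        k = len(self.variables)
        if C.shape != (k, k):
            raise ValueError(f"correlation matrix must be {k}×{k}, got {C.shape}")
        if not np.allclose(C, C.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ValueError("correlation matrix is not positive semi-definite")
        object.__setattr__(self, "target_correlation", C)
        missing = [v for v in self.variables if v not in self.marginal_means_sds]
        if missing:
            raise ValueError(f"marginals missing for variables: {missing}")


def make_synthetic_roiset(volume_shape: tuple[int, int, int]):
    """Disjoint box ROIs emulating the motor-network atlas layout.

    Cortical regions (M1, S1, SMA, PMC) get one box per hemisphere —
    left hemisphere is the lower half of the x axis — in the top half of
    the slice stack; bilateral subcortical regions (cerebellum, putamen,
    caudate, thalamus) span both hemispheres in the bottom half.
    """
    from cordbold.roi import CORTICAL_ROIS, SUBCORTICAL_ROIS, RoiSet

    nx, ny, nz = volume_shape
    if nx < 8 or ny < 8 or nz < 4:
        raise ValueError(f"volume {volume_shape} too small for the synthetic ROI layout")
    masks = {}
    y_edges = np.linspace(0, ny, len(CORTICAL_ROIS) + 1).astype(int)
    z_top = slice(nz // 2, nz)
    for i, name in enumerate(CORTICAL_ROIS):
        ys = slice(y_edges[i], y_edges[i + 1])
        left = np.zeros(volume_shape, dtype=bool)
        left[1 : nx // 2 - 1, ys, z_top] = True
        right = np.zeros(volume_shape, dtype=bool)
        right[nx // 2 + 1 : nx - 1, ys, z_top] = True
        masks[f"{name}_left"] = left
        masks[f"{name}_right"] = right
    y_edges = np.linspace(0, ny, len(SUBCORTICAL_ROIS) + 1).astype(int)
    z_bottom = slice(0, nz // 2)
    for i, name in enumerate(SUBCORTICAL_ROIS):
        ys = slice(y_edges[i], y_edges[i + 1])
        m = np.zeros(volume_shape, dtype=bool)
        m[1 : nx - 1, ys, z_bottom] = True
        masks[name] = m
    return RoiSet(masks=masks, provenance="synthetic")


def make_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Draw a synthetic cohort from the specified Gaussian model."""
    rng = np.random.default_rng(spec.seed)
    C = spec.target_correlation
    w, V = np.linalg.eigh(C)
    factor = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((spec.n_subjects, len(spec.variables))) @ factor.T
    df = pd.DataFrame({"case_id": np.arange(1, spec.n_subjects + 1)})
    for j, name in enumerate(spec.variables):
        mean, sd = spec.marginal_means_sds[name]
        col = mean + sd * z[:, j]
        if name.startswith("mjoa"):
            col = np.clip(np.round(col), 0, 18).astype(int)
        df[name] = col
    return df
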