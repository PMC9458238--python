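"""Synthetic MALDI-MSI data with known ground truth.

Generates per-pixel spectra as sums of Gaussian peptide peaks over a common
m/z axis, with spatially coherent molecular clusters planted inside each
ROI, optional paired tumor/node ROIs with controllable divergence, baseline
drift, multiplicative TIC variation, additive noise, and a minority of
TIC-outlier pixels.  Everything is deterministic under a fixed seed.

A pixel spectrum is built as::

    TIC_scale * ( sum_k A[cluster, k] * Gauss(mz; mu_k, sigma_k) + baseline(mz) ) + noise

where the Gaussians have unit area, so the planted abundance ``A`` is the
integrated peak area contributed by peptide species ``k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import MSIDataset, gaussian_profiles

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "StudyPatient",
    "StudyBundle",
    "simulate_dataset",
    "simulate_two_arm_study",
    "planted_simpson",
]


class ConfigurationError(ValueError):
    """Raised for inconsistent simulation configurations."""


@dataclass
class SimulationConfig:
    """Study conditions of one simulated specimen (and, via the study
    helpers, of one trial arm).

    Defaults mirror the imaged-cohort design: spectra on 700-3000 m/z at
    ~0.1 m/z spacing (>= 10 channels per peak), ROIs of a few thousand
    pixels, several spatially coherent molecular clusters per cancer ROI,
    moderate per-pixel acquisition variation and a small fraction of
    outlying spectra.
    """

    n_patients_per_group: int = 20
    mz_min: float = 700.0
    mz_max: float = 3000.0
    n_channels: int = 23000
    n_peaks: int = 150
    peak_sigma_range: tuple[float, float] = (0.2, 0.35)
    roi_shape: tuple[int, int] = (40, 40)
    n_clusters_per_roi: int = 4
    cluster_proportions: str | Sequence[float] = "balanced"
    proportion_concentration: float | None = None
    tn_divergence: float = 0.0
    paired_tn: bool = False
    baseline_amplitude: float = 0.5
    tic_cv: float = 0.15
    noise_sd: float = 0.05
    outlier_fraction: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.mz_min >= self.mz_max:
            raise ConfigurationError("mz_min must be below mz_max")
        if self.n_channels < 10 or self.n_peaks < 1:
            raise ConfigurationError("need at least 10 channels and 1 peak")
        if self.n_clusters_per_roi < 1:
            raise ConfigurationError("n_clusters_per_roi must be >= 1")
        if not (0.0 <= self.outlier_fraction <= 1.0):
            raise ConfigurationError("outlier_fraction must lie in [0, 1]")
        if not (0.0 <= self.tn_divergence <= 1.0):
            raise ConfigurationError("tn_divergence must lie in [0, 1]")
        if self.tic_cv < 0 or self.noise_sd < 0 or self.baseline_amplitude < 0:
            raise ConfigurationError("noise parameters must be nonnegative")
        if self.peak_sigma_range[0] <= 0 or (
            self.peak_sigma_range[0] > self.peak_sigma_range[1]
        ):
            raise ConfigurationError("invalid peak_sigma_range")
        if self.proportion_concentration is not None and (
            self.proportion_concentration <= 0
        ):
            raise ConfigurationError("proportion_concentration must be positive")
        p = self.resolved_proportions()
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError("cluster proportions must be a simplex vector")

    def resolved_proportions(self) -> np.ndarray:
        k = self.n_clusters_per_roi
        if isinstance(self.cluster_proportions, str):
            if self.cluster_proportions == "balanced":
                return np.full(k, 1.0 / k)
            if self.cluster_proportions == "skewed":
                p = 0.5 ** np.arange(k)
                return p / p.sum()
            raise ConfigurationError(
                f"unknown proportions preset {self.cluster_proportions!r}"
            )
        p = np.asarray(self.cluster_proportions, dtype=float)
        if len(p) != k:
            raise ConfigurationError("cluster_proportions length != n_clusters_per_roi")
        return p


@dataclass
class GroundTruth:
    """Planted truth accompanying a simulated dataset."""

    peak_means: np.ndarray
    peak_sigmas: np.ndarray
    cluster_label_map: np.ndarray  # per pixel, aligned with the dataset
    cluster_mean_profiles: np.ndarray  # clusters x peaks, nonnegative
    outlier_mask: np.ndarray  # per pixel


def planted_simpson(labels: np.ndarray) -> float:
    """Gini-Simpson diversity of a planted label vector."""
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(1.0 - np.sum(p**2))


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------


def _draw_peaks(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Peak means uniform over the axis with minimum spacing 3 sigma_max,
    keeping 5 sigma_max clear of the axis edges."""
    s_lo, s_hi = config.peak_sigma_range
    gap = 3.0 * s_hi
    margin = 5.0 * s_hi
    span = (config.mz_max - config.mz_min) - 2 * margin - (config.n_peaks - 1) * gap
    if span <= 0:
        raise ConfigurationError("m/z range too narrow for n_peaks at 3-sigma spacing")
    u = np.sort(rng.uniform(0.0, span, size=config.n_peaks))
    means = config.mz_min + margin + u + gap * np.arange(config.n_peaks)
    sigmas = rng.uniform(s_lo, s_hi, size=config.n_peaks)
    return means, sigmas


def _draw_profiles(
    n_clusters: int, n_peaks: int, rng: np.random.Generator
) -> np.ndarray:
    """Cluster mean abundance profiles: independent log-normal peak areas."""
    return rng.lognormal(mean=0.0, sigma=1.0, size=(n_clusters, n_peaks))


def _patch_labels(
    shape: tuple[int, int], proportions: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Spatially contiguous cluster patches with exact planted proportions.

    Voronoi-style: each cluster claims its quota of the pixels nearest to
    its random seed point, in cluster order, among pixels still free.
    """
    rows, cols = shape
    n = rows * cols
    k = len(proportions)
    yy, xx = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    pts = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    seeds = np.column_stack(
        [rng.uniform(0, rows, size=k), rng.uniform(0, cols, size=k)]
    )
    counts = np.floor(proportions * n).astype(int)
    counts[: n - counts.sum()] += 1  # largest-remainder style top-up
    labels = np.full(n, -1, dtype=int)
    free = np.ones(n, dtype=bool)
    for c in range(k):
        d = np.linalg.norm(pts - seeds[c], axis=1)
        d[~free] = np.inf
        take = np.argsort(d, kind="stable")[: counts[c]]
        labels[take] = c
        free[take] = False
    return labels


def _pixel_spectra(
    labels: np.ndarray,
    profiles: np.ndarray,
    peak_means: np.ndarray,
    peak_sigmas: np.ndarray,
    mz_axis: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    n = len(labels)
    G = gaussian_profiles(peak_means, peak_sigmas, mz_axis)
    base = profiles[labels] @ G.toarray()
    if config.baseline_amplitude > 0:
        span = config.mz_max - config.mz_min
        baseline = config.baseline_amplitude * np.exp(
            -(mz_axis - config.mz_min) / (span / 3.0)
        )
        base = base + baseline
    if config.tic_cv > 0:
        s = np.sqrt(np.log1p(config.tic_cv**2))
        scale = rng.lognormal(mean=-0.5 * s**2, sigma=s, size=n)
    else:
        scale = np.ones(n)
    outliers = np.zeros(n, dtype=bool)
    n_out = int(np.floor(config.outlier_fraction * n))
    if n_out > 0:
        idx = rng.choice(n, size=n_out, replace=False)
        outliers[idx] = True
        scale[idx] *= rng.choice([10.0, 0.1], size=n_out)
    spectra = base * scale[:, None]
    if config.noise_sd > 0:
        spectra = spectra + rng.normal(0.0, config.noise_sd, size=spectra.shape)
    return np.clip(spectra, 0.0, None), outliers


# ---------------------------------------------------------------------------
# Public generators
# ---------------------------------------------------------------------------


def simulate_dataset(
    config: SimulationConfig,
    *,
    rng: np.random.Generator | None = None,
    peaks: tuple[np.ndarray, np.ndarray] | None = None,
    profile_library: np.ndarray | None = None,
    patient_id: str = "P01",
    group: str = "NED",
    lhr_category: str = "intermediate",
) -> tuple[MSIDataset, GroundTruth]:
    """Simulate one specimen: a tumor ROI and, when ``config.paired_tn`` is
    set, a paired lymph-node ROI whose cluster profiles diverge on a
    ``tn_divergence`` fraction of the peaks.

    ``peaks`` and ``profile_library`` allow a study-level caller to share
    the peptide species and molecular phenotypes across patients.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mz_axis = np.linspace(config.mz_min, config.mz_max, config.n_channels)
    if peaks is None:
        peak_means, peak_sigmas = _draw_peaks(config, rng)
    else:
        peak_means, peak_sigmas = (np.asarray(p, dtype=float) for p in peaks)
        if len(peak_means) != config.n_peaks:
            raise ConfigurationError("shared peaks inconsistent with n_peaks")
    k = config.n_clusters_per_roi
    if profile_library is None:
        profiles = _draw_profiles(k, config.n_peaks, rng)
    else:
        profile_library = np.asarray(profile_library, dtype=float)
        if profile_library.shape[0] < k or profile_library.shape[1] != config.n_peaks:
            raise ConfigurationError("profile library inconsistent with config")
        profiles = profile_library[:k]

    def realized_proportions() -> np.ndarray:
        # with a finite concentration, each ROI's composition is a Dirichlet
        # draw around the configured proportions (biological variability)
        p = config.resolved_proportions()
        if config.proportion_concentration is None or k == 1:
            return p
        return rng.dirichlet(config.proportion_concentration * p)

    rows, cols = config.roi_shape
    yy, xx = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords_t = np.column_stack([xx.ravel(), yy.ravel()])
    labels_t = _patch_labels(config.roi_shape, realized_proportions(), rng)
    spectra_t, out_t = _pixel_spectra(
        labels_t, profiles, peak_means, peak_sigmas, mz_axis, config, rng
    )

    spectra = [spectra_t]
    coords = [coords_t]
    roi_labels = [np.zeros(len(labels_t), dtype=int)]
    labels_all = [labels_t]
    outliers = [out_t]
    meta_rows = [
        {
            "patient_id": patient_id,
            "group": group,
            "tissue": "T",
            "lhr_category": lhr_category,
        }
    ]
    if config.paired_tn:
        n_div = int(round(config.tn_divergence * config.n_peaks))
        factors = np.ones(config.n_peaks)
        if n_div > 0:
            div_idx = rng.choice(config.n_peaks, size=n_div, replace=False)
            factors[div_idx] = rng.choice([2.0, 0.5], size=n_div)
        profiles_n = profiles * factors
        labels_n = _patch_labels(config.roi_shape, realized_proportions(), rng)
        spectra_n, out_n = _pixel_spectra(
            labels_n, profiles_n, peak_means, peak_sigmas, mz_axis, config, rng
        )
        coords_n = coords_t + np.array([cols + 5, 0])
        spectra.append(spectra_n)
        coords.append(coords_n)
        roi_labels.append(np.ones(len(labels_n), dtype=int))
        labels_all.append(labels_n)
        outliers.append(out_n)
        meta_rows.append(
            {
                "patient_id": patient_id,
                "group": group,
                "tissue": "N",
                "lhr_category": lhr_category,
            }
        )

    dataset = MSIDataset(
        mz_axis=mz_axis,
        spectra=np.vstack(spectra),
        coords=np.vstack(coords),
        roi_labels=np.concatenate(roi_labels),
        roi_meta=pd.DataFrame(meta_rows),
    )
    truth = GroundTruth(
        peak_means=peak_means,
        peak_sigmas=peak_sigmas,
        cluster_label_map=np.concatenate(labels_all),
        cluster_mean_profiles=profiles,
        outlier_mask=np.concatenate(outliers),
    )
    return dataset, truth


@dataclass
class StudyPatient:
    patient_id: str
    arm: str
    dataset: MSIDataset
    truth: GroundTruth
    planted_simpson: float


@dataclass
class StudyBundle:
    """A two-arm synthetic cohort sharing peptide species and phenotypes."""

    patients: list[StudyPatient]
    arm_names: tuple[str, str]
    peak_means: np.ndarray
    peak_sigmas: np.ndarray
    profile_library: np.ndarray
    planted_simpson_by_arm: dict = field(default_factory=dict)
    #: arm -> Gini-Simpson index of the *configured* cluster proportions
    design_simpson_by_arm: dict = field(default_factory=dict)

    def datasets(self) -> list[MSIDataset]:
        return [p.dataset for p in self.patients]


def simulate_two_arm_study(
    config_high: SimulationConfig,
    config_low: SimulationConfig,
    *,
    arm_names: tuple[str, str] = ("NED", "PD"),
) -> StudyBundle:
    """Simulate a cohort with a high-ITH arm and a low-ITH arm.

    Both arms share one peptide peak set and one library of cluster
    phenotype profiles (the low arm uses a subset), so that a pooled
    segmentation across patients is meaningful.  The planted per-patient
    Simpson diversity is recorded per arm.
    """
    for cfg in (config_high, config_low):
        cfg.validate()
    same_axis = (
        config_high.mz_min == config_low.mz_min
        and config_high.mz_max == config_low.mz_max
        and config_high.n_channels == config_low.n_channels
        and config_high.n_peaks == config_low.n_peaks
    )
    if not same_axis:
        raise ConfigurationError("arms must share m/z axis and peak count")
    master = np.random.default_rng(config_high.seed)
    peaks = _draw_peaks(config_high, master)
    n_lib = max(config_high.n_clusters_per_roi, config_low.n_clusters_per_roi)
    library = _draw_profiles(n_lib, config_high.n_peaks, master)

    patients: list[StudyPatient] = []
    simpson_by_arm: dict[str, list[float]] = {a: [] for a in arm_names}
    for arm_idx, (arm, cfg) in enumerate(
        zip(arm_names, (config_high, config_low))
    ):
        for i in range(cfg.n_patients_per_group):
            rng = np.random.default_rng([cfg.seed, arm_idx, i])
            pid = f"{arm}{i + 1:02d}"
            ds, truth = simulate_dataset(
                cfg,
                rng=rng,
                peaks=peaks,
                profile_library=library,
                patient_id=pid,
                group=arm,
            )
            t_pixels = ds.roi_labels == 0
            d = planted_simpson(truth.cluster_label_map[t_pixels])
            patients.append(
                StudyPatient(
                    patient_id=pid,
                    arm=arm,
                    dataset=ds,
                    truth=truth,
                    planted_simpson=d,
                )
            )
            simpson_by_arm[arm].append(d)
    return StudyBundle(
        patients=patients,
        arm_names=arm_names,
        peak_means=peaks[0],
        peak_sigmas=peaks[1],
        profile_library=library,
        planted_simpson_by_arm={
            a: np.asarray(v) for a, v in simpson_by_arm.items()
        },
        design_simpson_by_arm={
            arm: float(1.0 - np.sum(cfg.resolved_proportions() ** 2))
            for arm, cfg in zip(arm_names, (config_high, config_low))
        },
    )
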