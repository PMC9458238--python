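"""Spectral preprocessing for MALDI-MSI datasets.

Turns raw per-pixel spectra into a pixels x components abundance matrix.
The stages run in a fixed order: mass-channel unification, baseline
subtraction, outlying-spectra removal, peak alignment, TIC normalization,
Gaussian-mixture componentization of the average spectrum, and per-pixel
abundance estimation by inner product with the unit-area component
profiles.  Each stage appends its name to the dataset provenance log so
that the contract on stage ordering is checkable after the fact.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse
from scipy.ndimage import minimum_filter1d, uniform_filter1d
from scipy.signal import find_peaks, peak_widths

__all__ = [
    "MSIDataset",
    "ComponentModel",
    "AbundanceMatrix",
    "PreprocessParams",
    "PreprocessResult",
    "unify_mass_channels",
    "subtract_baseline",
    "subtract_baseline_dataset",
    "detect_outlier_pixels",
    "estimate_pixel_shifts",
    "align_peaks",
    "tic_normalize",
    "average_spectrum",
    "fit_gmm_components",
    "estimate_abundance",
    "merge_isotope_envelopes",
    "gaussian_profiles",
    "concatenate_datasets",
    "preprocess_pipeline",
]

#: Canonical stage order of the preprocessing pipeline.
STAGE_ORDER = (
    "unify_mass_channels",
    "subtract_baseline",
    "detect_outlier_pixels",
    "align_peaks",
    "tic_normalize",
    "fit_gmm_components",
    "estimate_abundance",
)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class MSIDataset:
    """Pixel spectra on a shared m/z axis plus spatial and clinical metadata.

    Parameters
    ----------
    mz_axis
        Strictly increasing m/z values, shape ``(C,)``.
    spectra
        Intensities, shape ``(P, C)``; one row per image pixel.
    coords
        Integer ``(x, y)`` grid positions, shape ``(P, 2)``.
    roi_labels
        Per-pixel ROI id (index into ``roi_meta``); ``-1`` marks pixels
        outside every delineated region.
    roi_meta
        One row per ROI: ``patient_id``, ``group`` (NED/PD), ``tissue``
        (T/N) and ``lhr_category`` (weak/intermediate/strong).
    """

    mz_axis: np.ndarray
    spectra: np.ndarray
    coords: np.ndarray
    roi_labels: np.ndarray
    roi_meta: pd.DataFrame
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mz_axis = np.asarray(self.mz_axis, dtype=float)
        self.spectra = np.asarray(self.spectra)
        self.coords = np.asarray(self.coords, dtype=int)
        self.roi_labels = np.asarray(self.roi_labels, dtype=int)
        if self.mz_axis.ndim != 1 or np.any(np.diff(self.mz_axis) <= 0):
            raise ValueError("mz_axis must be 1-D and strictly increasing")
        if self.spectra.shape != (len(self.coords), len(self.mz_axis)):
            raise ValueError(
                f"spectra shape {self.spectra.shape} inconsistent with "
                f"{len(self.coords)} pixels x {len(self.mz_axis)} channels"
            )
        if self.roi_labels.shape != (len(self.coords),):
            raise ValueError("roi_labels must have one entry per pixel")

    @property
    def n_pixels(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_channels(self) -> int:
        return self.spectra.shape[1]

    def tic(self) -> np.ndarray:
        """Total ion current (summed intensity) per pixel."""
        return np.asarray(self.spectra.sum(axis=1), dtype=float)

    def subset(self, mask: np.ndarray) -> "MSIDataset":
        """Restrict to the pixels where ``mask`` is true."""
        mask = np.asarray(mask, dtype=bool)
        return MSIDataset(
            mz_axis=self.mz_axis,
            spectra=self.spectra[mask],
            coords=self.coords[mask],
            roi_labels=self.roi_labels[mask],
            roi_meta=self.roi_meta,
            provenance=list(self.provenance),
        )

    def replace(self, *, stage: str | None = None, **changes) -> "MSIDataset":
        ds = dataclasses.replace(self, **changes)
        ds.provenance = list(self.provenance)
        if stage is not None:
            ds.provenance.append(stage)
        return ds

    def pixel_meta(self, column: str) -> np.ndarray:
        """Broadcast a ``roi_meta`` column to pixel level (``None`` off-ROI)."""
        values = np.empty(self.n_pixels, dtype=object)
        values[:] = None
        inside = self.roi_labels >= 0
        values[inside] = self.roi_meta[column].to_numpy()[self.roi_labels[inside]]
        return values


@dataclass
class ComponentModel:
    """Gaussian peak components fitted to the average spectrum.

    Each component ``k`` is a unit-area Gaussian with mean ``means[k]``
    (m/z), width ``sigmas[k]`` (m/z) and mixture weight ``weights[k]``.
    """

    means: np.ndarray
    sigmas: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not (len(self.means) == len(self.sigmas) == len(self.weights)):
            raise ValueError("means, sigmas, weights must share length")
        if np.any(self.sigmas <= 0):
            raise ValueError("all sigmas must be positive")
        if np.any(np.diff(self.means) < 0):
            raise ValueError("means must be sorted ascending")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")

    @property
    def n_components(self) -> int:
        return len(self.means)

    def profile_matrix(self, mz_axis: np.ndarray) -> scipy.sparse.csr_matrix:
        """Unit-area component profiles evaluated on ``mz_axis`` (K x C)."""
        return gaussian_profiles(self.means, self.sigmas, mz_axis)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "means": self.means.tolist(),
                    "sigmas": self.sigmas.tolist(),
                    "weights": self.weights.tolist(),
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "ComponentModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["means"], d["sigmas"], d["weights"])


@dataclass
class AbundanceMatrix:
    """Pixels x components abundances aligned with an :class:`MSIDataset`."""

    values: np.ndarray
    component_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.component_ids = np.asarray(self.component_ids, dtype=int)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.component_ids):
            raise ValueError("values must be pixels x len(component_ids)")
        if np.any(self.values < 0):
            raise ValueError("abundances must be nonnegative")

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def n_components(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def gaussian_profiles(
    means: Sequence[float],
    sigmas: Sequence[float],
    mz_axis: np.ndarray,
    support: float = 8.0,
) -> scipy.sparse.csr_matrix:
    """Unit-area Gaussian profiles on a channel axis, truncated at ``support``
    standard deviations (sparse, K x C)."""
    mz_axis = np.asarray(mz_axis, dtype=float)
    means = np.asarray(means, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    rows, cols, vals = [], [], []
    for k, (mu, s) in enumerate(zip(means, sigmas)):
        lo = np.searchsorted(mz_axis, mu - support * s)
        hi = np.searchsorted(mz_axis, mu + support * s)
        if hi <= lo:
            continue
        x = mz_axis[lo:hi]
        g = np.exp(-0.5 * ((x - mu) / s) ** 2) / (s * np.sqrt(2.0 * np.pi))
        rows.append(np.full(hi - lo, k))
        cols.append(np.arange(lo, hi))
        vals.append(g)
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
    return scipy.sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(means), len(mz_axis))
    )


def concatenate_datasets(datasets: Sequence[MSIDataset]) -> MSIDataset:
    """Stack datasets sharing an m/z axis; ROI ids are re-numbered globally."""
    if not datasets:
        raise ValueError("no datasets to concatenate")
    axis = datasets[0].mz_axis
    for ds in datasets[1:]:
        if len(ds.mz_axis) != len(axis) or not np.allclose(ds.mz_axis, axis):
            raise ValueError("datasets must share the m/z axis; unify first")
    metas, labels = [], []
    offset = 0
    for ds in datasets:
        lab = ds.roi_labels.copy()
        lab[lab >= 0] += offset
        labels.append(lab)
        metas.append(ds.roi_meta)
        offset += len(ds.roi_meta)
    return MSIDataset(
        mz_axis=axis,
        spectra=np.vstack([ds.spectra for ds in datasets]),
        coords=np.vstack([ds.coords for ds in datasets]),
        roi_labels=np.concatenate(labels),
        roi_meta=pd.concat(metas, ignore_index=True),
        provenance=list(datasets[0].provenance),
    )


# ---------------------------------------------------------------------------
# Stage 1: mass channel unification
# ---------------------------------------------------------------------------


def unify_mass_channels(datasets: Sequence[MSIDataset]) -> list[MSIDataset]:
    """Resample all datasets onto one common m/z axis.

    The common axis spans the intersection of the native ranges at the
    finest native spacing; spectra are linearly interpolated.
    """
    if not datasets:
        return []
    lo = max(float(ds.mz_axis[0]) for ds in datasets)
    hi = min(float(ds.mz_axis[-1]) for ds in datasets)
    if lo >= hi:
        raise ValueError("datasets have disjoint m/z ranges")
    spacing = min(float(np.median(np.diff(ds.mz_axis))) for ds in datasets)
    identical = all(
        len(ds.mz_axis) == len(datasets[0].mz_axis)
        and np.array_equal(ds.mz_axis, datasets[0].mz_axis)
        for ds in datasets
    )
    if identical:
        return [ds.replace(stage="unify_mass_channels") for ds in datasets]
    n = int(np.floor((hi - lo) / spacing)) + 1
    axis = lo + spacing * np.arange(n)
    out = []
    for ds in datasets:
        resampled = np.empty((ds.n_pixels, n), dtype=float)
        for p in range(ds.n_pixels):
            resampled[p] = np.interp(axis, ds.mz_axis, ds.spectra[p])
        out.append(
            ds.replace(mz_axis=axis, spectra=resampled, stage="unify_mass_channels")
        )
    return out


# ---------------------------------------------------------------------------
# Stage 2: baseline subtraction
# ---------------------------------------------------------------------------


def subtract_baseline(spectrum: np.ndarray, window: int) -> np.ndarray:
    """Remove a slowly varying baseline from one spectrum.

    The baseline is estimated as the rolling minimum over ``window``
    channels, smoothed by a moving average of the same width; the result
    is subtracted and negatives are clipped to zero.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if window < 3:
        raise ValueError("window must span at least 3 channels")
    if window > spectrum.shape[-1]:
        raise ValueError("window larger than the spectrum")
    envelope = minimum_filter1d(spectrum, size=window, axis=-1, mode="nearest")
    baseline = uniform_filter1d(envelope, size=window, axis=-1, mode="nearest")
    return np.clip(spectrum - baseline, 0.0, None)


def subtract_baseline_dataset(dataset: MSIDataset, window: int) -> MSIDataset:
    return dataset.replace(
        spectra=subtract_baseline(dataset.spectra, window),
        stage="subtract_baseline",
    )


# ---------------------------------------------------------------------------
# Stage 3: outlying spectra identification
# ---------------------------------------------------------------------------


def detect_outlier_pixels(dataset: MSIDataset, n_sigma: float = 3.0) -> np.ndarray:
    """Flag pixels whose log total ion current is a robust outlier.

    A pixel is flagged when its log-TIC deviates from the median by more
    than ``n_sigma`` MAD-based robust standard deviations.  Pixels with
    nonpositive TIC are always flagged.
    """
    if dataset.n_pixels < 10:
        raise ValueError("need at least 10 pixels for outlier detection")
    tic = dataset.tic()
    flags = tic <= 0
    log_tic = np.where(flags, np.nan, np.log(np.where(flags, 1.0, tic)))
    med = np.nanmedian(log_tic)
    mad = np.nanmedian(np.abs(log_tic - med))
    robust_sd = 1.4826 * mad
    dev = np.abs(np.nan_to_num(log_tic - med, nan=np.inf))
    if robust_sd > 0:
        flags |= dev > n_sigma * robust_sd
    else:
        # degenerate spread: the band collapses onto the median itself
        flags |= dev > 1e-12
    return flags


# ---------------------------------------------------------------------------
# Stage 4: peak alignment
# ---------------------------------------------------------------------------


def estimate_pixel_shifts(
    dataset: MSIDataset, reference: np.ndarray, max_shift: int = 5
) -> np.ndarray:
    """Integer channel shift per pixel maximizing cross-correlation with
    ``reference``; ties resolve toward the smallest magnitude."""
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (dataset.n_channels,):
        raise ValueError("reference must live on the dataset m/z axis")
    C = dataset.n_channels
    shifts_order = sorted(range(-max_shift, max_shift + 1), key=lambda s: (abs(s), s))
    best_score = np.full(dataset.n_pixels, -np.inf)
    best_shift = np.zeros(dataset.n_pixels, dtype=int)
    for s in shifts_order:
        # corrected[c] = spectrum[c - s]; score = sum_c spectrum[c - s] ref[c]
        j0, j1 = max(0, -s), C - max(0, s)
        score = dataset.spectra[:, j0:j1] @ reference[j0 + s : j1 + s]
        better = score > best_score
        best_score[better] = score[better]
        best_shift[better] = s
    return best_shift


def _roll_zero(spectra: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    out = np.zeros_like(spectra)
    C = spectra.shape[1]
    for s in np.unique(shifts):
        rows = shifts == s
        if s == 0:
            out[rows] = spectra[rows]
        elif s > 0:
            out[rows, s:] = spectra[rows][:, : C - s]
        else:
            out[rows, :s] = spectra[rows][:, -s:]
    return out


def align_peaks(
    dataset: MSIDataset, reference: np.ndarray | None = None, max_shift: int = 5
) -> MSIDataset:
    """Align each pixel to the reference (default: dataset average spectrum)
    by a constant integer channel shift."""
    if reference is None:
        reference = average_spectrum(dataset)
    shifts = estimate_pixel_shifts(dataset, reference, max_shift=max_shift)
    return dataset.replace(
        spectra=_roll_zero(np.asarray(dataset.spectra, dtype=float), shifts),
        stage="align_peaks",
    )


# ---------------------------------------------------------------------------
# Stage 5: TIC normalization
# ---------------------------------------------------------------------------


def tic_normalize(dataset: MSIDataset) -> MSIDataset:
    """Scale every pixel to the mean total ion current of the dataset."""
    tic = dataset.tic()
    if np.any(tic <= 0):
        raise ValueError("zero-TIC pixel encountered; remove outliers first")
    target = tic.mean()
    return dataset.replace(
        spectra=np.asarray(dataset.spectra, dtype=float) * (target / tic)[:, None],
        stage="tic_normalize",
    )


def average_spectrum(dataset: MSIDataset) -> np.ndarray:
    return np.asarray(dataset.spectra, dtype=float).mean(axis=0)


# ---------------------------------------------------------------------------
# Stage 6: GMM componentization of the average spectrum
# ---------------------------------------------------------------------------


def fit_gmm_components(
    average: np.ndarray,
    mz_axis: np.ndarray,
    *,
    q: float = 50.0,
    w_min: float = 1e-5,
    sigma_bounds: tuple[float, float] | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
    support: float = 6.0,
) -> ComponentModel:
    """Model the average spectrum as a mixture of Gaussian peaks.

    The baseline-subtracted average spectrum, normalized to unit mass, is
    treated as a density over m/z.  Components are initialized at local
    maxima above the ``q``-quantile intensity threshold and refined by EM
    on the binned data.  Components with weight below ``w_min`` or width
    outside ``sigma_bounds`` are pruned.

    EM truncates each component's support at ``support`` standard
    deviations, which keeps the fit linear in the number of components.
    """
    y = np.clip(np.asarray(average, dtype=float), 0.0, None)
    mz = np.asarray(mz_axis, dtype=float)
    if y.shape != mz.shape:
        raise ValueError("average spectrum and mz axis must share shape")
    total = y.sum()
    if total <= 0:
        raise ValueError("average spectrum is empty")
    dm = float(np.median(np.diff(mz)))
    if sigma_bounds is None:
        sigma_bounds = (0.5 * dm, 100.0 * dm)
    theta = np.percentile(y, q)
    idx, _ = find_peaks(y, height=max(theta, np.finfo(float).tiny))
    if len(idx) == 0:
        raise ValueError("no local maxima above the intensity threshold")
    width_ch = peak_widths(y, idx, rel_height=0.5)[0]
    mu = mz[idx].astype(float)
    sigma = np.clip(width_ch * dm / 2.355, sigma_bounds[0], sigma_bounds[1])
    w = y[idx] / y[idx].sum()
    yn = y / total
    alive = np.ones(len(mu), dtype=bool)
    ll_old = -np.inf
    sqrt2pi = np.sqrt(2.0 * np.pi)
    for _ in range(max_iter):
        denom = np.zeros_like(yn)
        slices, dens = [], []
        for k in range(len(mu)):
            if not alive[k]:
                slices.append(None)
                dens.append(None)
                continue
            lo = np.searchsorted(mz, mu[k] - support * sigma[k])
            hi = np.searchsorted(mz, mu[k] + support * sigma[k])
            if hi - lo < 2:
                alive[k] = False
                slices.append(None)
                dens.append(None)
                continue
            x = mz[lo:hi]
            d = w[k] * np.exp(-0.5 * ((x - mu[k]) / sigma[k]) ** 2) / (
                sigma[k] * sqrt2pi
            )
            denom[lo:hi] += d
            slices.append((lo, hi))
            dens.append(d)
        pos = denom > 0
        ll = float(np.sum(yn[pos] * np.log(denom[pos])))
        for k in range(len(mu)):
            if not alive[k]:
                continue
            lo, hi = slices[k]
            r = np.zeros(hi - lo)
            p = denom[lo:hi] > 0
            r[p] = dens[k][p] / denom[lo:hi][p]
            wy = yn[lo:hi] * r
            s0 = wy.sum()
            if s0 <= 0:
                alive[k] = False
                continue
            x = mz[lo:hi]
            m1 = float(wy @ x) / s0
            var = float(wy @ (x - m1) ** 2) / s0
            mu[k] = m1
            sigma[k] = float(np.clip(np.sqrt(max(var, 0.0)), 0.25 * dm, None))
            w[k] = s0
        w[~alive] = 0.0
        ws = w.sum()
        if ws <= 0:
            raise ValueError("all components died during EM")
        w = w / ws
        if np.isfinite(ll_old) and abs(ll - ll_old) <= tol * abs(ll_old):
            break
        ll_old = ll
    keep = alive & (w >= w_min) & (sigma >= sigma_bounds[0]) & (sigma <= sigma_bounds[1])
    if not np.any(keep):
        raise ValueError("all components pruned; relax w_min or sigma_bounds")
    order = np.argsort(mu[keep])
    return ComponentModel(
        means=mu[keep][order],
        sigmas=sigma[keep][order],
        weights=(w[keep] / w[keep].sum())[order],
    )


def merge_isotope_envelopes(
    model: ComponentModel, spacing: float = 1.00235, tol: float = 0.3
) -> ComponentModel:
    """Collapse chains of components spaced by one isotope gap (~1.00235 Da)
    into their monoisotopic member.  Off by default in the pipeline: the
    components are treated as peptide species including their envelopes."""
    keep = np.ones(model.n_components, dtype=bool)
    weights = model.weights.copy()
    head = 0
    for k in range(1, model.n_components):
        gap = model.means[k] - model.means[k - 1]
        if abs(gap - spacing) <= tol * spacing:
            weights[head] += weights[k]
            keep[k] = False
        else:
            head = k
    return ComponentModel(
        means=model.means[keep],
        sigmas=model.sigmas[keep],
        weights=weights[keep] / weights[keep].sum(),
    )


# ---------------------------------------------------------------------------
# Stage 7: abundance estimation
# ---------------------------------------------------------------------------


def estimate_abundance(dataset: MSIDataset, model: ComponentModel) -> AbundanceMatrix:
    """Per-pixel component abundances.

    ``abundance[p, k] = sum_c spectrum_p(mz_c) * Gauss(mz_c; mu_k, sigma_k)
    * dmz`` — the inner product of the spectrum with the unit-area
    component profile, i.e. the component-spectrum convolution evaluated
    at zero lag.
    """
    mz = dataset.mz_axis
    if model.means[0] < mz[0] - 1e-9 or model.means[-1] > mz[-1] + 1e-9:
        raise ValueError("component means fall outside the dataset m/z axis")
    dm = float(np.median(np.diff(mz)))
    profiles = model.profile_matrix(mz)
    values = np.asarray(dataset.spectra @ profiles.T.tocsc()) * dm
    values = np.clip(np.asarray(values, dtype=float), 0.0, None)
    return AbundanceMatrix(values=values, component_ids=np.arange(model.n_components))


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


@dataclass
class PreprocessParams:
    """Tunables of the preprocessing pipeline."""

    baseline_window: int = 201
    max_shift: int = 5
    outlier_n_sigma: float = 3.0
    gmm_q: float = 50.0
    gmm_w_min: float = 1e-5
    gmm_sigma_bounds: tuple[float, float] | None = None
    gmm_max_iter: int = 500
    gmm_tol: float = 1e-8
    merge_envelopes: bool = False


@dataclass
class PreprocessResult:
    dataset: MSIDataset
    model: ComponentModel
    abundances: AbundanceMatrix
    outlier_flags: np.ndarray
    retained_index: np.ndarray  # indices into the concatenated input pixels

    @property
    def provenance(self) -> list:
        return self.dataset.provenance


def preprocess_pipeline(
    datasets: Iterable[MSIDataset], params: PreprocessParams | None = None
) -> PreprocessResult:
    """Run the full preprocessing chain on one or more datasets (pooled)."""
    params = params or PreprocessParams()
    datasets = list(datasets)
    unified = unify_mass_channels(datasets)
    ds = concatenate_datasets(unified) if len(unified) > 1 else unified[0]
    ds = subtract_baseline_dataset(ds, params.baseline_window)
    flags = detect_outlier_pixels(ds, n_sigma=params.outlier_n_sigma)
    retained = np.flatnonzero(~flags)
    ds = ds.subset(~flags)
    ds.provenance.append("detect_outlier_pixels")
    ds = align_peaks(ds, max_shift=params.max_shift)
    ds = tic_normalize(ds)
    avg = average_spectrum(ds)
    model = fit_gmm_components(
        avg,
        ds.mz_axis,
        q=params.gmm_q,
        w_min=params.gmm_w_min,
        sigma_bounds=params.gmm_sigma_bounds,
        max_iter=params.gmm_max_iter,
        tol=params.gmm_tol,
    )
    ds.provenance.append("fit_gmm_components")
    if params.merge_envelopes:
        model = merge_isotope_envelopes(model)
    abundances = estimate_abundance(ds, model)
    ds.provenance.append("estimate_abundance")
    return PreprocessResult(
        dataset=ds,
        model=model,
        abundances=abundances,
        outlier_flags=flags,
        retained_index=retained,
    )
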