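"""Six-class tissue segmentation by an EM-fitted Gaussian intensity mixture.

Posterior probability maps are produced for CSF, GM, WM, deep GM,
cerebellum, and brainstem.  Components are fitted on intensities inside the
brain mask and assigned to tissue classes by sorting component means
against a configurable darkest-to-brightest ordering (CSF darkest, WM
brighter than GM on T1).  No spatial regularization is applied; the fit is
deterministic (quantile initialization, fixed iteration schedule).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

from .volumes import CLASS_NAMES, ImageVolume, Tissue, TissueProbabilitySet

logger = logging.getLogger(__name__)

#: Default darkest-to-brightest class ordering used to name components.
DEFAULT_ORDERING: Tuple[str, ...] = ("CSF", "GM", "DGM", "WM", "CBM", "BST")

_VAR_FLOOR = 1e-6


@dataclasses.dataclass
class MixtureModel:
    """Fitted Gaussian mixture: one component per tissue class."""

    means: np.ndarray  # per class, sorted by the ordering
    variances: np.ndarray
    weights: np.ndarray
    ordering: Tuple[str, ...]
    log_likelihoods: np.ndarray  # per-iteration trace (non-decreasing)

    def __post_init__(self) -> None:
        if (self.variances <= 0).any():
            raise ValueError("variances must be positive")
        if abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("weights must sum to 1")


def _log_gauss(x: np.ndarray, mean: float, var: float) -> np.ndarray:
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mean) ** 2 / var)


def _init_means(x: np.ndarray, k: int) -> np.ndarray:
    """Histogram-mode initialization of component means.

    Tissue classes form well-separated intensity modes but can be wildly
    unbalanced in size (brainstem vs white matter), which defeats quantile
    initialization; local maxima of a smoothed histogram find small modes
    regardless of their mass.  Deterministic.
    """
    from scipy.ndimage import gaussian_filter1d

    lo, hi = np.quantile(x, [0.001, 0.999])
    counts, edges = np.histogram(x, bins=512, range=(lo, hi))
    smooth = gaussian_filter1d(counts.astype(float), 4.0)
    interior = smooth[1:-1]
    is_peak = (interior > smooth[:-2]) & (interior >= smooth[2:])
    peak_idx = np.flatnonzero(is_peak) + 1
    centers = (edges[:-1] + edges[1:]) / 2.0
    if len(peak_idx) > k:  # keep the k tallest
        order = np.argsort(smooth[peak_idx])[::-1][:k]
        peak_idx = np.sort(peak_idx[order])
    means = centers[peak_idx]
    if len(means) < k:  # degenerate histogram: pad with quantiles
        fill = np.quantile(x, (np.arange(k - len(means)) + 0.5) / (k - len(means)))
        means = np.sort(np.concatenate([means, fill]))
    return means


def fit_mixture(
    x: np.ndarray,
    k: int,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """EM fit of a k-component 1D Gaussian mixture.

    Initialization is deterministic: means at smoothed-histogram modes,
    shared variance, equal weights.  Returns (means, variances, weights,
    log-likelihood trace); components are in fitted order (not sorted).
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    n = x.size
    means = _init_means(x, k)
    variances = np.full(k, max(x.var() / max(k * k, 1), _VAR_FLOOR))
    weights = np.full(k, 1.0 / k)
    trace = []
    prev_ll = -np.inf
    for it in range(max_iter):
        log_p = np.stack(
            [
                np.log(weights[j] + 1e-300) + _log_gauss(x, means[j], variances[j])
                for j in range(k)
            ]
        )  # (k, n)
        log_norm = logsumexp(log_p, axis=0)
        ll = float(log_norm.sum())
        trace.append(ll)
        resp = np.exp(log_p - log_norm)  # (k, n)
        nk = resp.sum(axis=1) + 1e-12
        means = (resp @ x) / nk
        variances = np.maximum(
            (resp * (x[None, :] - means[:, None]) ** 2).sum(axis=1) / nk, _VAR_FLOOR
        )
        weights = nk / nk.sum()
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * abs(prev_ll):
            break
        prev_ll = ll
    return means, variances, weights, np.asarray(trace)


def fit_mixture_with_priors(
    x: np.ndarray,
    priors: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-6,
    prior_floor: float = 1e-2,
    fit_subset: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """EM fit with fixed per-voxel spatial class priors.

    ``priors`` is (k, n); each column is floored and renormalized, then the
    E-step responsibility is prior * Gaussian likelihood.  Component-class
    identity comes from the prior, so classes that overlap in intensity
    (deep gray between GM and WM) stay separable.  ``fit_subset`` restricts
    the *parameter estimation* to a boolean subset of voxels (e.g.
    everything outside a resection cavity, where the priors no longer
    describe the tissue) while posteriors are still produced everywhere.
    Returns (means, variances, weights, responsibilities, log-likelihood
    trace).
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    k = priors.shape[0]
    P = np.maximum(np.asarray(priors, dtype=np.float64), prior_floor)
    P /= P.sum(axis=0, keepdims=True)
    logP = np.log(P)
    if fit_subset is None:
        x_fit, logP_fit = x, logP
    else:
        fit_subset = np.asarray(fit_subset, dtype=bool)
        if not fit_subset.any():
            raise ValueError("fit_subset excludes every voxel")
        x_fit, logP_fit = x[fit_subset], logP[:, fit_subset]
    P_fit = np.exp(logP_fit)
    nk0 = P_fit.sum(axis=1)
    means = (P_fit @ x_fit) / nk0
    variances = np.maximum(
        (P_fit * (x_fit[None, :] - means[:, None]) ** 2).sum(axis=1) / nk0,
        _VAR_FLOOR,
    )
    trace = []
    prev_ll = -np.inf
    for it in range(max_iter):
        log_p = logP_fit + np.stack(
            [_log_gauss(x_fit, means[j], variances[j]) for j in range(k)]
        )
        log_norm = logsumexp(log_p, axis=0)
        ll = float(log_norm.sum())
        trace.append(ll)
        resp = np.exp(log_p - log_norm)
        nk = resp.sum(axis=1) + 1e-12
        means = (resp @ x_fit) / nk
        variances = np.maximum(
            (resp * (x_fit[None, :] - means[:, None]) ** 2).sum(axis=1) / nk,
            _VAR_FLOOR,
        )
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * abs(prev_ll):
            break
        prev_ll = ll
    # final E-step over all voxels with the fitted parameters
    log_p = logP + np.stack([_log_gauss(x, means[j], variances[j]) for j in range(k)])
    resp = np.exp(log_p - logsumexp(log_p, axis=0))
    weights = resp.sum(axis=1) / x.size
    return means, variances, weights, resp, np.asarray(trace)


def segment_tissues(
    vol: ImageVolume,
    brain_mask: np.ndarray,
    k: int = 6,
    seed: int = 0,
    ordering: Optional[Sequence[str]] = None,
    priors: Optional[dict] = None,
    exclude_from_fit: Optional[np.ndarray] = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    return_model: bool = False,
):
    """Segment a T1 volume into ``k`` tissue posterior probability maps.

    Without ``priors``, components are fitted from intensity alone and
    named by sorting their means against ``ordering`` (darkest to
    brightest; default the first ``k`` of CSF, GM, DGM, WM, CBM, BST, or
    the classic CSF/GM/WM triple for k = 3).  With ``priors`` (a dict of
    class name -> spatial prior volume, e.g. smoothed template tissue
    maps), classes are identified by their prior and intensity only
    refines them — the only way intensity-overlapping classes can be kept
    apart.  Posteriors sum to 1 inside the mask and are 0 outside.  The
    ``seed`` is accepted for interface uniformity; the fit is
    deterministic.
    """
    brain_mask = np.asarray(brain_mask).astype(bool)
    if brain_mask.shape != vol.shape:
        raise ValueError("brain mask not on the volume grid")
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    if ordering is None:
        if priors is not None:
            ordering = tuple(n for n in CLASS_NAMES if n in priors)
        else:
            ordering = ("CSF", "GM", "WM") if k == 3 else DEFAULT_ORDERING[:k]
    ordering = tuple(ordering)
    k = len(ordering) if priors is not None else k
    if len(ordering) != k:
        raise ValueError(f"ordering must name {k} classes")
    unknown = set(ordering) - set(CLASS_NAMES)
    if unknown:
        raise ValueError(f"unknown classes in ordering: {sorted(unknown)}")

    x = vol.data[brain_mask].astype(np.float64)
    if np.unique(x).size < k:
        raise ValueError(
            f"only {np.unique(x).size} distinct intensity levels for {k} classes"
        )
    if priors is not None:
        missing = set(ordering) - set(priors)
        if missing:
            raise ValueError(f"priors missing for classes: {sorted(missing)}")
        P = np.stack(
            [np.asarray(priors[name], dtype=np.float64)[brain_mask]
             for name in ordering]
        )
        fit_subset = None
        if exclude_from_fit is not None:
            fit_subset = ~np.asarray(exclude_from_fit, dtype=bool)[brain_mask]
        means, variances, weights, resp, trace = fit_mixture_with_priors(
            x, P, max_iter=max_iter, tol=tol, fit_subset=fit_subset
        )
        model = MixtureModel(
            means=means, variances=variances, weights=weights / weights.sum(),
            ordering=ordering, log_likelihoods=trace,
        )
        maps = {}
        for j, name in enumerate(ordering):
            full = np.zeros(vol.shape, dtype=np.float32)
            full[brain_mask] = resp[j]
            maps[name] = full
        probs = TissueProbabilitySet(
            maps=maps, affine=vol.affine, brain_mask=brain_mask
        )
        return (probs, model) if return_model else probs

    x_fit = x
    if exclude_from_fit is not None:
        keep = ~np.asarray(exclude_from_fit, dtype=bool)[brain_mask]
        if not keep.any():
            raise ValueError("exclude_from_fit removes every voxel")
        x_fit = x[keep]
    means, variances, weights, trace = fit_mixture(
        x_fit, k, max_iter=max_iter, tol=tol
    )
    order = np.argsort(means)
    means, variances, weights = means[order], variances[order], weights[order]
    model = MixtureModel(
        means=means,
        variances=variances,
        weights=weights,
        ordering=ordering,
        log_likelihoods=trace,
    )
    log_p = np.stack(
        [
            np.log(weights[j] + 1e-300) + _log_gauss(x, means[j], variances[j])
            for j in range(k)
        ]
    )
    resp = np.exp(log_p - logsumexp(log_p, axis=0))
    maps = {}
    for j, name in enumerate(ordering):
        full = np.zeros(vol.shape, dtype=np.float32)
        full[brain_mask] = resp[j]
        maps[name] = full
    probs = TissueProbabilitySet(maps=maps, affine=vol.affine, brain_mask=brain_mask)
    if return_model:
        return probs, model
    return probs


def posterior_maps(
    vol: ImageVolume,
    brain_mask: np.ndarray,
    model: MixtureModel,
    priors: Optional[dict] = None,
    prior_floor: float = 1e-2,
) -> TissueProbabilitySet:
    """Posterior probability maps for ``vol`` under a fixed fitted model.

    Longitudinal use: fit the mixture once (e.g. on the single-subject
    template) and classify each timepoint with the same parameters, so the
    class boundaries are identical across timepoints and thickness change
    is not biased by per-scan parameter drift.
    """
    brain_mask = np.asarray(brain_mask).astype(bool)
    if brain_mask.shape != vol.shape:
        raise ValueError("brain mask not on the volume grid")
    x = vol.data[brain_mask].astype(np.float64)
    k = len(model.ordering)
    if priors is not None:
        P = np.stack(
            [np.asarray(priors[name], dtype=np.float64)[brain_mask]
             for name in model.ordering]
        )
        P = np.maximum(P, prior_floor)
        P /= P.sum(axis=0, keepdims=True)
        log_w = np.log(P)
    else:
        log_w = np.log(model.weights + 1e-300)[:, None]
    log_p = log_w + np.stack(
        [_log_gauss(x, model.means[j], model.variances[j]) for j in range(k)]
    )
    resp = np.exp(log_p - logsumexp(log_p, axis=0))
    maps = {}
    for j, name in enumerate(model.ordering):
        full = np.zeros(vol.shape, dtype=np.float32)
        full[brain_mask] = resp[j]
        maps[name] = full
    return TissueProbabilitySet(maps=maps, affine=vol.affine, brain_mask=brain_mask)


def classify(probs: TissueProbabilitySet) -> np.ndarray:
    """Per-voxel argmax tissue labels (:class:`Tissue` values, 0 = outside).

    Ties are broken toward the lowest class index (canonical class order).
    """
    stacked = probs.stack()
    idx = stacked.argmax(axis=0)  # first maximum wins -> lowest class index
    label_values = np.array([Tissue[n] for n in probs.classes], dtype=np.int8)
    labels = label_values[idx]
    labels[~probs.brain_mask] = 0
    return labels
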