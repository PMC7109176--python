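"""Three-class Gaussian-mixture lesion segmentation on SUV values.

The segmenter fits a univariate 3-component Gaussian mixture to the voxel
values of a manually cropped SUV region.  Components are labelled by
ascending mean as *background* (lowest uptake), *unknown* (intermediate,
dominated by partial-volume rim voxels) and *tumor* (highest uptake).  To
avoid over-estimation from partial-volume effects, intermediate voxels are
treated as non-tumor: the tumor decision threshold is the SUV value where the
weighted densities of the unknown and tumor components cross, and the tumor
mask is every cropped voxel strictly above that threshold.

Two conventional comparator segmenters are provided: a fixed SUV > 2.5
threshold and an adaptive threshold at 42% of the in-crop maximum SUV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .image import BinaryMask, CropBox, ScalarSlice

__all__ = [
    "DegenerateFitError",
    "MixtureFit",
    "SegmentationResult",
    "kmeanspp_init",
    "fit_gmm",
    "class_assign",
    "tumor_threshold",
    "segment_gmm",
    "segment_fixed",
    "segment_percent_max",
]

CLASS_NAMES = ("background", "unknown", "tumor")

#: variance floor, as a fraction of the data variance, guarding EM collapse
VARIANCE_FLOOR_FRAC = 1e-6


class DegenerateFitError(RuntimeError):
    """Raised when a mixture fit cannot support a tumor/unknown threshold."""


@dataclass(frozen=True)
class MixtureFit:
    """Parameters and diagnostics of a fitted univariate Gaussian mixture.

    Components are stored in ascending-mean order, so index 0 is background,
    1 is unknown and 2 is tumor for the default k = 3.  ``log_likelihood_history``
    records the total log-likelihood at every EM iteration of the winning
    restart (non-decreasing by construction of EM).
    """

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood: float
    n_iter: int
    converged: bool
    log_likelihood_history: tuple[float, ...] = ()
    degenerate_components: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        m = np.asarray(self.means, dtype=float)
        v = np.asarray(self.variances, dtype=float)
        if not (w.shape == m.shape == v.shape) or w.ndim != 1:
            raise ValueError("weights, means, variances must be equal-length 1-D")
        if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        if np.any(v <= 0):
            raise ValueError("variances must be positive")
        if np.any(np.diff(m) < 0):
            raise ValueError("components must be ordered by ascending mean")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "variances", v)

    @property
    def k(self) -> int:
        return len(self.weights)

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "log_likelihood": self.log_likelihood,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "degenerate_components": list(self.degenerate_components),
            "class_names": list(CLASS_NAMES[: self.k]) if self.k == 3 else None,
        }


@dataclass(frozen=True)
class SegmentationResult:
    """Mask plus provenance for one segmentation method on one crop."""

    mask: BinaryMask
    method: str  # gmm_pet | suv_fixed | suv_percent_max
    threshold: float | None
    fit: MixtureFit | None = None
    crop: CropBox | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.method in ("suv_fixed", "suv_percent_max", "gmm_pet"):
            if self.threshold is not None and not math.isfinite(self.threshold):
                raise ValueError("threshold must be finite when present")


# ---------------------------------------------------------------------------
# k-means++ seeding and EM


def kmeanspp_init(values: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Draw ``k`` initial centers from ``values`` by the k-means++ scheme.

    The first center is drawn uniformly from the data; each subsequent one is
    drawn with probability proportional to the squared distance to the nearest
    already-chosen center.  Deterministic given ``seed``.
    """
    values = np.asarray(values, dtype=float).ravel()
    if np.unique(values).size < k:
        raise ValueError(f"need >= {k} distinct values for k-means++ with k={k}")
    rng = np.random.default_rng(seed)
    centers = np.empty(k)
    centers[0] = values[rng.integers(len(values))]
    d2 = (values - centers[0]) ** 2
    for c in range(1, k):
        probs = d2 / d2.sum()
        centers[c] = values[rng.choice(len(values), p=probs)]
        d2 = np.minimum(d2, (values - centers[c]) ** 2)
    return centers


def _log_norm_pdf(x: np.ndarray, mean: np.ndarray, var: np.ndarray) -> np.ndarray:
    """log N(x; mean, var), broadcasting x (n,1) against components (k,)."""
    return -0.5 * (np.log(2 * np.pi * var) + (x - mean) ** 2 / var)


def _em_once(
    values: np.ndarray,
    centers: np.ndarray,
    var_floor: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float], bool]:
    """Run EM from a hard k-means++-style assignment to ``centers``."""
    x = values[:, None]
    # initial hard assignment to the nearest center
    labels = np.argmin((x - centers[None, :]) ** 2, axis=1)
    k = len(centers)
    n = len(values)
    w = np.empty(k)
    mu = np.empty(k)
    var = np.empty(k)
    global_var = max(values.var(), var_floor)
    for c in range(k):
        sel = labels == c
        cnt = sel.sum()
        w[c] = max(cnt, 1) / n
        mu[c] = values[sel].mean() if cnt else centers[c]
        var[c] = max(values[sel].var(), var_floor) if cnt else global_var
    w /= w.sum()

    ll_history: list[float] = []
    converged = False
    log_r = None
    for _ in range(max_iter):
        # E-step
        log_joint = np.log(np.maximum(w, 1e-300)) + _log_norm_pdf(x, mu, var)
        log_norm = np.logaddexp.reduce(log_joint, axis=1)
        ll = float(log_norm.sum())
        log_r = log_joint - log_norm[:, None]
        r = np.exp(log_r)
        # M-step
        nk = r.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        w = nk / n
        mu = (r * x).sum(axis=0) / nk
        var = np.maximum((r * (x - mu) ** 2).sum(axis=0) / nk, var_floor)

        if ll_history and (ll - ll_history[-1]) <= tol * abs(ll_history[-1]):
            ll_history.append(ll)
            converged = True
            break
        ll_history.append(ll)
    return w, mu, var, ll_history, converged


def fit_gmm(
    values: np.ndarray,
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 5,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MixtureFit:
    """Fit a k-component univariate Gaussian mixture by EM.

    Each restart is seeded by k-means++ with a sub-seed derived from ``seed``;
    the restart with the highest final log-likelihood wins.  Components are
    relabelled in ascending order of mean (ties broken by ascending variance),
    matching the background / unknown / tumor intensity semantics.

    Convergence is a relative log-likelihood change below ``tol``; running past
    ``max_iter`` sets ``converged=False`` rather than raising.  A component
    whose variance sits at the floor with weight < 1e-6 is reported in
    ``degenerate_components``.
    """
    values = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if np.unique(values).size < 2 * k:
        raise ValueError(
            f"need >= {2 * k} distinct values to identify a {k}-component mixture"
        )
    var_floor = VARIANCE_FLOOR_FRAC * values.var()
    sub_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                 np.random.SeedSequence(seed).spawn(n_restarts)]

    best: tuple | None = None
    for sub in sub_seeds:
        centers = kmeanspp_init(values, k, sub)
        w, mu, var, ll_hist, conv = _em_once(values, centers, var_floor, tol, max_iter)
        if best is None or ll_hist[-1] > best[3][-1]:
            best = (w, mu, var, ll_hist, conv)
    assert best is not None
    w, mu, var, ll_hist, conv = best

    order = np.lexsort((var, mu))  # ascending mean, ties by variance
    w, mu, var = w[order], mu[order], var[order]
    degenerate = tuple(
        int(c) for c in range(k) if var[c] <= var_floor * (1 + 1e-9) and w[c] < 1e-6
    )
    return MixtureFit(
        weights=w / w.sum(),
        means=mu,
        variances=var,
        log_likelihood=ll_hist[-1],
        n_iter=len(ll_hist),
        converged=conv,
        log_likelihood_history=tuple(ll_hist),
        degenerate_components=degenerate,
    )


def class_assign(fit: MixtureFit, values: np.ndarray) -> np.ndarray:
    """Maximum-posterior class index per value; ties go to the lower-mean class.

    For k = 3 the indices map to ``CLASS_NAMES`` = (background, unknown, tumor).
    """
    x = np.asarray(values, dtype=float).ravel()[:, None]
    log_joint = np.log(np.maximum(fit.weights, 1e-300)) + _log_norm_pdf(
        x, fit.means, fit.variances
    )
    # argmax returns the first (lowest-mean, given ascending order) maximizer
    return np.argmax(log_joint, axis=1)


# ---------------------------------------------------------------------------
# tumor threshold from the unknown/tumor density crossing


def tumor_threshold(fit: MixtureFit) -> tuple[float, tuple[str, ...]]:
    """SUV value where the weighted unknown and tumor densities intersect.

    Solves ``w_u N(x; mu_u, s_u^2) = w_t N(x; mu_t, s_t^2)`` as a quadratic in
    ``x`` (linear when variances are equal) and returns the smallest root in
    the open interval ``(mu_u, mu_t)``.  The background component plays no
    role in the crossing.  If no root lies between the means — possible with
    extreme weight or variance ratios — the midpoint is returned with a
    ``"midpoint_fallback"`` flag.

    Raises :class:`DegenerateFitError` when ``mu_u >= mu_t``.
    """
    if fit.k < 2:
        raise DegenerateFitError("threshold requires at least two components")
    w_u, w_t = fit.weights[-2], fit.weights[-1]
    mu_u, mu_t = fit.means[-2], fit.means[-1]
    v_u, v_t = fit.variances[-2], fit.variances[-1]
    if not mu_u < mu_t:
        raise DegenerateFitError(
            f"unknown mean ({mu_u}) must lie strictly below tumor mean ({mu_t})"
        )
    midpoint = 0.5 * (mu_u + mu_t)
    if w_u <= 0 or w_t <= 0:
        return midpoint, ("midpoint_fallback",)

    # equate log weighted densities: A x^2 + B x + C = 0
    a = 0.5 / v_t - 0.5 / v_u
    b = mu_u / v_u - mu_t / v_t
    c = (
        0.5 * mu_t**2 / v_t
        - 0.5 * mu_u**2 / v_u
        + math.log(w_u / w_t)
        + 0.5 * math.log(v_t / v_u)
    )
    roots: list[float] = []
    if abs(a) < 1e-300 * max(1.0, abs(b)):
        if b != 0:
            roots = [-c / b]
    else:
        disc = b * b - 4 * a * c
        if disc >= 0:
            sq = math.sqrt(disc)
            roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    in_between = sorted(r for r in roots if mu_u < r < mu_t)
    if in_between:
        return float(in_between[0]), ()
    return midpoint, ("midpoint_fallback",)


# ---------------------------------------------------------------------------
# segmenters


def _embed(
    crop_mask: np.ndarray, cropped: ScalarSlice, full_shape: tuple[int, int] | None,
    box: CropBox | None,
) -> BinaryMask:
    """Place a crop-local mask into full-grid coordinates when a box is given."""
    if box is None or full_shape is None:
        return BinaryMask(mask=crop_mask, spacing=cropped.spacing, origin=cropped.origin)
    full = np.zeros(full_shape, dtype=bool)
    full[box.slices()] = crop_mask
    origin = (
        cropped.origin[0] - box.row_min * cropped.spacing[0],
        cropped.origin[1] - box.col_min * cropped.spacing[1],
    )
    return BinaryMask(mask=full, spacing=cropped.spacing, origin=origin)


def segment_gmm(
    cropped_suv: ScalarSlice,
    seed: int = 0,
    n_restarts: int = 5,
    tol: float = 1e-6,
    max_iter: int = 500,
    full_shape: tuple[int, int] | None = None,
    box: CropBox | None = None,
) -> SegmentationResult:
    """GMM–PET segmentation of a cropped SUV region.

    Fits the 3-component mixture to all cropped voxel values, derives the
    unknown/tumor intersection threshold, and returns the mask of voxels with
    SUV strictly above it.  Voxels in the intermediate (unknown) class below
    the threshold are considered non-tumor, guarding against partial-volume
    over-estimation.  Pass ``full_shape`` and ``box`` to embed the mask back
    into the uncropped grid.
    """
    fit = fit_gmm(
        cropped_suv.values.ravel(),
        k=3,
        seed=seed,
        n_restarts=n_restarts,
        tol=tol,
        max_iter=max_iter,
    )
    thr, flags = tumor_threshold(fit)
    crop_mask = cropped_suv.values > thr
    if not fit.converged:
        flags = flags + ("em_not_converged",)
    if fit.degenerate_components:
        flags = flags + ("degenerate_component",)
    # heuristic: a crop with no real lesion fits three heavily overlapping
    # components; flag when tumor/unknown separation is under 2 pooled sd
    sep = (fit.means[2] - fit.means[1]) / math.sqrt(
        0.5 * (fit.variances[2] + fit.variances[1])
    )
    if sep < 2.0:
        flags = flags + ("low_separation",)
    return SegmentationResult(
        mask=_embed(crop_mask, cropped_suv, full_shape, box),
        method="gmm_pet",
        threshold=thr,
        fit=fit,
        crop=box,
        flags=flags,
    )


def segment_fixed(
    cropped_suv: ScalarSlice,
    t: float = 2.5,
    full_shape: tuple[int, int] | None = None,
    box: CropBox | None = None,
) -> SegmentationResult:
    """Fixed-threshold comparator: mask = {SUV > t} (strictly), may be empty."""
    crop_mask = cropped_suv.values > t
    flags = ("empty_mask",) if not crop_mask.any() else ()
    return SegmentationResult(
        mask=_embed(crop_mask, cropped_suv, full_shape, box),
        method="suv_fixed",
        threshold=float(t),
        crop=box,
        flags=flags,
    )


def segment_percent_max(
    cropped_suv: ScalarSlice,
    frac: float = 0.42,
    full_shape: tuple[int, int] | None = None,
    box: CropBox | None = None,
) -> SegmentationResult:
    """Percent-of-maximum comparator: threshold = frac * max(SUV), mask = {SUV >= threshold}.

    Inclusive, so the maximum voxel always survives and the mask is never
    empty.  Invariant to positive rescaling of the SUV map.
    """
    if cropped_suv.values.size == 0:
        raise ValueError("empty crop")
    thr = float(frac * cropped_suv.values.max())
    crop_mask = cropped_suv.values >= thr
    return SegmentationResult(
        mask=_embed(crop_mask, cropped_suv, full_shape, box),
        method="suv_percent_max",
        threshold=thr,
        crop=box,
        flags=(),
    )
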