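"""Digital lesion phantoms: co-registered SUV, DWI, truth and reference masks.

Each phantom emulates a single central breast-lesion slice as acquired by a
simultaneous PET/MRI protocol on a 2 x 2 mm in-plane grid: a perturbed-ellipse
tumor with heterogeneous FDG uptake well above a low soft-tissue background, a
partial-volume rim where uptake blends linearly into background (standing in
for the ~4 mm reconstruction point-spread), multi-b diffusion-weighted signal
with reduced diffusivity inside the tumor and Rician magnitude noise, and a
reference mask that proxies a manually drawn contrast-enhanced (DCE) ROI by
jittering and offsetting the true boundary.

A scalar *treatment effect* f in [0, 1] moves the phantom along the response
trajectory: tumor uptake (mean and heterogeneity) shrinks toward background as
(1 - f) and tumor diffusivity rises toward the background ADC, so that at
large f the lesion's maximum SUV can fall below the fixed 2.5 threshold, the
regime where fixed-threshold segmentation finds no tumor at all.

Noise models: Gaussian additive noise on the SUV map, Rician noise on DWI
magnitudes.  Uptake heterogeneity is a smoothed Gaussian random field with a
configurable correlation length.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import BinaryMask, CropBox, DWIStack, ScalarSlice

__all__ = ["PhantomSpec", "PhantomCase", "make_phantom", "simulate_cohort"]

DEFAULT_BVALUES = (0.0, 50.0, 120.0, 200.0, 400.0, 700.0)


@dataclass(frozen=True)
class PhantomSpec:
    """All knobs of one synthetic lesion slice.  Lengths in mm, ADC in mm^2/s."""

    shape: tuple[int, int] = (96, 96)
    spacing: tuple[float, float] = (2.0, 2.0)
    center_mm: tuple[float, float] | None = None  # None -> grid center
    semi_axes_mm: tuple[float, float] = (14.0, 10.0)
    lobularity: float = 0.15  # relative radial boundary perturbation amplitude

    background_suv: float = 1.0
    background_suv_sd: float = 0.15
    tumor_suv: float = 8.0
    #: within-lesion uptake heterogeneity, as sd relative to the
    #: tumor-background contrast (a contrast-referenced CV); shrinks with the
    #: contrast itself under treatment
    tumor_heterogeneity: float = 0.15
    correlation_length_mm: float = 6.0
    rim_width_mm: float = 4.0

    adc_tumor: float = 1.0e-3
    adc_background: float = 1.8e-3
    s0: float = 1000.0
    rician_sigma: float = 20.0
    perfusion_fraction: float = 0.0  # IVIM-like fast component, off by default
    pseudo_diffusion: float = 10.0e-3
    bvalues: tuple[float, ...] = DEFAULT_BVALUES

    treatment_effect: float = 0.0  # f: 0 = untreated, 1 = full response
    dce_jitter_sd_mm: float = 1.0
    dce_offset_mm: float = 0.5
    crop_margin_voxels: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        f = self.treatment_effect
        if not 0.0 <= f <= 1.0:
            raise ValueError("treatment_effect must lie in [0, 1]")
        if f < 1.0 and self.tumor_suv <= self.background_suv:
            raise ValueError("tumor SUV mean must exceed background for f < 1")
        if self.adc_tumor >= self.adc_background:
            raise ValueError("tumor ADC must be below background ADC")
        for name in ("background_suv_sd", "tumor_heterogeneity", "rician_sigma",
                     "dce_jitter_sd_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.perfusion_fraction < 1.0:
            raise ValueError("perfusion_fraction must lie in [0, 1)")

    @property
    def tumor_suv_effective(self) -> float:
        """Tumor uptake mean after treatment scaling toward background."""
        f = self.treatment_effect
        return self.background_suv + (self.tumor_suv - self.background_suv) * (1 - f)

    @property
    def adc_tumor_effective(self) -> float:
        f = self.treatment_effect
        return self.adc_tumor + f * (self.adc_background - self.adc_tumor)


@dataclass(frozen=True)
class PhantomCase:
    """One simulated lesion: maps, masks, crop box and the generating spec."""

    suv: ScalarSlice
    dwi: DWIStack | None
    truth: BinaryMask
    reference: BinaryMask
    crop: CropBox
    adc_map: np.ndarray  # noise-free generating ADC field, mm^2/s
    spec: PhantomSpec

    def content_hash(self) -> str:
        """SHA-256 over all array content; used for determinism checks."""
        h = hashlib.sha256()
        h.update(self.suv.values.tobytes())
        if self.dwi is not None:
            for s in self.dwi.signals:
                h.update(s.tobytes())
        h.update(self.truth.mask.tobytes())
        h.update(self.reference.mask.tobytes())
        h.update(np.asarray(
            [self.crop.row_min, self.crop.row_max, self.crop.col_min,
             self.crop.col_max]).tobytes())
        return h.hexdigest()


def _smooth_unit_field(
    rng: np.random.Generator,
    shape: tuple[int, int],
    spacing: tuple[float, float],
    corr_mm: float,
) -> np.ndarray:
    """Zero-mean, unit-sd Gaussian random field with the given correlation length."""
    raw = rng.standard_normal(shape)
    sigma_vox = (corr_mm / spacing[0], corr_mm / spacing[1])
    sm = ndimage.gaussian_filter(raw, sigma_vox, mode="reflect")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def _signed_distance_mm(mask: np.ndarray, spacing: tuple[float, float]) -> np.ndarray:
    """Signed Euclidean distance to the mask boundary: negative inside."""
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    return outside - inside


def make_phantom(spec: PhantomSpec, with_dwi: bool = True) -> PhantomCase:
    """Generate one phantom case, deterministic given ``spec.seed``.

    ``with_dwi=False`` skips DWI synthesis (the SUV map, masks and ADC field
    are unaffected), for workflows that only exercise the segmenters.
    """
    nrow, ncol = spec.shape
    sp = spec.spacing
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(spec.seed).spawn(5)]
    rng_geom, rng_het, rng_suv, rng_dwi, rng_dce = streams

    # --- tumor geometry: perturbed ellipse ---------------------------------
    if spec.center_mm is None:
        center = ((nrow - 1) * sp[0] / 2.0, (ncol - 1) * sp[1] / 2.0)
    else:
        center = spec.center_mm
    a_mm, b_mm = spec.semi_axes_mm
    ii, jj = np.meshgrid(np.arange(nrow), np.arange(ncol), indexing="ij")
    dx = ii * sp[0] - center[0]
    dy = jj * sp[1] - center[1]
    rho = np.sqrt((dx / a_mm) ** 2 + (dy / b_mm) ** 2)
    theta = np.arctan2(dy, dx)
    # low-order harmonic boundary perturbation (lobular outline)
    harmonics = (2, 3, 4, 5)
    coefs = rng_geom.standard_normal((len(harmonics), 2)) / np.sqrt(len(harmonics))
    eta = np.zeros_like(theta)
    for (c_m, s_m), m in zip(coefs, harmonics):
        eta += c_m * np.cos(m * theta) + s_m * np.sin(m * theta)
    boundary = 1.0 + spec.lobularity * eta
    truth_arr = rho <= boundary

    if not truth_arr.any():
        raise ValueError("tumor geometry produced an empty lesion")
    edge = (truth_arr[0, :].any() or truth_arr[-1, :].any()
            or truth_arr[:, 0].any() or truth_arr[:, -1].any())
    if edge:
        raise ValueError("tumor extends outside the grid")

    # --- SUV field ----------------------------------------------------------
    f = spec.treatment_effect
    dist_out = ndimage.distance_transform_edt(~truth_arr, sampling=sp)
    if spec.rim_width_mm > 0:
        alpha = np.clip(1.0 - dist_out / spec.rim_width_mm, 0.0, 1.0)
    else:
        alpha = truth_arr.astype(float)
    het = _smooth_unit_field(rng_het, spec.shape, sp, spec.correlation_length_mm)
    contrast = spec.tumor_suv_effective - spec.background_suv
    tumor_field = spec.tumor_suv_effective + spec.tumor_heterogeneity * contrast * het
    suv_arr = spec.background_suv + alpha * (tumor_field - spec.background_suv)
    if spec.background_suv_sd > 0:
        suv_arr = suv_arr + rng_suv.normal(0.0, spec.background_suv_sd, spec.shape)
    suv_arr = np.maximum(suv_arr, 0.0)

    # --- ADC field and DWI signals -----------------------------------------
    adc_map = np.where(truth_arr, spec.adc_tumor_effective, spec.adc_background)
    dwi = None
    if with_dwi:
        pf = spec.perfusion_fraction
        signals = []
        for b in spec.bvalues:
            s = spec.s0 * (
                (1 - pf) * np.exp(-b * adc_map) + pf * np.exp(-b * spec.pseudo_diffusion)
            )
            if spec.rician_sigma > 0:
                n1 = rng_dwi.normal(0.0, spec.rician_sigma, spec.shape)
                n2 = rng_dwi.normal(0.0, spec.rician_sigma, spec.shape)
                s = np.sqrt((s + n1) ** 2 + n2**2)
            signals.append(s)
        dwi = DWIStack(signals=tuple(signals), bvalues=spec.bvalues, spacing=sp)

    # --- DCE-proxy reference mask ------------------------------------------
    d = _signed_distance_mm(truth_arr, sp)
    if spec.dce_offset_mm > 0:
        phi = rng_dce.uniform(0.0, 2 * np.pi)
        shift_vox = (
            spec.dce_offset_mm * np.cos(phi) / sp[0],
            spec.dce_offset_mm * np.sin(phi) / sp[1],
        )
        d = ndimage.shift(d, shift_vox, order=1, mode="nearest")
    jitter = _smooth_unit_field(rng_dce, spec.shape, sp, spec.correlation_length_mm)
    reference_arr = d <= spec.dce_jitter_sd_mm * jitter
    if not reference_arr.any():
        reference_arr = truth_arr.copy()  # proxy collapsed; fall back to truth

    # --- crop box around lesion + reference --------------------------------
    union = truth_arr | reference_arr
    rows = np.where(union.any(axis=1))[0]
    cols = np.where(union.any(axis=0))[0]
    m = spec.crop_margin_voxels
    box = CropBox(
        row_min=max(int(rows[0]) - m, 0),
        row_max=min(int(rows[-1]) + 1 + m, nrow),
        col_min=max(int(cols[0]) - m, 0),
        col_max=min(int(cols[-1]) + 1 + m, ncol),
    )

    return PhantomCase(
        suv=ScalarSlice(values=suv_arr, spacing=sp),
        dwi=dwi,
        truth=BinaryMask(mask=truth_arr, spacing=sp),
        reference=BinaryMask(mask=reference_arr, spacing=sp),
        crop=box,
        adc_map=adc_map,
        spec=spec,
    )


def simulate_cohort(
    n_untreated: int,
    n_treated: int,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    f_range: tuple[float, float] = (0.3, 0.9),
    with_dwi: bool = True,
) -> tuple[list[PhantomCase], pd.DataFrame]:
    """Simulate a cohort of untreated and treated lesion phantoms.

    Per-case geometry and uptake are jittered around ``base_spec`` with
    reproducible sub-seeds; treated cases draw the treatment effect f
    uniformly from ``f_range``.  Returns the cases plus a manifest recording
    every drawn parameter.
    """
    if n_untreated < 1 or n_treated < 1:
        raise ValueError("need at least one case per group")
    base = base_spec if base_spec is not None else PhantomSpec()
    n_total = n_untreated + n_treated
    sub = np.random.SeedSequence(seed).spawn(n_total)
    cases: list[PhantomCase] = []
    rows: list[dict] = []
    for i in range(n_total):
        group = "untreated" if i < n_untreated else "treated"
        rng = np.random.default_rng(sub[i])
        case_seed = int(sub[i].generate_state(1)[0] % (2**31))
        a_mm = rng.uniform(10.0, 20.0)
        b_mm = rng.uniform(8.0, 16.0)
        lob = rng.uniform(0.05, 0.25)
        tum_suv = rng.uniform(5.0, 10.0)
        het = rng.uniform(0.5, 1.5) * base.tumor_heterogeneity
        dc = rng.uniform(-4.0, 4.0, size=2)
        nrow, ncol = base.shape
        center = (
            (nrow - 1) * base.spacing[0] / 2.0 + dc[0],
            (ncol - 1) * base.spacing[1] / 2.0 + dc[1],
        )
        f = 0.0 if group == "untreated" else float(rng.uniform(*f_range))
        spec = replace(
            base,
            center_mm=center,
            semi_axes_mm=(a_mm, b_mm),
            lobularity=lob,
            tumor_suv=tum_suv,
            tumor_heterogeneity=het,
            treatment_effect=f,
            seed=case_seed,
        )
        cases.append(make_phantom(spec, with_dwi=with_dwi))
        rows.append(
            {
                "case_id": f"case{i:03d}",
                "group": group,
                "seed": case_seed,
                "semi_axis_a_mm": a_mm,
                "semi_axis_b_mm": b_mm,
                "lobularity": lob,
                "tumor_suv": tum_suv,
                "tumor_heterogeneity": het,
                "center_row_mm": center[0],
                "center_col_mm": center[1],
                "treatment_effect": f,
                "dce_jitter_sd_mm": base.dce_jitter_sd_mm,
                "dce_offset_mm": base.dce_offset_mm,
            }
        )
    return cases, pd.DataFrame(rows)
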