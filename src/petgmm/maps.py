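"""Quantitative map computation: SUV normalization and ADC fitting.

SUV follows the body-weight convention: tracer concentration divided by
injected dose per gram of body weight, which for concentration in kBq/mL,
weight in kg and dose in MBq reduces to ``SUV = C * weight / dose``.  Decay
correction to injection time is assumed to have been applied upstream by the
scanner reconstruction.

ADC maps come from an ordinary least-squares fit of ``ln S_b`` against ``b``
under the mono-exponential signal model ``S_b = S_0 * exp(-b * ADC)``.  By
default only b >= 200 s/mm^2 contributes, which suppresses the fast
pseudo-diffusion (perfusion) component that contaminates low-b signal; the
resulting map is "perfusion-insensitive".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import DWIStack, ScalarSlice

__all__ = ["SUVParams", "ADCFitResult", "compute_suv", "fit_adc"]

#: concentration unit tags accepted by :class:`SUVParams`
_UNIT_SCALE = {"kBq/mL": 1.0, "Bq/mL": 1e-3}


@dataclass(frozen=True)
class SUVParams:
    """Injected dose (MBq), body weight (kg) and input concentration units."""

    injected_dose: float
    body_weight: float
    units_in: str = "kBq/mL"

    def __post_init__(self) -> None:
        if self.injected_dose <= 0:
            raise ValueError("injected dose must be positive")
        if self.body_weight <= 0:
            raise ValueError("body weight must be positive")
        if self.units_in not in _UNIT_SCALE:
            raise ValueError(
                f"units_in must be one of {sorted(_UNIT_SCALE)}, got {self.units_in!r}"
            )


@dataclass(frozen=True)
class ADCFitResult:
    """Per-voxel ADC map (mm^2/s), extrapolated S0 map and validity flags.

    ``valid`` is False wherever the log-linear fit is ill-posed (a
    non-positive signal at any used b-value); ``adc`` and ``s0`` are NaN
    there.
    """

    adc: np.ndarray
    s0: np.ndarray
    valid: np.ndarray
    bvalues_used: tuple[float, ...]
    spacing: tuple[float, float]
    origin: tuple[float, float]

    def adc_slice(self) -> ScalarSlice:
        """ADC as a ScalarSlice (NaN on invalid voxels)."""
        return ScalarSlice(values=self.adc, spacing=self.spacing, origin=self.origin)


def compute_suv(activity: ScalarSlice, params: SUVParams) -> ScalarSlice:
    """Normalize an activity-concentration map to SUV by body weight and dose.

    ``SUV(v) = C(v) [kBq/mL] * body_weight [kg] / injected_dose [MBq]``,
    dimensionless under the g/mL convention.
    """
    conc = activity.values * _UNIT_SCALE[params.units_in]
    if np.any(conc[np.isfinite(conc)] < 0):
        raise ValueError("activity concentration must be non-negative")
    suv = conc * params.body_weight / params.injected_dose
    return ScalarSlice(values=suv, spacing=activity.spacing, origin=activity.origin)


def fit_adc(
    stack: DWIStack,
    b_min: float = 200.0,
    clamp_negative: bool = False,
) -> ADCFitResult:
    """Fit a mono-exponential decay per voxel over b-values >= ``b_min``.

    Ordinary least squares of ``ln S_b`` against ``b``; ``adc = -slope`` and
    ``s0 = exp(intercept)``.  Voxels with any non-positive signal among the
    used b-values are flagged invalid (the log transform is undefined there)
    rather than imputed.  Negative fitted ADC values are retained by default;
    ``clamp_negative=True`` clamps them to zero (the ``valid`` flag is
    unaffected either way).

    Raises ``ValueError`` if fewer than two b-values satisfy the restriction.
    """
    bvals = np.asarray(stack.bvalues, dtype=float)
    use = bvals >= b_min
    if use.sum() < 2:
        raise ValueError(
            f"need >= 2 b-values >= {b_min} s/mm^2, have {int(use.sum())}"
        )
    b = bvals[use]
    sig = stack.as_array()[use]  # (n_b, rows, cols)

    valid = np.all(sig > 0, axis=0) & np.all(np.isfinite(sig), axis=0)
    log_s = np.where(sig > 0, np.log(np.where(sig > 0, sig, 1.0)), 0.0)

    # closed-form simple linear regression, vectorized over voxels
    b_mean = b.mean()
    b_var = np.sum((b - b_mean) ** 2)
    y_mean = log_s.mean(axis=0)
    slope = np.tensordot(b - b_mean, log_s - y_mean, axes=(0, 0)) / b_var
    intercept = y_mean - slope * b_mean

    adc = -slope
    s0 = np.exp(intercept)
    if clamp_negative:
        adc = np.maximum(adc, 0.0)
    adc = np.where(valid, adc, np.nan)
    s0 = np.where(valid, s0, np.nan)
    return ADCFitResult(
        adc=adc,
        s0=s0,
        valid=valid,
        bvalues_used=tuple(b),
        spacing=stack.spacing,
        origin=stack.origin,
    )
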