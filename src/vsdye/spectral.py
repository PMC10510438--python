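"""Energy-gap spectral mapping.

Converts ensembles of excited-minus-ground force-field energy gaps into peak
absorption/emission wavelengths via lambda = hc / (<dE> - offset), where the
voltage-independent empirical offset absorbs nonradiative vibrational and
reorganization contributions. Also provides Stokes shifts, windowed linear
voltage-response fits, and the full-range average shift per 100 mV.

The gap is averaged over the trajectory first and then inverted (the shift of
the mean, not the mean of the shifts); uncertainties come from block-average
standard errors propagated to wavelength by the first-order delta method,
SE(lambda) = lambda^2 * SE(<dE>) / hc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import HC_KCAL_NM_PER_MOL, VoltageCondition
from .observables import block_average


@dataclass
class EnergyGapSeries:
    """Per-frame excited-minus-ground total-energy differences, kcal/mol.

    Computed on configurations sampled from the trajectory of ``cond.state``:
    a ground-state trajectory yields absorption gaps, an excited-state
    trajectory emission gaps (vertical transitions on fixed nuclei).
    """

    cond: VoltageCondition
    frames: np.ndarray
    values: np.ndarray  # kcal/mol

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.frames.shape != self.values.shape:
            raise ValueError("frames and values must have the same length")
        if self.values.size == 0:
            raise ValueError("energy-gap series has no frames")
        if len(self.frames) > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("frame indices must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("energy-gap series contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class OffsetConstants:
    """Voltage-independent empirical offsets, kcal/mol.

    ``c_ab`` is subtracted from absorption gaps, ``c_em`` from emission gaps;
    both are calibrated once against a reference spectrum and held fixed
    across voltages.
    """

    c_ab: float
    c_em: float


@dataclass
class SpectralResult:
    """One voltage's spectral observables (wavelengths in nm)."""

    v_mp: float
    lambda_ab: float
    lambda_ab_se: float
    lambda_em: float
    lambda_em_se: float

    @property
    def stokes(self) -> float:
        return self.lambda_em - self.lambda_ab


def wavelength_from_gaps(
    series: EnergyGapSeries, offset: float, n_blocks: int = 10
) -> tuple[float, float]:
    """Peak wavelength (nm) and block-average SE from an energy-gap ensemble.

    lambda = hc / (<dE> - offset); requires the offset-corrected mean gap to
    be positive.
    """
    mean, se_gap = block_average(series.values, n_blocks=n_blocks)
    energy = mean - offset
    if energy <= 0:
        raise ValueError(
            f"offset {offset} kcal/mol leaves non-positive transition energy "
            f"({energy:.4f} kcal/mol) for mean gap {mean:.4f}"
        )
    lam = HC_KCAL_NM_PER_MOL / energy
    se = lam * lam * se_gap / HC_KCAL_NM_PER_MOL
    return float(lam), float(se)


def offset_from_reference(series: EnergyGapSeries, lambda_ref: float) -> float:
    """Calibrate the empirical offset so the series maps to ``lambda_ref``.

    offset = <dE> - hc/lambda_ref; round-trips exactly with
    :func:`wavelength_from_gaps`.
    """
    if lambda_ref <= 0:
        raise ValueError("reference wavelength must be positive")
    return float(series.values.mean() - HC_KCAL_NM_PER_MOL / lambda_ref)


def stokes_shift(lambda_ab: float, lambda_em: float) -> float:
    """Stokes shift, nm: emission minus absorption peak wavelength."""
    if lambda_ab <= 0 or lambda_em <= 0:
        raise ValueError("wavelengths must be positive")
    return lambda_em - lambda_ab


def fit_voltage_response(
    points, voltage_window: tuple[float, float] = (-100.0, 100.0)
) -> tuple[float, float]:
    """Ordinary least-squares (slope nm/mV, intercept nm) on windowed points.

    ``points`` is an iterable of (v_mp mV, wavelength nm); only points with
    voltage inside the closed window enter the fit. Large applied voltages sit
    outside the dye's linear-response range, so the headline fit defaults to
    the +/-100 mV window.
    """
    lo, hi = voltage_window
    pts = [(v, lam) for v, lam in points if lo <= v <= hi]
    if len(pts) < 2:
        raise ValueError(
            f"need >= 2 points inside window [{lo}, {hi}] mV, got {len(pts)}"
        )
    v = np.array([p[0] for p in pts], float)
    lam = np.array([p[1] for p in pts], float)
    slope, intercept = np.polyfit(v, lam, 1)
    return float(slope), float(intercept)


def average_shift_per_100mV(points) -> float:
    """Endpoint-average wavelength change per 100 mV over the full range.

    |lambda(min V) - lambda(max V)| / (voltage span / 100).
    """
    pts = sorted(points, key=lambda p: p[0])
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    (v_lo, lam_lo), (v_hi, lam_hi) = pts[0], pts[-1]
    span = v_hi - v_lo
    if span == 0:
        raise ValueError("all voltages identical")
    return abs(lam_lo - lam_hi) / (span / 100.0)
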