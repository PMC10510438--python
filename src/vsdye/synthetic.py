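"""Synthetic surrogate trajectories with prescribed stationary statistics.

Microsecond-scale membrane MD is far outside desk scale, so every downstream
stage of the pipeline is exercised on surrogate per-frame data instead: the
generators here emit energy-gap series, atom z-tracks, chromophore-axis
orientations and paired electrostatic grids whose stationary means, SDs and
lag-1 autocorrelations are prescribed, not estimated.

All scalar series are stationary Gaussian AR(1) processes

    x_t = mu + rho * (x_{t-1} - mu) + sqrt(1 - rho^2) * sigma * eps_t

initialized from the stationary distribution, so the mean is mu, the
stationary SD is sigma and the lag-1 autocorrelation is rho for every t.
Tilt angles use the same AR(1) driver mapped through a Gaussian copula onto
a normal marginal truncated to [0, 180] degrees. Fixed seeds give
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .core import VoltageCondition
from .observables import ATOM_LABELS, AtomTrack, OrientationSeries
from .potential import PotentialFractionProfile, PotentialGrid, interpolate_f
from .spectral import EnergyGapSeries


@dataclass(frozen=True)
class GapGenSpec:
    """Generative parameters for an energy-gap series.

    The stationary mean is ``mu0 + kappa * v_mp`` (kcal/mol), with ``kappa``
    the linear voltage sensitivity in kcal/mol per mV; ``sigma`` is the
    stationary SD and ``rho`` the lag-1 autocorrelation.
    """

    mu0: float
    kappa: float = 0.0
    sigma: float = 2.0
    rho: float = 0.9

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")


@dataclass(frozen=True)
class TrackGenSpec:
    """Per-atom-label (mean z, SD) pairs in Angstrom, plus shared rho."""

    stats: dict[str, tuple[float, float]]
    rho: float = 0.9

    def __post_init__(self) -> None:
        for label, (_, sd) in self.stats.items():
            if label not in ATOM_LABELS:
                raise ValueError(
                    f"unknown atom label {label!r}; expected one of {ATOM_LABELS}"
                )
            if sd < 0:
                raise ValueError(f"SD for {label!r} must be non-negative")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")


@dataclass(frozen=True)
class OrientationGenSpec:
    """Mean and SD of the tilt angle (degrees), plus lag-1 autocorrelation."""

    tilt_mean: float
    tilt_sd: float
    rho: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.tilt_mean <= 180.0:
            raise ValueError("tilt_mean must lie in [0, 180] degrees")
        if self.tilt_sd < 0:
            raise ValueError("tilt_sd must be non-negative")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")


def _ar1_standard(rho: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Stationary standard-normal AR(1) deviates (mean 0, SD 1, lag-1 rho)."""
    z = rng.standard_normal(n)
    if n == 1 or rho == 0.0:
        return z
    w = np.empty(n)
    w[0] = z[0]                                # stationary start
    w[1:] = math.sqrt(1.0 - rho * rho) * z[1:]
    return signal.lfilter([1.0], [1.0, -rho], w)


def _ar1(mean: float, sigma: float, rho: float, n: int,
         rng: np.random.Generator) -> np.ndarray:
    if sigma == 0.0:
        rng.standard_normal(n)  # keep the stream layout seed-stable
        return np.full(n, mean)
    return mean + sigma * _ar1_standard(rho, n, rng)


def generate_energy_gap_series(
    spec: GapGenSpec, cond: VoltageCondition, n_frames: int, seed: int
) -> EnergyGapSeries:
    """Stationary AR(1) energy-gap series for one voltage condition."""
    if n_frames < 1:
        raise ValueError("n_frames must be at least 1")
    rng = np.random.default_rng(seed)
    mean = spec.mu0 + spec.kappa * cond.v_mp
    values = _ar1(mean, spec.sigma, spec.rho, n_frames, rng)
    return EnergyGapSeries(cond=cond, frames=np.arange(n_frames), values=values)


def generate_atom_tracks(
    spec: TrackGenSpec, cond: VoltageCondition, n_frames: int, seed: int
) -> dict[str, AtomTrack]:
    """One stationary AR(1) z-track per labeled atom, keyed by label.

    Labels are generated in the fixed order of ``ATOM_LABELS`` from a single
    seeded stream, so output is reproducible regardless of dict order in
    ``spec.stats``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be at least 1")
    unknown = set(spec.stats) - set(ATOM_LABELS)
    if unknown:
        raise ValueError(f"unknown atom labels {sorted(unknown)!r}")
    rng = np.random.default_rng(seed)
    frames = np.arange(n_frames)
    tracks: dict[str, AtomTrack] = {}
    for label in ATOM_LABELS:
        if label not in spec.stats:
            continue
        mean, sd = spec.stats[label]
        z = _ar1(mean, sd, spec.rho, n_frames, rng)
        tracks[label] = AtomTrack(label=label, frames=frames, z=z)
    return tracks


def generate_orientation_series(
    spec: OrientationGenSpec, n_frames: int, seed: int
) -> OrientationSeries:
    """Unit N1->N2 axis vectors with prescribed tilt statistics.

    The tilt angle series is an AR(1) Gaussian process pushed through a
    Gaussian copula onto a normal(mean, SD) marginal truncated to [0, 180]
    degrees; the azimuth about the membrane normal is independent and
    uniform. With SD = 0 every vector lies exactly at the prescribed tilt.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be at least 1")
    rng = np.random.default_rng(seed)
    if spec.tilt_sd == 0.0:
        theta = np.full(n_frames, spec.tilt_mean)
        rng.standard_normal(n_frames)
    else:
        w = _ar1_standard(spec.rho, n_frames, rng)
        a = (0.0 - spec.tilt_mean) / spec.tilt_sd
        b = (180.0 - spec.tilt_mean) / spec.tilt_sd
        u = stats.norm.cdf(w)
        # clip away exact 0/1 quantiles (ppf would return the bound +/- inf)
        u = np.clip(u, 1e-15, 1.0 - 1e-15)
        theta = stats.truncnorm.ppf(u, a, b, loc=spec.tilt_mean, scale=spec.tilt_sd)
    phi = rng.uniform(0.0, 2.0 * np.pi, n_frames)
    t = np.radians(theta)
    vectors = np.column_stack(
        (np.sin(t) * np.cos(phi), np.sin(t) * np.sin(phi), np.cos(t))
    )
    # renormalize: sin/cos round-off can leave |v| off unity at the 1e-16 level
    vectors /= np.linalg.norm(vectors, axis=1, keepdims=True)
    return OrientationSeries(frames=np.arange(n_frames), vectors=vectors)


def generate_potential_grids(
    f_profile: PotentialFractionProfile,
    v_mp: float,
    box: tuple[float, float, float] = (60.0, 60.0, 72.0),
    spacing: float = 1.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[PotentialGrid, PotentialGrid]:
    """Paired electrostatic maps at ``v_mp`` and 0 mV embedding a known f(z).

    The biased grid carries ``v_mp * f(z)`` on every xy plane; both grids get
    independent Gaussian voxel noise of SD ``noise_sd / sqrt(2)`` mV, so
    their difference has noise of SD exactly ``noise_sd``. The grid origin
    puts z = 0 at the box midplane. ``spacing`` must divide every box
    dimension to within 1e-9.
    """
    if v_mp == 0:
        raise ValueError("v_mp must be nonzero for the biased grid")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    counts = []
    for dim in box:
        c = dim / spacing
        if abs(c - round(c)) > 1e-9 or round(c) < 1:
            raise ValueError(f"spacing {spacing} does not divide box dimension {dim}")
        counts.append(int(round(c)))
    nx, ny, nz = counts
    origin = np.array([0.0, 0.0, -box[2] / 2.0])
    sp = np.array([spacing, spacing, spacing])
    z_nodes = origin[2] + spacing * np.arange(nz)
    fz = np.asarray(interpolate_f(f_profile, z_nodes), float)

    rng = np.random.default_rng(seed)
    per_grid_sd = noise_sd / math.sqrt(2.0)
    noise_v = per_grid_sd * rng.standard_normal((nx, ny, nz))
    noise_0 = per_grid_sd * rng.standard_normal((nx, ny, nz))
    vals_v = v_mp * fz[None, None, :] + noise_v
    vals_0 = noise_0
    grid_v = PotentialGrid(origin=origin, spacing=sp, values=vals_v)
    grid_0 = PotentialGrid(origin=origin, spacing=sp.copy(), values=vals_0)
    return grid_v, grid_0
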