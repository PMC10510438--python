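"""Configurational statistics for a membrane-bound probe.

Tilt angles of the chromophore axis against the membrane normal, z-position
tracks and density profiles of labeled atoms, per-condition summaries, range
of motion across applied voltages, and block-average error estimation for
correlated time series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import VoltageCondition

#: Atom labels tracked along the membrane normal: the sulfonate sulfur, the
#: pyridinium nitrogen (N1), the amino nitrogen (N2), and the per-frame average
#: of the two terminal tail carbons.
ATOM_LABELS = ("S", "N1", "N2", "C_tail")

#: Membrane normal (+z by convention; bilayer midplane at z = 0).
MEMBRANE_NORMAL = np.array([0.0, 0.0, 1.0])


@dataclass
class AtomTrack:
    """Per-frame z-positions (Angstrom) of one labeled atom."""

    label: str
    frames: np.ndarray  # integer frame indices, strictly increasing
    z: np.ndarray       # Angstrom

    def __post_init__(self) -> None:
        if self.label not in ATOM_LABELS:
            raise ValueError(
                f"unknown atom label {self.label!r}; expected one of {ATOM_LABELS}"
            )
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.z = np.asarray(self.z, dtype=float)
        if self.frames.shape != self.z.shape:
            raise ValueError("frames and z must have the same length")
        if len(self.frames) == 0:
            raise ValueError("track has no frames")
        if len(self.frames) > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("frame indices must be strictly increasing")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("track contains non-finite z values")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class OrientationSeries:
    """Per-frame unit vectors for the N1->N2 chromophore axis."""

    frames: np.ndarray
    vectors: np.ndarray  # shape (n, 3), unit length

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != 3:
            raise ValueError("vectors must have shape (n, 3)")
        if len(self.frames) != len(self.vectors):
            raise ValueError("frames and vectors must have the same length")
        if len(self.frames) == 0:
            raise ValueError("orientation series has no frames")
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.all(np.abs(norms - 1.0) <= 1e-9):
            raise ValueError("orientation vectors must be unit length (tol 1e-9)")

    def __len__(self) -> int:
        return len(self.frames)

    def tilt_angles(self, normal: np.ndarray = MEMBRANE_NORMAL) -> np.ndarray:
        """Angle of every axis vector to the membrane normal, degrees."""
        n = np.asarray(normal, float)
        n = n / np.linalg.norm(n)
        cosang = np.clip(self.vectors @ n, -1.0, 1.0)
        return np.degrees(np.arccos(cosang))


@dataclass
class DensityProfile:
    """Histogram of z-positions along the membrane normal."""

    bin_edges: np.ndarray   # Angstrom, strictly increasing
    density: np.ndarray     # per-bin values, >= 0
    normalization: str      # "count" or "unit_peak"

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, float)
        self.density = np.asarray(self.density, float)
        if len(self.bin_edges) != len(self.density) + 1:
            raise ValueError("need len(bin_edges) == len(density) + 1")
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.density < 0):
            raise ValueError("densities must be non-negative")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class ConditionSummary:
    """Mean +/- SD of every tracked observable under one voltage condition.

    SDs are population SDs over frames (divisor n): they describe the spread of
    the configurational distribution, not the uncertainty of the mean.
    """

    cond: VoltageCondition
    n_frames: int
    z_stats: dict[str, tuple[float, float]] = field(default_factory=dict)
    tilt_stats: tuple[float, float] = (math.nan, math.nan)


def tilt_angle(axis, normal) -> float:
    """Angle in degrees between an axis vector and the membrane normal.

    Unfolded: the result lies in [0, 180] and antiparallel vectors give 180.
    Invariant to positive rescaling of either argument.
    """
    a = np.asarray(axis, float)
    n = np.asarray(normal, float)
    na, nn = np.linalg.norm(a), np.linalg.norm(n)
    if na == 0.0 or nn == 0.0:
        raise ValueError("tilt_angle requires nonzero vectors")
    cosang = np.clip(float(a @ n) / (na * nn), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def density_profile(
    samples, bin_width: float = 0.5, normalization: str = "count"
) -> DensityProfile:
    """Histogram z-positions into fixed-width bins.

    Bins start at the sample minimum and extend in whole ``bin_width`` steps
    until the maximum is covered. ``unit_peak`` rescales so the tallest bin
    equals 1 (profiles of different species can then be overlaid, each scaled
    relative to its own peak).
    """
    x = np.asarray(samples, float)
    if x.size == 0:
        raise ValueError("density_profile requires at least one sample")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if normalization not in ("count", "unit_peak"):
        raise ValueError(f"unknown normalization {normalization!r}")
    lo, hi = float(x.min()), float(x.max())
    n_bins = max(1, int(math.ceil((hi - lo) / bin_width - 1e-12)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(x, bins=edges)
    dens = counts.astype(float)
    if normalization == "unit_peak":
        dens = dens / dens.max()
    return DensityProfile(edges, dens, normalization)


def block_average(series, n_blocks: int = 10) -> tuple[float, float]:
    """Mean and block-average standard error of a (possibly correlated) series.

    The series is cut into ``n_blocks`` contiguous blocks of equal size, with
    any remainder frames assigned to the last block. The returned mean is the
    grand mean over all frames; the standard error is the sample SD (ddof=1)
    of the block means divided by sqrt(n_blocks). For blocks much longer than
    the correlation time this estimates the true SE of the mean.
    """
    x = np.asarray(series, float)
    n = x.size
    if n_blocks < 2:
        raise ValueError("n_blocks must be at least 2")
    if n_blocks > n:
        raise ValueError(f"n_blocks={n_blocks} exceeds series length {n}")
    if np.all(x == x[0]):  # constant series: SE exactly 0, no round-off
        return float(x[0]), 0.0
    size = n // n_blocks
    starts = [i * size for i in range(n_blocks)]
    stops = starts[1:] + [n]
    means = np.array([x[a:b].mean() for a, b in zip(starts, stops)])
    se = float(means.std(ddof=1) / math.sqrt(n_blocks))
    return float(x.mean()), se


def summarize_condition(
    tracks, orient: OrientationSeries, cond: VoltageCondition
) -> ConditionSummary:
    """Per-label mean +/- SD of z and of the tilt angle over all frames."""
    tracks = list(tracks)
    lengths = {len(t) for t in tracks} | {len(orient)}
    if len(lengths) != 1:
        raise ValueError(f"series length mismatch: {sorted(lengths)}")
    n = lengths.pop()
    z_stats = {
        t.label: (float(t.z.mean()), float(t.z.std(ddof=0))) for t in tracks
    }
    tilts = orient.tilt_angles()
    return ConditionSummary(
        cond=cond,
        n_frames=n,
        z_stats=z_stats,
        tilt_stats=(float(tilts.mean()), float(tilts.std(ddof=0))),
    )


def range_of_motion(summaries, label: str) -> float:
    """Shift of an atom's mean z between the extreme applied voltages, Angstrom.

    ``summaries`` are ConditionSummary objects for one electronic state at
    several voltages; the result is |mean z at max voltage - mean z at min
    voltage| for ``label``.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no summaries given")
    lo = min(summaries, key=lambda s: s.cond.v_mp)
    hi = max(summaries, key=lambda s: s.cond.v_mp)
    for s in (lo, hi):
        if label not in s.z_stats:
            raise KeyError(f"label {label!r} absent from summary at {s.cond.v_mp} mV")
    return abs(hi.z_stats[label][0] - lo.z_stats[label][0])
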