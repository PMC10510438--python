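"""Transmembrane potential fraction from paired electrostatic maps.

An applied membrane potential V_mp enters the simulation as a uniform field
E_z = V_mp / L_z along the membrane normal. The fraction of that potential
felt at depth z is obtained by subtracting the average 3-D electrostatic map
at 0 mV from the map at V_mp, averaging the difference over the membrane
(xy) plane, and dividing by V_mp:

    f(z) = < phi(r; V_mp) - phi(r; 0) >_xy / V_mp

f is dimensionless; in the bulk-water regions it plateaus at 0 on one side
of the membrane and 1 on the other, with the drop concentrated across the
hydrophobic core. No symmetrization across leaflets and no re-binning is
applied: f is reported on the grid's native z nodes, and values outside
[0, 1] are allowed (real maps can over/undershoot near the interfaces).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PotentialGrid:
    """A 3-D scalar electrostatic-potential map on a regular orthogonal grid.

    Values are in mV; ``origin`` and ``spacing`` are in Angstrom. Axis order
    is (x, y, z) with z the membrane normal; grid node (i, j, k) sits at
    ``origin + spacing * (i, j, k)``.
    """

    origin: np.ndarray     # (3,) Angstrom
    spacing: np.ndarray    # (3,) Angstrom per voxel
    values: np.ndarray     # (nx, ny, nz), mV

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float).reshape(3)
        self.spacing = np.asarray(self.spacing, float).reshape(3)
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive on every axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def box(self) -> np.ndarray:
        """Box dimensions (Lx, Ly, Lz), Angstrom."""
        return self.spacing * np.array(self.shape)

    @property
    def z_nodes(self) -> np.ndarray:
        """z-coordinates of the grid planes, Angstrom."""
        return self.origin[2] + self.spacing[2] * np.arange(self.shape[2])

    def congruent_with(self, other: "PotentialGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=1e-9)
            and np.allclose(self.spacing, other.spacing, atol=1e-9)
        )


@dataclass
class PotentialFractionProfile:
    """Dimensionless potential fraction f on z nodes along the membrane normal."""

    z: np.ndarray   # Angstrom, strictly increasing
    f: np.ndarray   # dimensionless

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, float)
        self.f = np.asarray(self.f, float)
        if self.z.shape != self.f.shape or self.z.ndim != 1:
            raise ValueError("z and f must be 1-D arrays of equal length")
        if self.z.size == 0:
            raise ValueError("profile has no nodes")
        if self.z.size > 1 and not np.all(np.diff(self.z) > 0):
            raise ValueError("z nodes must be strictly increasing")
        if not np.all(np.isfinite(self.f)):
            raise ValueError("profile contains non-finite values")


def applied_field(v_mp: float, l_z: float) -> float:
    """Uniform applied field E_z = V_mp / L_z, in mV/Angstrom."""
    if l_z <= 0:
        raise ValueError("box length l_z must be positive")
    return v_mp / l_z


def potential_fraction_profile(
    grid_v: PotentialGrid, grid_0: PotentialGrid, v_mp: float
) -> PotentialFractionProfile:
    """f(z) from maps at an applied voltage and at 0 mV.

    Per z slab, the unweighted mean over all xy voxels of (grid_v - grid_0)
    divided by ``v_mp``. The grids must be congruent (same origin, spacing
    and shape); any xy-independent gauge constant common to both maps
    cancels in the difference.
    """
    if v_mp == 0:
        raise ValueError("v_mp must be nonzero to define the potential fraction")
    if not grid_v.congruent_with(grid_0):
        raise ValueError("grids are not congruent (origin/spacing/shape differ)")
    diff = grid_v.values - grid_0.values
    f = diff.mean(axis=(0, 1)) / v_mp
    return PotentialFractionProfile(z=grid_v.z_nodes, f=f)


def interpolate_f(profile: PotentialFractionProfile, z) -> float | np.ndarray:
    """Linear interpolation of f at z (Angstrom), clamped to the end values."""
    out = np.interp(np.asarray(z, float), profile.z, profile.f)
    return float(out) if out.ndim == 0 else out


def coupling_fraction(charges, profile: PotentialFractionProfile) -> float:
    """Coupling of a set of point charges to the transmembrane potential.

    ``charges`` is an iterable of (q in elementary charges, z in Angstrom);
    the result is sum_i q_i * f(z_i), dimensionless and linear in the
    charges. A unit charge in the f=1 bulk couples fully (1), one in the
    f=0 bulk not at all.
    """
    total = 0.0
    for q, z in charges:
        total += q * interpolate_f(profile, z)
    return float(total)
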