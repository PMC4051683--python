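"""Fourier synthesis of bilayer electron-density profiles and absolute scaling.

For a centrosymmetric bilayer with period d the electron density is
reconstructed from the phased form factors by a truncated cosine series

    ρ*(z) = (2/d) Σ_{n=1}^{N} ν_n |F_n| cos(2πnz/d),

even and d-periodic by construction, on an arbitrary (relative) scale.
The profile is placed on an absolute e/Å³ scale by an affine map
ρ = αρ* + β with α, β chosen so that

  * ρ(0) equals a known bilayer-center density (0.22 e/Å³, the density of
    a CH2 group, for pure-lipid gel bilayers; up to 0.33 e/Å³, the mean
    amino-acid density, when peptide resides in the center), and
  * A_L ∫ ρ dz over one period equals twice the per-leaflet electron
    budget from :mod:`memdiff.composition` (two leaflets per period).

α > 0 is enforced; a negative α means the sign convention is flipped and
is corrected with a warning.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np

from .peakfit import FormFactorSet

__all__ = [
    "ScaleState",
    "DensityProfile",
    "fourier_synthesis",
    "scale_to_absolute",
    "landmark_report",
]

CH2_DENSITY = 0.22       # e/Å^3, bilayer-center density of a gel-state lipid
AMINO_ACID_DENSITY = 0.33  # e/Å^3, mean amino-acid electron density
WATER_DENSITY = 0.333    # e/Å^3, bulk water


class ScaleState(str, enum.Enum):
    RELATIVE = "relative"
    ABSOLUTE = "absolute"


@dataclass
class DensityProfile:
    """ρ(z) over one lamellar period on a symmetric z grid."""

    d_spacing: float
    z: np.ndarray
    rho: np.ndarray
    scale_state: ScaleState = ScaleState.RELATIVE
    rho_water: float = WATER_DENSITY

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.z.shape != self.rho.shape or self.z.ndim != 1:
            raise ValueError("z and rho must be 1-D arrays of equal length")
        if not np.allclose(self.z, -self.z[::-1], atol=1e-9 * self.d_spacing):
            raise ValueError("z grid must be symmetric about 0")
        if not np.allclose(self.rho, self.rho[::-1], rtol=0, atol=1e-9 * max(1.0, np.abs(self.rho).max())):
            raise ValueError("profile must be centrosymmetric: rho(z) == rho(-z)")

    @property
    def center_value(self) -> float:
        return float(np.interp(0.0, self.z, self.rho))

    def integral(self) -> float:
        """∫ρ dz over the period (trapezoidal on the uniform grid)."""
        return float(np.trapezoid(self.rho, self.z))


def fourier_synthesis(ffset: FormFactorSet, grid_points: int = 1024) -> DensityProfile:
    """Synthesize the relative-scale profile ρ*(z) from phased form factors.

    ρ*(z) = (2/d)·Σ ν_n|F_n| cos(2πnz/d) on a symmetric grid of
    ``grid_points`` points over [−d/2, d/2].  Missing orders simply do
    not contribute (the series runs over observed orders only).
    """
    if not ffset.assigned:
        raise ValueError("signs must be assigned before Fourier synthesis")
    n_max = int(ffset.orders.max()) if len(ffset.orders) else 0
    if grid_points < 4 * max(n_max, 1):
        raise ValueError("grid_points must be at least 4x the highest order")
    d = ffset.d_spacing
    # odd point count so z = 0 is on the grid and the grid is symmetric
    npts = grid_points + 1 - (grid_points % 2)
    z = np.linspace(-d / 2.0, d / 2.0, npts)
    phases = np.cos(2.0 * np.pi * np.outer(z, ffset.orders) / d)
    rho = (2.0 / d) * phases @ ffset.signed
    return DensityProfile(d, z, rho, ScaleState.RELATIVE)


def scale_to_absolute(
    profile: DensityProfile,
    budget: float,
    area_per_lipid: float,
    center_density: float = CH2_DENSITY,
) -> DensityProfile:
    """Affine-map a relative profile onto the absolute e/Å³ scale.

    Solves ρ = αρ* + β such that ρ(0) = ``center_density`` and
    A_L ∫ρ dz = 2·``budget`` (electrons of both leaflets in one period).
    α > 0 fixes the global sign convention (head-group maxima positive);
    a solution with α < 0 indicates flipped signs upstream and is
    corrected with a warning.
    """
    if profile.scale_state is not ScaleState.RELATIVE:
        raise ValueError("profile is already on an absolute scale")
    if area_per_lipid <= 0 or budget <= 0:
        raise ValueError("area_per_lipid and budget must be positive")
    rho0 = profile.center_value
    integ = profile.integral()
    d = profile.d_spacing
    # [rho0 1; A_L*integ A_L*d] [alpha beta]^T = [center, 2*budget]^T
    mat = np.array([[rho0, 1.0], [area_per_lipid * integ, area_per_lipid * d]])
    det = np.linalg.det(mat)
    if abs(det) < 1e-12 * max(1.0, abs(rho0) * area_per_lipid * d):
        raise ValueError("degenerate scaling system (flat profile)")
    alpha, beta = np.linalg.solve(mat, [center_density, 2.0 * budget])
    if alpha <= 0:
        warnings.warn("negative scale factor: global sign flipped to restore "
                      "head-group-positive convention")
        alpha, beta = np.linalg.solve(
            np.array([[-rho0, 1.0], [-area_per_lipid * integ, area_per_lipid * d]]),
            [center_density, 2.0 * budget])
        rho_abs = alpha * (-profile.rho) + beta
    else:
        rho_abs = alpha * profile.rho + beta
    return DensityProfile(profile.d_spacing, profile.z.copy(), rho_abs,
                          ScaleState.ABSOLUTE, profile.rho_water)


def landmark_report(profile: DensityProfile) -> tuple[float, float, float]:
    """Locate the head-group landmark of an absolute profile.

    Returns (head_peak_z, center_value, head_value): the position of the
    maximum over z ∈ (d/4, d/2) — the head-group region of the outer
    leaflet — plus ρ(0) and the maximum's value.  A flat region yields a
    warning and the degenerate position.
    """
    if profile.scale_state is not ScaleState.ABSOLUTE:
        raise ValueError("landmark_report expects an absolute-scale profile")
    d = profile.d_spacing
    sel = (profile.z > d / 4.0) & (profile.z < d / 2.0)
    zw, rw = profile.z[sel], profile.rho[sel]
    if np.ptp(rw) < 1e-12 * max(1.0, abs(rw).max()):
        warnings.warn("degenerate head-group region (flat); returning center value")
    idx = int(np.argmax(rw))
    return float(zw[idx]), profile.center_value, float(rw[idx])
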