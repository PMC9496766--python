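"""Distribution analysis of plasticity metrics.

Gaussian-kernel density estimates of bending-angle samples, modal values
with quadratic refinement, and Boltzmann-inversion free-energy profiles
ΔG(θ) = −kT·ln[p(θ)/p(θ_mode)].  Angle samples are treated as plain
scalars: observed α2-α2 angles live far from the 0°/180° wrap, so
circular statistics would change nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

__all__ = [
    "DensityEstimate",
    "FreeEnergyProfile",
    "KT_KCAL_300K",
    "kde",
    "kde_mode",
    "spread",
    "free_energy",
]

# kT in kcal/mol at 300 K (simulation temperature)
KT_KCAL_300K = 0.593


@dataclass
class DensityEstimate:
    """Gaussian-kernel density on a regular grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float  # same units as grid

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        integral = np.trapezoid(self.density, self.grid)
        if abs(integral - 1.0) > 1e-3:
            raise ValueError(f"density integrates to {integral:.5f}, not 1")


@dataclass
class FreeEnergyProfile:
    """ΔG relative to the distribution mode, in units of kT."""

    grid: np.ndarray
    delta_g: np.ndarray  # kT; NaN where density is masked
    reference_mode: float

    def __post_init__(self) -> None:
        finite = np.isfinite(self.delta_g)
        if np.any(self.delta_g[finite] < -1e-9):
            raise ValueError("ΔG must be non-negative (0 at the mode)")

    def at(self, value: float) -> float:
        """ΔG interpolated at *value* (kT); error in masked regions."""
        g = float(np.interp(value, self.grid, self.delta_g))
        if not np.isfinite(g):
            raise ValueError(f"ΔG undefined at {value} (density below mask threshold)")
        return g


def _check_samples(samples) -> np.ndarray:
    x = np.asarray(samples, dtype=float).ravel()
    if len(x) < 10:
        raise ValueError("need at least 10 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    if np.std(x) < 1e-12:
        raise ValueError("zero-variance sample")
    return x


def kde(samples, bandwidth: float | None = None,
        n_grid: int = 2001) -> DensityEstimate:
    """Gaussian-kernel density estimate with Scott's-rule default bandwidth.

    The grid spans the data ± 3 bandwidths.  The recorded ``bandwidth`` is
    the kernel standard deviation in data units.
    """
    x = _check_samples(samples)
    if bandwidth is None:
        k = gaussian_kde(x)  # Scott's rule
    else:
        if bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        k = gaussian_kde(x, bw_method=bandwidth / np.std(x, ddof=1))
    bw = float(k.factor * np.std(x, ddof=1))
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, n_grid)
    density = k(grid)
    density /= np.trapezoid(density, grid)
    return DensityEstimate(grid=grid, density=density, bandwidth=bw)


def kde_mode(samples, bandwidth: float | None = None,
             n_grid: int = 2001) -> float:
    """Most probable value: grid argmax of the KDE, quadratically refined.

    A parabola through the argmax and its two grid neighbours localizes
    the maximum below grid resolution.  Ties break toward the smaller
    grid value.
    """
    est = kde(samples, bandwidth=bandwidth, n_grid=n_grid)
    i = int(np.argmax(est.density))  # argmax takes the first (smallest) on ties
    if 0 < i < len(est.grid) - 1:
        y0, y1, y2 = est.density[i - 1:i + 2]
        denom = y0 - 2 * y1 + y2
        if abs(denom) > 1e-300:
            shift = 0.5 * (y0 - y2) / denom
            if abs(shift) <= 1.0:
                h = est.grid[1] - est.grid[0]
                return float(est.grid[i] + shift * h)
    return float(est.grid[i])


def spread(samples) -> float:
    """Sample standard deviation (n−1 denominator)."""
    x = np.asarray(samples, dtype=float).ravel()
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    return float(np.std(x, ddof=1))


def free_energy(samples, kt: float = 1.0, bandwidth: float | None = None,
                n_grid: int = 2001, mask_fraction: float = 1e-6) -> FreeEnergyProfile:
    """Boltzmann-inversion free-energy profile from a sample distribution.

    ΔG(θ) = −kT·ln[p(θ)/p(θ_mode)], zero at the mode and non-negative
    everywhere.  Grid points with density below ``mask_fraction`` of the
    maximum are masked (NaN): the log of a vanishing tail is noise, not
    energy.  With ``kt=KT_KCAL_300K`` the profile comes out in kcal/mol.
    """
    if kt <= 0:
        raise ValueError("kT must be positive")
    est = kde(samples, bandwidth=bandwidth, n_grid=n_grid)
    p_max = est.density.max()
    mode = kde_mode(samples, bandwidth=bandwidth, n_grid=n_grid)
    dg = np.full_like(est.density, np.nan)
    ok = est.density >= mask_fraction * p_max
    dg[ok] = -kt * np.log(est.density[ok] / p_max)
    return FreeEnergyProfile(grid=est.grid, delta_g=dg, reference_mode=mode)
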