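"""Density-based free-energy profiles and double-Gaussian barrier fits.

The potential of mean force along the membrane normal is obtained from the
equilibrium solute density, dG(eta) = -kB T ln rho(eta), on a uniform grid
(default bin width 1 A).  Replica profiles are averaged bin-wise; the averaged
curve is modelled as a sum of two Gaussians, from which the barrier height
dG_barrier (interior extremum vs the mean of its flanking extrema) and the
profile width sigma (mean of the two Gaussian widths) are extracted.  The
uncertainty on sigma comes from a fixed-x residual bootstrap of the fit.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import argrelextrema

from .constants import thermal_energy
from .geometry import ZSeries
from .models import double_gaussian, double_gaussian_jac


@dataclass
class DensityProfile:
    """Normalized solute number density on uniform eta bins."""

    bin_centers: np.ndarray
    counts: np.ndarray
    bin_width: float

    def __post_init__(self):
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.counts = np.asarray(self.counts)
        widths = np.diff(self.bin_centers)
        if widths.size and not np.allclose(widths, widths[0], rtol=1e-6):
            raise ValueError("bin width must be uniform")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def density(self) -> np.ndarray:
        """rho(eta), normalized so that sum(rho)*bin_width = 1."""
        return self.counts / (self.total * self.bin_width)


@dataclass
class FreeEnergyProfile:
    """dG(eta) in kcal/mol on the density grid; empty bins are masked."""

    eta: np.ndarray
    dg: np.ndarray  # masked (NaN) on empty bins
    temperature: float
    counts: Optional[np.ndarray] = None
    sd: Optional[np.ndarray] = None
    replicas: Optional[List[np.ndarray]] = None

    @property
    def mask(self) -> np.ndarray:
        """True on bins where dG is defined."""
        return np.isfinite(self.dg)


def density_profile(z: Union[ZSeries, np.ndarray], bin_width: float = 0.1,
                    bounds: Optional[Tuple[float, float]] = None) -> DensityProfile:
    """Histogram of all solute samples (all molecules, all frames), unit integral."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    samples = z.wrapped().ravel() if isinstance(z, ZSeries) else np.asarray(z, float).ravel()
    if samples.size == 0:
        raise ValueError("no samples")
    if bounds is None:
        bounds = (float(samples.min()), float(samples.max()) + bin_width)
    lo, hi = bounds
    if samples.min() < lo or samples.max() > hi:
        raise ValueError("bounds must cover all observed eta")
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(samples, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(centers, counts, bin_width)


def free_energy_profile(profile: DensityProfile, temperature: float) -> FreeEnergyProfile:
    """dG = -kB T ln rho on non-empty bins, shifted so min(dG) = 0.

    Empty bins are masked, never imputed: -kT ln 0 is undefined and smoothing
    would invent sampling that never happened.
    """
    kt = thermal_energy(temperature)
    rho = profile.density
    with np.errstate(divide="ignore"):
        dg = np.where(rho > 0, -kt * np.log(np.where(rho > 0, rho, 1.0)), np.nan)
    if not np.any(np.isfinite(dg)):
        raise ValueError("all bins empty")
    dg = dg - np.nanmin(dg)
    return FreeEnergyProfile(profile.bin_centers.copy(), dg, float(temperature),
                             counts=profile.counts.copy())


def average_profiles(profiles: Sequence[FreeEnergyProfile]) -> FreeEnergyProfile:
    """Bin-wise mean and sample SD over replicas on an identical grid.

    Bins empty (masked) in any replica are masked in the average.
    """
    if not profiles:
        raise ValueError("no profiles")
    ref = profiles[0]
    for p in profiles[1:]:
        if p.eta.shape != ref.eta.shape or not np.allclose(p.eta, ref.eta):
            raise ValueError("replica binning mismatch")
        if p.temperature != ref.temperature:
            raise ValueError("replica temperature mismatch")
    stack = np.vstack([p.dg for p in profiles])
    ok = np.all(np.isfinite(stack), axis=0)
    mean = np.where(ok, stack.mean(axis=0), np.nan)
    sd = np.where(ok, stack.std(axis=0, ddof=1) if len(profiles) > 1 else 0.0, np.nan)
    return FreeEnergyProfile(ref.eta.copy(), mean, ref.temperature, sd=sd,
                             replicas=[p.dg for p in profiles])


# ---------------------------------------------------------------------------
# double-Gaussian fit
# ---------------------------------------------------------------------------

@dataclass
class BarrierFit:
    """Fitted sum-of-two-Gaussians barrier model and derived metrics."""

    params: Tuple[float, float, float, float, float, float]  # a1, mu1, s1, a2, mu2, s2
    orientation: str  # "maxima_flanking_minimum" | "minima_flanking_maximum"
    barrier_height: float  # kcal/mol
    width: float  # nm, mean of the two Gaussian widths
    eta: np.ndarray
    residuals: np.ndarray
    ci: Optional[Tuple[float, float]] = None
    n_boot: Optional[int] = None
    seed: Optional[int] = None
    offset: float = 0.0
    offset_fitted: bool = False

    @property
    def widths(self) -> Tuple[float, float]:
        return self.params[2], self.params[5]

    def evaluate(self, eta):
        return double_gaussian(eta, *self.params) + self.offset


class FitError(RuntimeError):
    pass


def _classify_orientation(fn, lo, hi) -> Tuple[str, float]:
    """Find the interior extremum pattern of a fitted curve on a fine grid.

    Returns (orientation, barrier height = |central extremum - mean flanks|).
    """
    grid = np.linspace(lo, hi, 4001)
    vals = fn(grid)
    maxima = argrelextrema(vals, np.greater, order=5)[0]
    minima = argrelextrema(vals, np.less, order=5)[0]
    # central-min between two maxima
    if maxima.size >= 2:
        pair = maxima[np.argsort(vals[maxima])[-2:]]
        i, j = np.sort(pair)
        inner = minima[(minima > i) & (minima < j)]
        if inner.size:
            c = inner[np.argmin(vals[inner])]
            height = 0.5 * (vals[i] + vals[j]) - vals[c]
            return "maxima_flanking_minimum", float(abs(height))
    if minima.size >= 2:
        pair = minima[np.argsort(vals[minima])[:2]]
        i, j = np.sort(pair)
        inner = maxima[(maxima > i) & (maxima < j)]
        if inner.size:
            c = inner[np.argmax(vals[inner])]
            height = vals[c] - 0.5 * (vals[i] + vals[j])
            return "minima_flanking_maximum", float(abs(height))
    raise FitError("no interior extremum flanked by two outer extrema")


def _dg_with_offset(eta, a1, mu1, s1, a2, mu2, s2, c):
    return double_gaussian(eta, a1, mu1, s1, a2, mu2, s2) + c


def _dg_offset_jac(eta, a1, mu1, s1, a2, mu2, s2, c):
    base = double_gaussian_jac(eta, a1, mu1, s1, a2, mu2, s2)
    return np.concatenate([base, np.ones((base.shape[0], 1))], axis=1)


def _fit_once(eta, y, p0, maxfev=5000):
    """One curve_fit run; p0 of length 6, or 7 with a trailing baseline offset."""
    with_offset = len(p0) == 7
    fn = _dg_with_offset if with_offset else double_gaussian
    jac = _dg_offset_jac if with_offset else double_gaussian_jac
    popt, _ = curve_fit(fn, eta, y, p0=p0, jac=jac, maxfev=maxfev)
    popt = list(popt)
    popt[2], popt[5] = abs(popt[2]), abs(popt[5])
    if popt[1] > popt[4]:  # order Gaussians left-to-right
        popt = popt[3:6] + popt[:3] + popt[6:]
    return tuple(popt)


def fit_double_gaussian(profile: Union[FreeEnergyProfile, Tuple[np.ndarray, np.ndarray]],
                        fit_offset: bool = False) -> BarrierFit:
    """Least-squares fit of G(eta) = A1 g(mu1, s1) + A2 g(mu2, s2) to unmasked bins.

    Initialization is multi-start with symmetric seeds at +- the profile's
    extremum positions, trying both barrier orientations; the best residual
    wins.  ``fit_offset`` adds a jointly fitted constant baseline for
    min-referenced profiles whose bulk plateau is nonzero.
    """
    if isinstance(profile, FreeEnergyProfile):
        eta = profile.eta[profile.mask]
        y = profile.dg[profile.mask]
    else:
        eta, y = (np.asarray(a, dtype=float) for a in profile)
        ok = np.isfinite(y)
        eta, y = eta[ok], y[ok]
    if eta.size < (7 if fit_offset else 6):
        raise ValueError("need at least as many unmasked bins as parameters")

    c0 = float(np.median(np.concatenate([y[:3], y[-3:]]))) if fit_offset else 0.0
    yc = y - c0
    span = eta.max() - eta.min()
    amp = yc[np.argmax(np.abs(yc))]
    mu_seed = abs(eta[np.argmax(np.abs(yc))]) or 0.25 * span
    starts = []
    for sign in (np.sign(amp) or 1.0, -(np.sign(amp) or 1.0)):
        for mu in (mu_seed, 0.5 * mu_seed, 0.25 * span):
            for s in (0.25 * span, 0.1 * span):
                p0 = (sign * abs(amp), -mu, s, sign * abs(amp), mu, s)
                starts.append(p0 + (c0,) if fit_offset else p0)

    def model(x, popt):
        return _dg_with_offset(x, *popt) if fit_offset else double_gaussian(x, *popt)

    best, best_res = None, np.inf
    for p0 in starts:
        try:
            popt = _fit_once(eta, y, p0)
        except RuntimeError:
            continue
        res = float(np.sum((model(eta, popt) - y) ** 2))
        if res < best_res:
            best, best_res = popt, res
    if best is None:
        raise FitError("double-Gaussian fit failed to converge from all starts")

    gauss = best[:6]
    offset = best[6] if fit_offset else 0.0
    resid = y - model(eta, best)
    pad = 2.0 * max(gauss[2], gauss[5])
    orientation, height = _classify_orientation(
        lambda x: double_gaussian(x, *gauss),
        min(eta.min(), gauss[1] - pad), max(eta.max(), gauss[4] + pad))
    width = 0.5 * (gauss[2] + gauss[5])
    return BarrierFit(gauss, orientation, height, width, eta.copy(), resid,
                      offset=offset, offset_fitted=fit_offset)


def barrier_metrics(fit_or_profile: Union[BarrierFit, FreeEnergyProfile],
                    membrane_bounds: Optional[Tuple[float, float]] = None) -> float:
    """Barrier height dG_barrier in kcal/mol.

    For a fit, the analytic form is evaluated on a fine grid and the height is
    the interior extremum against the mean of its flanking extrema.  For a raw
    profile the fallback is max - min over the membrane region.
    """
    if isinstance(fit_or_profile, BarrierFit):
        return fit_or_profile.barrier_height
    prof = fit_or_profile
    eta, dg = prof.eta[prof.mask], prof.dg[prof.mask]
    if membrane_bounds is not None:
        sel = (eta >= membrane_bounds[0]) & (eta <= membrane_bounds[1])
        eta, dg = eta[sel], dg[sel]
    if dg.size == 0 or np.ptp(dg) == 0:
        raise FitError("no identifiable extremum in profile")
    return float(dg.max() - dg.min())


def bootstrap_width_ci(fit: BarrierFit, n_boot: int = 2000, seed: int = 0,
                       max_failure_fraction: float = 0.1,
                       alpha: float = 0.05) -> BarrierFit:
    """Percentile CI on the width from a fixed-x residual bootstrap.

    Synthetic curves = fitted form + resampled residuals are refit (initialized
    at the point estimate); the (alpha/2, 1-alpha/2) percentiles of the refit
    widths give the CI.  Fails if more than ``max_failure_fraction`` of refits
    do not converge.  Returns a new BarrierFit carrying the CI.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200")
    rng = np.random.default_rng(seed)
    base = fit.evaluate(fit.eta)
    resid = fit.residuals
    p0 = fit.params + ((fit.offset,) if fit.offset_fitted else ())
    if np.allclose(resid, 0):
        ci = (fit.width, fit.width)
    else:
        widths, failures = [], 0
        for _ in range(n_boot):
            y = base + rng.choice(resid, size=resid.size, replace=True)
            if not fit.offset_fitted:
                y = y - fit.offset
            try:
                popt = _fit_once(fit.eta, y, p0, maxfev=2000)
            except RuntimeError:
                failures += 1
                continue
            widths.append(0.5 * (popt[2] + popt[5]))
        if failures > max_failure_fraction * n_boot:
            raise FitError(f"{failures}/{n_boot} bootstrap refits failed")
        lo, hi = np.percentile(widths, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        ci = (float(lo), float(hi))
    return BarrierFit(fit.params, fit.orientation, fit.barrier_height, fit.width,
                      fit.eta, fit.residuals, ci=ci, n_boot=n_boot, seed=seed,
                      offset=fit.offset, offset_fitted=fit.offset_fitted)
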