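"""Gaussian fitting of correlation histograms.

The 5'-3' strand correlation plot ('+'-strand tags as reference, '-'-strand
tags as target) of a ChIP-seq sample shows a Gaussian-shaped peak whose
center estimates the average length of the immunoprecipitated fragments;
half of it is the recommended tag-centering distance.  The autocorrelation
plot of centered tags shows a Gaussian centered at zero whose width, together
with the sample's background density, suggests a window size and tag
threshold for peak calling.  A background (control) sample yields an
essentially flat profile, which the fit reports as a non-converged verdict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import poisson

from .correlate import CorrelationProfile

#: full-width-at-half-maximum factor: FWHM = 2*sqrt(2 ln 2) * sigma
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class GaussianFit:
    """Parameters of h(d) = baseline + amplitude * exp(-(d-mu)^2/(2 sigma^2))."""

    mu: float
    sigma: float
    amplitude: float
    baseline: float
    rmse: float
    converged: bool


@dataclass
class PeakRecommendation:
    """Suggested peak-calling parameters derived from a Gaussian fit."""

    centering_distance: int   # round(mu/2) from a 5'-3' fit
    window: int               # recommended window width (bp)
    threshold: int            # recommended tag threshold


def _gauss(d, baseline, amplitude, mu, sigma):
    return baseline + amplitude * np.exp(-((d - mu) ** 2) / (2.0 * sigma ** 2))


def fit_gaussian(profile: CorrelationProfile) -> GaussianFit:
    """Least-squares Gaussian-plus-baseline fit over the profile's bin
    centers.

    Initialization: baseline = median, amplitude = max - baseline, mu =
    argmax bin center, sigma = half-width at half maximum / sqrt(2 ln 2).
    The fit is reported as non-converged (flat-profile verdict) when the
    optimizer fails or when the fitted amplitude does not exceed twice the
    residual RMSE.
    """
    x = np.asarray(profile.bin_centers(), dtype=float)
    h = np.asarray(profile.values, dtype=float)
    if len(h) < 5:
        raise ValueError("profile must have at least 5 bins")

    b0 = float(np.median(h))
    a0 = float(h.max() - b0)
    imax = int(np.argmax(h))
    mu0 = float(x[imax])
    # half width at half max around the peak
    half_level = b0 + a0 / 2.0
    above = np.nonzero(h >= half_level)[0]
    if a0 > 0 and len(above) > 0:
        hwhm = max((x[above[-1]] - x[above[0]]) / 2.0, profile.width / 2.0)
    else:
        hwhm = profile.width
    sigma0 = max(hwhm / math.sqrt(2.0 * math.log(2.0)), 1e-6)

    try:
        popt, _ = curve_fit(
            _gauss, x, h, p0=[b0, max(a0, 1e-12), mu0, sigma0],
            bounds=([-np.inf, 0.0, -np.inf, 1e-9],
                    [np.inf, np.inf, np.inf, np.inf]),
            maxfev=10000)
        baseline, amplitude, mu, sigma = (float(v) for v in popt)
        residuals = h - _gauss(x, *popt)
        rmse = float(np.sqrt(np.mean(residuals ** 2)))
        # amplitude must beat the residual noise and, for numerically flat
        # profiles (rmse ~ 0), a tiny fraction of the profile's scale
        scale = max(float(np.max(np.abs(h))), 1.0)
        converged = amplitude > max(2.0 * rmse, 1e-8 * scale)
    except (RuntimeError, ValueError):
        baseline, amplitude, mu, sigma = b0, a0, mu0, sigma0
        rmse = float(np.sqrt(np.mean((h - b0) ** 2)))
        converged = False
    return GaussianFit(mu, sigma, amplitude, baseline, rmse, converged)


def recommend_peak_params(fit: GaussianFit, total_count: int,
                          genome_length: int, kappa: float = FWHM_FACTOR,
                          alpha: float = 1e-4) -> PeakRecommendation:
    """Derive recommended peak-calling parameters from a converged fit.

    Window = round(kappa * sigma) (by default the full width at half
    maximum of the fitted Gaussian); threshold = the smallest tag count T
    such that a Poisson background with mean lambda_bg * window exceeds or
    reaches T with probability below alpha, floored at 2 tags.
    """
    if not fit.converged:
        raise ValueError(
            "Gaussian fit did not converge (flat profile?); "
            "choose peak-calling parameters manually")
    if total_count < 1 or genome_length < 1:
        raise ValueError("total_count and genome_length must be >= 1")
    if kappa <= 0 or not (0 < alpha <= 1):
        raise ValueError("kappa must be > 0 and alpha in (0, 1]")
    window = max(1, round(kappa * fit.sigma))
    mean_bg = (total_count / genome_length) * window
    t = 2
    # P(X >= t) = sf(t - 1)
    while poisson.sf(t - 1, mean_bg) >= alpha:
        t += 1
    return PeakRecommendation(
        centering_distance=round(fit.mu / 2.0),
        window=window,
        threshold=t)
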