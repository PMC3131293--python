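"""Slow reference Bayes factors by numerical integration.

This module recomputes the marginal-likelihood ratios of :mod:`reqtl.bf`
by adaptive numerical quadrature over the effect-size prior — 1-D for
models M1-M3 (a single scalar effect) and genuinely nested 2-D for M4
(independent difference- and average-block effects).  The Gaussian
log-likelihood difference against the null is evaluated through its
sufficient statistics (sum x^2 and sum x*y), which is exact algebra; the
integration over the effect remains fully numeric.  The module exists to
validate the closed-form engine and is orders of magnitude slower; it is
never used in the mapping pipeline.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate

from .bf import BlockPrecisions, block_precisions
from .preprocess import PairedPhenotype


def _suffstats(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(x @ x), float(x @ y)


def _integrate(loglik_diff, prior_sd: float, peak: float, peak_sd: float) -> float:
    """Adaptive quadrature of exp(loglik_diff(b)) * N(b; 0, prior_sd^2).

    The interval covers both the prior and the likelihood peak with wide
    margins; the peak location is passed as a subdivision hint.
    """
    lo = min(-20.0 * prior_sd, peak - 12.0 * peak_sd)
    hi = max(20.0 * prior_sd, peak + 12.0 * peak_sd)

    norm_const = 1.0 / (math.sqrt(2.0 * math.pi) * prior_sd)
    inv_2var = 0.5 / (prior_sd * prior_sd)

    def integrand(b: float) -> float:
        return math.exp(loglik_diff(b) - b * b * inv_2var) * norm_const

    val, _ = integrate.quad(
        integrand, lo, hi, points=[0.0, peak], limit=200, epsabs=0.0, epsrel=1e-10
    )
    return val


def quadrature_single_block_logbf(
    response: np.ndarray, predictor: np.ndarray, tau: float, prior_var: float
) -> float:
    """1-D quadrature of the single-coefficient marginal likelihood ratio."""
    sxx, sxy = _suffstats(response, predictor)

    def loglik_diff(b: float) -> float:
        return -0.5 * tau * (b * b * sxx - 2.0 * b * sxy)

    peak = sxy / sxx
    peak_sd = 1.0 / math.sqrt(tau * sxx)
    return math.log10(_integrate(loglik_diff, math.sqrt(prior_var), peak, peak_sd))


def quadrature_shared_logbf(
    d: np.ndarray,
    m: np.ndarray,
    x: np.ndarray,
    taus: BlockPrecisions,
    c_d: float,
    c_m: float,
    prior_var: float,
) -> float:
    """1-D quadrature for one scalar effect loading on both blocks."""
    sxx, sxd = _suffstats(d, x)
    _, sxm = _suffstats(m, x)

    def loglik_diff(b: float) -> float:
        bd, bm = c_d * b, c_m * b
        return -0.5 * taus.tau_d * (bd * bd * sxx - 2.0 * bd * sxd) - 0.5 * (
            taus.tau_m
        ) * (bm * bm * sxx - 2.0 * bm * sxm)

    prec = (taus.tau_d * c_d * c_d + taus.tau_m * c_m * c_m) * sxx
    peak = (taus.tau_d * c_d * sxd + taus.tau_m * c_m * sxm) / prec
    return math.log10(
        _integrate(loglik_diff, math.sqrt(prior_var), peak, 1.0 / math.sqrt(prec))
    )


def quadrature_general_logbf(
    d: np.ndarray,
    m: np.ndarray,
    x: np.ndarray,
    taus: BlockPrecisions,
    prior_var_d: float,
    prior_var_m: float,
) -> float:
    """Nested 2-D quadrature over independent (beta_d, beta_m) effects."""
    sxx, sxd = _suffstats(d, x)
    _, sxm = _suffstats(m, x)
    peak_d, sd_d = sxd / sxx, 1.0 / math.sqrt(taus.tau_d * sxx)
    peak_m, sd_m = sxm / sxx, 1.0 / math.sqrt(taus.tau_m * sxx)

    def inner(bd: float) -> float:
        def loglik_m(bm: float) -> float:
            return -0.5 * taus.tau_m * (bm * bm * sxx - 2.0 * bm * sxm)

        val = _integrate(loglik_m, math.sqrt(prior_var_m), peak_m, sd_m)
        ll_d = -0.5 * taus.tau_d * (bd * bd * sxx - 2.0 * bd * sxd)
        return math.exp(ll_d) * val

    sd_prior_d = math.sqrt(prior_var_d)
    lo = min(-20.0 * sd_prior_d, peak_d - 12.0 * sd_d)
    hi = max(20.0 * sd_prior_d, peak_d + 12.0 * sd_d)
    norm_d = 1.0 / (math.sqrt(2.0 * math.pi) * sd_prior_d)
    val, _ = integrate.quad(
        lambda bd: inner(bd) * norm_d * math.exp(-bd * bd / (2.0 * prior_var_d)),
        lo, hi, points=[0.0, peak_d], limit=200, epsabs=0.0, epsrel=1e-9,
    )
    return math.log10(val)


def quadrature_model_logbfs(
    pheno: PairedPhenotype, x: np.ndarray, sigma_b: float
) -> np.ndarray:
    """log10 BFs for M1-M4 at one grid point, entirely by quadrature.

    Uses the same plug-in block precisions and pooled-sd prior scaling as
    the closed-form engine, so any disagreement isolates the integration
    step itself.
    """
    x = np.asarray(x, dtype=float)
    taus = block_precisions(pheno, x)
    sd_y = float(np.std(np.concatenate([pheno.treated, pheno.control]), ddof=1))
    w = (sigma_b * sd_y) ** 2
    d = pheno.diff - pheno.diff.mean()
    m = pheno.avg - pheno.avg.mean()
    xc = x - x.mean()
    return np.array(
        [
            quadrature_single_block_logbf(m, xc, taus.tau_m, w),
            quadrature_shared_logbf(d, m, xc, taus, 1.0, 0.5, w),
            quadrature_shared_logbf(d, m, xc, taus, -1.0, 0.5, w),
            quadrature_general_logbf(d, m, xc, taus, 2.0 * w, w / 2.0),
        ]
    )
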