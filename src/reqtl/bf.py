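"""Per-SNP Bayes factors for genotype-by-treatment interaction models.

Five models describe how a SNP's additive dosage effect may differ
between paired treatment conditions:

* M0 — no genotype effect in either condition (the null),
* M1 — the same effect in both conditions (no interaction),
* M2 — an effect only in treated samples,
* M3 — an effect only in control samples,
* M4 — different effects in the two conditions (general interaction).

The paired measurements of each individual are transformed to the
difference ``d = y_T - y_C`` and average ``m = (y_T + y_C)/2``.  The
shared individual-level component (the source of the pairing
correlation) cancels in ``d`` and loads entirely on ``m``, so the two
blocks are modelled as independent Gaussian regressions with their own
residual precisions (plugged in from the residuals of each block on
[1, x]).  Per-condition effects ``(beta_T, beta_C)`` map linearly onto
block effects ``beta_d = beta_T - beta_C`` and
``beta_m = (beta_T + beta_C)/2``, giving every model a closed-form
Bayes factor against M0:

* M1 (``beta_T = beta_C = beta``): a single coefficient in the m block,
  prior ``beta ~ N(0, w)``; the d block cancels in the ratio.
* M2 (``beta_C = 0``): one coefficient loading on both blocks with
  loadings ``(c_d, c_m) = (+1, +1/2)``.
* M3 (``beta_T = 0``): loadings ``(-1, +1/2)``.
* M4: independent ``beta_T, beta_C ~ N(0, w)`` give independent
  ``beta_d ~ N(0, 2w)`` and ``beta_m ~ N(0, w/2)``; the BF factorizes
  into the product of the two single-block BFs.

The per-condition prior variance is ``w = (sigma_b * sd_y)^2`` where
``sd_y`` is the pooled sd of treated and control values, evaluated on a
grid of ``sigma_b`` and averaged on the natural BF scale.  All formulas
are the standard approximate single-coefficient Bayes factor: with
``V = 1/(tau * sum x^2)`` and ``z = beta_hat / sqrt(V)``,
``BF = sqrt(V/(V+W)) * exp(z^2 W / (2 (V+W)))``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .config import DEFAULT_PRIOR_SD_GRID
from .preprocess import PairedPhenotype

LN10 = math.log(10.0)


class ModelId(enum.IntEnum):
    """The five genotype-by-treatment models."""

    M0 = 0  # null: no association in either condition
    M1 = 1  # no interaction: same effect in both conditions
    M2 = 2  # treated-only effect
    M3 = 3  # control-only effect
    M4 = 4  # general interaction: different effects

ALT_MODELS = (ModelId.M1, ModelId.M2, ModelId.M3, ModelId.M4)


class DegenerateSnpError(ValueError):
    """Raised when a SNP cannot be tested (constant dosage, too few
    complete cases, too few minor alleles, or zero residual variance)."""


@dataclass(frozen=True)
class BlockPrecisions:
    """Plug-in residual precisions of the difference and average blocks."""

    tau_d: float
    tau_m: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.tau_d) and self.tau_d > 0):
            raise ValueError("tau_d must be finite and positive")
        if not (np.isfinite(self.tau_m) and self.tau_m > 0):
            raise ValueError("tau_m must be finite and positive")


@dataclass
class SnpBF:
    """Grid-averaged log10 Bayes factors of one SNP against the null."""

    snp_id: str
    n_used: int
    log10_bf: np.ndarray          # shape (4,): M1..M4
    log10_bf_grid: np.ndarray     # shape (4, n_grid): per-grid-point diagnostics
    beta_treated: float
    beta_control: float

    def log10_bf_for(self, model: ModelId) -> float:
        if model == ModelId.M0:
            return 0.0
        return float(self.log10_bf[int(model) - 1])


def _residual_var_on_x(y: np.ndarray, x: np.ndarray) -> float:
    """Residual variance of y on [1, x], denominator n - 2."""
    n = y.size
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    beta = float(xc @ yc) / sxx
    resid = yc - beta * xc
    return float(resid @ resid) / (n - 2)


def block_precisions(pheno: PairedPhenotype, x: np.ndarray) -> BlockPrecisions:
    """Estimate the two block precisions from residuals on [1, x]."""
    x = np.asarray(x, dtype=float)
    if pheno.n < 5:
        raise DegenerateSnpError("need at least 5 complete cases")
    if np.all(x == x[0]):
        raise DegenerateSnpError("constant dosage vector")
    var_d = _residual_var_on_x(pheno.diff, x)
    var_m = _residual_var_on_x(pheno.avg, x)
    if var_d <= 0 or var_m <= 0:
        raise DegenerateSnpError("zero residual variance (degenerate phenotype)")
    return BlockPrecisions(tau_d=1.0 / var_d, tau_m=1.0 / var_m)


def _logbf_from_v(beta_hat: float, V: float, W: float) -> float:
    """log10 BF for one coefficient given its sampling variance V and
    prior variance W (symmetric in the sign of beta_hat)."""
    z2 = beta_hat * beta_hat / V
    ln_bf = 0.5 * math.log(V / (V + W)) + z2 * W / (2.0 * (V + W))
    return ln_bf / LN10


def single_block_logbf(
    response: np.ndarray, predictor: np.ndarray, tau: float, prior_var: float
) -> float:
    """log10 BF for a single regression coefficient in one block.

    ``response`` and ``predictor`` must be centered; the integral over
    ``beta ~ N(0, prior_var)`` of the Gaussian likelihood with known
    precision ``tau`` is available in closed form.
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(x))):
        raise ValueError("non-finite inputs")
    if not (np.isfinite(tau) and tau > 0 and np.isfinite(prior_var) and prior_var > 0):
        raise ValueError("tau and prior_var must be finite and positive")
    sxx = float(x @ x)
    if sxx <= 0:
        raise ValueError("predictor has zero sum of squares")
    beta_hat = float(x @ y) / sxx
    V = 1.0 / (tau * sxx)
    return _logbf_from_v(beta_hat, V, prior_var)


def shared_coefficient_logbf(
    d: np.ndarray,
    m: np.ndarray,
    x: np.ndarray,
    taus: BlockPrecisions,
    c_d: float,
    c_m: float,
    prior_var: float,
) -> float:
    """log10 BF for one scalar effect loading on both blocks.

    The effect beta enters the difference block with loading ``c_d`` and
    the average block with loading ``c_m`` (M2: (+1, +1/2); M3:
    (-1, +1/2)).  Information from the two independent blocks combines by
    precision weighting.
    """
    if c_d == 0.0 and c_m == 0.0:
        raise ValueError("at least one loading must be non-zero")
    d = np.asarray(d, dtype=float)
    m = np.asarray(m, dtype=float)
    x = np.asarray(x, dtype=float)
    sxx = float(x @ x)
    if sxx <= 0:
        raise ValueError("predictor has zero sum of squares")
    prec = taus.tau_d * c_d * c_d * sxx + taus.tau_m * c_m * c_m * sxx
    V = 1.0 / prec
    beta_hat = V * (
        taus.tau_d * c_d * float(x @ d) + taus.tau_m * c_m * float(x @ m)
    )
    return _logbf_from_v(beta_hat, V, prior_var)


def _log10_mean_of_pow10(log10_values: np.ndarray) -> float:
    """log10 of the arithmetic mean of 10**log10_values, overflow-safe."""
    v = np.asarray(log10_values, dtype=float)
    top = v.max()
    return float(top + math.log10(np.mean(np.power(10.0, v - top))))


def complete_cases(pheno: PairedPhenotype, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.isfinite(x) & np.isfinite(pheno.treated) & np.isfinite(pheno.control)


def snp_model_logbfs(
    pheno: PairedPhenotype,
    x: np.ndarray,
    prior_sd_grid: tuple[float, ...] = DEFAULT_PRIOR_SD_GRID,
    snp_id: str = "",
    min_complete: int = 5,
    min_minor_count: int = 2,
) -> SnpBF:
    """Grid-averaged log10 BFs for models M1-M4 against M0 at one SNP.

    Missing dosages are handled complete-case; SNPs with fewer than
    ``min_complete`` usable individuals or fewer than ``min_minor_count``
    minor alleles among them raise :class:`DegenerateSnpError` (callers
    record the reason and skip).  The prior sd grid is in units of the
    pooled phenotype sd, so all BFs are invariant under affine transforms
    applied to both conditions.
    """
    x = np.asarray(x, dtype=float)
    keep = complete_cases(pheno, x)
    n = int(keep.sum())
    if n < min_complete:
        raise DegenerateSnpError(f"only {n} complete cases (< {min_complete})")
    xk = x[keep]
    treated = pheno.treated[keep]
    control = pheno.control[keep]
    if np.all(xk == xk[0]):
        raise DegenerateSnpError("all dosages identical among used individuals")
    minor_count = min(float(xk.sum()), 2.0 * n - float(xk.sum()))
    if minor_count < min_minor_count:
        raise DegenerateSnpError(
            f"minor-allele count {minor_count:g} < {min_minor_count}"
        )

    sub = PairedPhenotype(treated, control)
    taus = block_precisions(sub, xk)
    sd_y = float(np.std(np.concatenate([treated, control]), ddof=1))
    if sd_y <= 0:
        raise DegenerateSnpError("constant phenotype")

    d = sub.diff - sub.diff.mean()
    m = sub.avg - sub.avg.mean()
    xc = xk - xk.mean()

    grid = np.asarray(prior_sd_grid, dtype=float)
    log10_grid = np.empty((4, grid.size))
    for j, sigma_b in enumerate(grid):
        w = (sigma_b * sd_y) ** 2
        log10_grid[0, j] = single_block_logbf(m, xc, taus.tau_m, w)
        log10_grid[1, j] = shared_coefficient_logbf(d, m, xc, taus, 1.0, 0.5, w)
        log10_grid[2, j] = shared_coefficient_logbf(d, m, xc, taus, -1.0, 0.5, w)
        log10_grid[3, j] = single_block_logbf(
            d, xc, taus.tau_d, 2.0 * w
        ) + single_block_logbf(m, xc, taus.tau_m, w / 2.0)
    log10_bf = np.array([_log10_mean_of_pow10(log10_grid[k]) for k in range(4)])

    sxx = float(xc @ xc)
    beta_t = float(xc @ (treated - treated.mean())) / sxx
    beta_c = float(xc @ (control - control.mean())) / sxx
    return SnpBF(
        snp_id=snp_id,
        n_used=n,
        log10_bf=log10_bf,
        log10_bf_grid=log10_grid,
        beta_treated=beta_t,
        beta_control=beta_c,
    )
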