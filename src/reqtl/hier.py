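"""Hierarchical combination of SNP-level Bayes factors.

SNP-level BFs are averaged within each gene's cis window (uniform SNP
prior, reflecting the at-most-one-eQTL-per-gene assumption), genome-wide
model proportions ``pi = (pi0..pi4)`` are estimated by EM over genes,
and per-gene posterior probabilities, interaction classifications, the
eQTN (most strongly associated SNP), and a posterior-based FDR follow.

All gene- and SNP-level BFs are carried in log10 to stay finite for
strong signals; mixture arithmetic uses log-sum-exp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .bf import LN10, ModelId, SnpBF

logger = logging.getLogger(__name__)

PI_FLOOR = 1e-8
DEFAULT_EM_INIT = (0.9, 0.04, 0.02, 0.02, 0.02)

MODEL_NAMES = ("M0", "M1", "M2", "M3", "M4")


@dataclass
class ModelPriors:
    """Genome-wide mixture proportions over the five models."""

    pi: np.ndarray
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (5,):
            raise ValueError("pi must have 5 components")
        if np.any(self.pi < 0) or not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("pi must be a probability vector")


def gene_log10_bf(snp_bfs: list[SnpBF]) -> np.ndarray:
    """Gene-level log10 BFs (M1..M4): arithmetic mean of SNP BFs.

    Uniform prior over the S usable SNPs in the window; under the
    at-most-one-eQTL assumption the gene marginal likelihood is the
    SNP-averaged mixture, so GBF(M) = mean_s BF_s(M).
    """
    if not snp_bfs:
        raise ValueError("no usable SNPs for this gene")
    mat = np.stack([s.log10_bf for s in snp_bfs])  # S x 4
    ln = mat * LN10
    return (logsumexp(ln, axis=0) - np.log(mat.shape[0])) / LN10


def _with_null(lgbf: np.ndarray) -> np.ndarray:
    """Prepend the log10 GBF of M0 (identically 0) to genes x 4."""
    lgbf = np.atleast_2d(np.asarray(lgbf, dtype=float))
    return np.column_stack([np.zeros(lgbf.shape[0]), lgbf])


def em_fit(
    lgbf: np.ndarray,
    init: tuple[float, ...] = DEFAULT_EM_INIT,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> ModelPriors:
    """Maximum-likelihood mixture proportions by EM.

    ``lgbf`` is genes x 4 log10 gene BFs for M1..M4 (M0 is the implicit
    reference with BF 1).  The E-step computes gene responsibilities
    r_g(M) proportional to pi_M * GBF_g(M); the M-step averages them.
    The log-likelihood sum_g log sum_M pi_M GBF_g(M) is non-decreasing;
    iteration stops when its increase falls below ``tol``.  Components
    hitting exactly zero are floored at 1e-8 and renormalized (logged).
    """
    ln_bf = _with_null(lgbf) * LN10  # genes x 5, natural log
    if ln_bf.shape[0] < 2:
        raise ValueError("EM needs at least 2 genes")
    if not np.all(np.isfinite(ln_bf)):
        raise ValueError("non-finite gene BFs")
    pi = np.asarray(init, dtype=float)
    pi = pi / pi.sum()
    trace: list[float] = []
    for it in range(1, max_iter + 1):
        with np.errstate(divide="ignore"):
            ln_joint = ln_bf + np.log(pi)  # genes x 5
        ln_marg = logsumexp(ln_joint, axis=1)
        loglik = float(ln_marg.sum())
        trace.append(loglik)
        resp = np.exp(ln_joint - ln_marg[:, None])
        new_pi = resp.mean(axis=0)
        if np.any(new_pi <= 0):
            logger.info("EM: flooring vanished components at %g", PI_FLOOR)
            new_pi = np.maximum(new_pi, PI_FLOOR)
        new_pi = new_pi / new_pi.sum()
        pi = new_pi
        if it > 1 and trace[-1] - trace[-2] < tol:
            break
    return ModelPriors(pi=pi, loglik_trace=trace, n_iter=len(trace))


def gene_log10_bf_grid(snp_bfs: list[SnpBF]) -> np.ndarray:
    """Gene-level log10 BFs resolved by prior grid point (4 x n_grid).

    Same SNP-averaging as :func:`gene_log10_bf` but without collapsing
    the effect-size grid, so the EM can estimate grid weights.
    """
    if not snp_bfs:
        raise ValueError("no usable SNPs for this gene")
    mat = np.stack([s.log10_bf_grid for s in snp_bfs])  # S x 4 x J
    ln = mat * LN10
    return (logsumexp(ln, axis=0) - np.log(mat.shape[0])) / LN10


def em_fit_grid(
    lgbf_grid: np.ndarray,
    init_pi: tuple[float, ...] = DEFAULT_EM_INIT,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> tuple[ModelPriors, np.ndarray]:
    """EM over model x effect-size-grid components.

    ``lgbf_grid`` is genes x 4 x n_grid.  Rather than fixing uniform
    weights over the effect-size grid, the grid weights within each
    non-null model are free mixture parameters estimated jointly with
    the model proportions — the fully hierarchical treatment of the
    effect-size prior.  Returns the aggregated :class:`ModelPriors`
    (pi_M = sum of that model's component weights) and the 4 x n_grid
    matrix of conditional grid weights per model.
    """
    lg = np.asarray(lgbf_grid, dtype=float)
    G, n_models, J = lg.shape
    if n_models != 4:
        raise ValueError("expected 4 non-null models")
    ln = np.concatenate(
        [np.zeros((G, 1)), lg.reshape(G, 4 * J) * LN10], axis=1
    )
    pi0 = np.asarray(init_pi, dtype=float)
    pi0 = pi0 / pi0.sum()
    w = np.empty(1 + 4 * J)
    w[0] = pi0[0]
    for m in range(4):
        w[1 + m * J : 1 + (m + 1) * J] = pi0[m + 1] / J
    trace: list[float] = []
    for it in range(1, max_iter + 1):
        with np.errstate(divide="ignore"):
            ln_joint = ln + np.log(w)
        ln_marg = logsumexp(ln_joint, axis=1)
        trace.append(float(ln_marg.sum()))
        resp = np.exp(ln_joint - ln_marg[:, None])
        new_w = resp.mean(axis=0)
        if np.any(new_w <= 0):
            new_w = np.maximum(new_w, PI_FLOOR / J)
        w = new_w / new_w.sum()
        if it > 1 and trace[-1] - trace[-2] < tol:
            break
    comp = w[1:].reshape(4, J)
    pi = np.concatenate([[w[0]], comp.sum(axis=1)])
    priors = ModelPriors(pi=pi / pi.sum(), loglik_trace=trace, n_iter=len(trace))
    with np.errstate(invalid="ignore"):
        grid_w = comp / comp.sum(axis=1, keepdims=True)
    return priors, grid_w


def gene_posteriors_grid(
    lgbf_grid: np.ndarray,
    priors: ModelPriors,
    grid_weights: np.ndarray,
    gene_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene model posteriors under grid-weighted effect priors.

    Collapses each model's grid components with the EM-estimated
    conditional weights before forming the five-model posterior; output
    layout matches :func:`gene_posteriors`.
    """
    lg = np.asarray(lgbf_grid, dtype=float)
    with np.errstate(divide="ignore"):
        ln_w = np.log(grid_weights)
    lgbf = (logsumexp(lg * LN10 + ln_w[None, :, :], axis=2)) / LN10
    return gene_posteriors(lgbf, priors, gene_ids)


def collapse_grid_bf(snp_bf: SnpBF, grid_weights: np.ndarray) -> np.ndarray:
    """Collapse one SNP's per-grid log10 BFs with per-model grid weights."""
    with np.errstate(divide="ignore"):
        ln_w = np.log(grid_weights)
    return logsumexp(snp_bf.log10_bf_grid * LN10 + ln_w, axis=1) / LN10


def gene_posteriors(
    lgbf: np.ndarray, priors: ModelPriors, gene_ids: list[str] | None = None
) -> pd.DataFrame:
    """Per-gene posterior probabilities over the five models.

    PP_g(M) = pi_M GBF_g(M) / sum_M' pi_M' GBF_g(M').  ``best_model`` is
    the argmax posterior among M1..M4 (ties broken by model order), and
    ``pp_interaction`` is PP(M2)+PP(M3)+PP(M4).
    """
    ln_bf = _with_null(lgbf) * LN10
    with np.errstate(divide="ignore"):
        ln_joint = ln_bf + np.log(priors.pi)
    pp = np.exp(ln_joint - logsumexp(ln_joint, axis=1)[:, None])
    best = np.argmax(pp[:, 1:], axis=1) + 1  # argmax keeps first (= lowest model) tie
    df = pd.DataFrame(pp, columns=[f"pp_{m}" for m in MODEL_NAMES])
    df["pp_interaction"] = pp[:, 2:].sum(axis=1)
    df["best_model"] = [MODEL_NAMES[b] for b in best]
    if gene_ids is not None:
        df.insert(0, "gene_id", gene_ids)
    return df


def bayesian_fdr(pp: np.ndarray, threshold: float) -> tuple[int, float]:
    """Bayesian FDR among features with posterior probability > threshold.

    Returns (n_selected, mean 1 - PP over the selected); an empty
    selection reports (0, nan).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    pp = np.asarray(pp, dtype=float)
    sel = pp > threshold
    n = int(sel.sum())
    if n == 0:
        return 0, float("nan")
    return n, float(np.mean(1.0 - pp[sel]))


def eqtn(
    snp_bfs: list[SnpBF], priors: ModelPriors, positions: np.ndarray | None = None
) -> str:
    """The gene's most strongly associated SNP.

    Scores each SNP by the prior-weighted mixture of its M1..M4 BFs and
    returns the maximizer; exact ties go to the smallest genomic
    position (or first listed when positions are not given).
    """
    if not snp_bfs:
        raise ValueError("no usable SNPs")
    with np.errstate(divide="ignore"):
        ln_pi = np.log(priors.pi[1:])
    scores = np.array(
        [logsumexp(s.log10_bf * LN10 + ln_pi) for s in snp_bfs]
    )
    best = scores.max()
    tied = np.flatnonzero(scores >= best - 1e-12)
    if positions is not None and len(tied) > 1:
        tied = tied[np.argsort(np.asarray(positions)[tied], kind="stable")]
    return snp_bfs[int(tied[0])].snp_id


def snp_interaction_bf(snp_bf: SnpBF, priors: ModelPriors) -> float:
    """SNP-level BF for interaction models (M2-M4) vs non-interaction
    models (M0-M1), with the hierarchical priors re-normalized within
    each group."""
    pi = priors.pi
    p_int = pi[2] + pi[3] + pi[4]
    p_non = pi[0] + pi[1]
    if p_int <= 0 or p_non <= 0:
        raise ValueError("both model groups need positive prior mass")
    ln = snp_bf.log10_bf * LN10  # M1..M4
    ln_num = logsumexp([np.log(pi[2]) + ln[1], np.log(pi[3]) + ln[2],
                        np.log(pi[4]) + ln[3]]) - np.log(p_int)
    ln_den = logsumexp([np.log(pi[0]), np.log(pi[1]) + ln[0]]) - np.log(p_non)
    return float(np.exp(ln_num - ln_den))
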