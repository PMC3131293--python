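"""Phenotype normalization, covariate correction, and pairing.

Expression values are quantile-normalized to N(0,1) normal scores
(average ranks for ties, offset (r - 0.5)/n) and optionally residualized
on measured covariates before any mapping.  Paired treated/control
vectors are decomposed into the per-individual log fold change
``d = y_T - y_C`` and average ``m = (y_T + y_C)/2``; the shared
individual-level component of the pair loads entirely on ``m``, which is
what lets the Bayes-factor engine treat the two blocks as independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CONDITIONS


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize_to_normal(values: np.ndarray) -> np.ndarray:
    """Map values to N(0,1) normal scores, preserving order.

    The value with 1-based rank r (ties averaged) maps to
    ``Phi^{-1}((r - 0.5)/n)``.  All-identical input is an error: there is
    no ranking to normalize.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need a 1-D vector with at least 2 values")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values cannot be rank-normalized")
    if np.all(values == values[0]):
        raise ValueError("all values identical; quantile normalization undefined")
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - 0.5) / values.size)


def normalize_expression(df: pd.DataFrame, mode: str = "joint") -> pd.DataFrame:
    """Quantile-normalize a paired expression table gene by gene.

    mode="joint": treated and control values of a gene are pooled into one
    vector and normalized together (used before differential-expression
    testing, so the treatment shift survives as a rank shift).
    mode="per-condition": each condition is normalized separately across
    individuals (used by the population-contrast analysis).  "per-gene" is
    accepted as an alias for "per-condition".
    """
    if mode == "per-gene":
        mode = "per-condition"
    out = df.copy()
    if mode == "joint":
        for gene in df.index:
            out.loc[gene] = quantile_normalize_to_normal(df.loc[gene].to_numpy())
    elif mode == "per-condition":
        for cond in CONDITIONS:
            cols = df.columns[df.columns.get_level_values("condition") == cond]
            block = df[cols].to_numpy()
            out[cols] = np.apply_along_axis(quantile_normalize_to_normal, 1, block)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return out


# ---------------------------------------------------------------------------
# covariate correction
# ---------------------------------------------------------------------------

def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None or covariates.size == 0:
        return np.ones((n, 1))
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[0] != n:
        covariates = covariates.T
    return np.column_stack([np.ones(n), covariates])


def residualize(y: np.ndarray, covariates: np.ndarray | None = None) -> np.ndarray:
    """OLS residuals of y on an intercept plus the covariate columns.

    Residuals have mean zero and are orthogonal to every covariate.  A
    rank-deficient design is an error naming the offending columns.
    """
    y = np.asarray(y, dtype=float)
    X = _design(covariates, y.size)
    if y.size <= X.shape[1]:
        raise ValueError("need more observations than covariates + intercept")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify collinear columns via vanishing R diagonal of a QR
        diag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        bad = np.flatnonzero(diag < 1e-10 * max(diag.max(), 1.0)).tolist()
        raise ValueError(f"rank-deficient covariate design (columns {bad})")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def residualize_expression(
    df: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Residualize each gene on the covariates, per condition separately.

    ``covariates`` is individuals × covariates; individuals must cover the
    expression table.
    """
    missing = set(df.columns.get_level_values("individual")) - set(covariates.index)
    if missing:
        raise ValueError(f"covariates missing for individuals: {sorted(missing)}")
    out = df.copy()
    for cond in CONDITIONS:
        cols = df.columns[df.columns.get_level_values("condition") == cond]
        inds = cols.get_level_values("individual")
        C = covariates.loc[inds].to_numpy(dtype=float)
        for gene in df.index:
            out.loc[gene, cols] = residualize(df.loc[gene, cols].to_numpy(), C)
    return out


def correct_secretion(protein_matrix: np.ndarray) -> np.ndarray:
    """Correct each protein's (log2) secretion by all other proteins.

    Row p is replaced by the residuals of an OLS regression of protein p
    on an intercept plus every other protein row.  Requires at least 3
    proteins and more individuals than regressors.
    """
    P = np.asarray(protein_matrix, dtype=float)
    if P.ndim != 2 or P.shape[0] < 3:
        raise ValueError("need a proteins x individuals matrix with >= 3 proteins")
    n_prot, n_ind = P.shape
    if n_ind <= n_prot:  # intercept + (n_prot - 1) regressors
        raise ValueError("more regressors than individuals; cannot correct")
    out = np.empty_like(P)
    for p in range(n_prot):
        others = np.delete(P, p, axis=0).T
        out[p] = residualize(P[p], others)
    return out


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

@dataclass
class PairedPhenotype:
    """Per-gene paired phenotype with its difference/average decomposition.

    ``diff`` is the log fold change (treated minus control) and ``avg``
    the per-individual mean of the two conditions; both are exact linear
    transforms of ``treated``/``control``.
    """

    treated: np.ndarray
    control: np.ndarray
    individuals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.treated = np.asarray(self.treated, dtype=float)
        self.control = np.asarray(self.control, dtype=float)
        if self.treated.shape != self.control.shape:
            raise ValueError("treated and control must have equal length")
        if self.individuals is not None:
            self.individuals = np.asarray(self.individuals)

    @property
    def diff(self) -> np.ndarray:
        return self.treated - self.control

    @property
    def avg(self) -> np.ndarray:
        return (self.treated + self.control) / 2.0

    @property
    def n(self) -> int:
        return self.treated.size


def make_paired(
    treated: np.ndarray,
    control: np.ndarray,
    treated_ids: np.ndarray | None = None,
    control_ids: np.ndarray | None = None,
) -> PairedPhenotype:
    """Pair treated/control vectors by individual id (ids optional)."""
    if (treated_ids is None) != (control_ids is None):
        raise ValueError("provide ids for both conditions or neither")
    if treated_ids is not None:
        t_ids = list(treated_ids)
        c_ids = list(control_ids)
        if t_ids != c_ids:
            raise ValueError(
                f"individual id mismatch between conditions: "
                f"{sorted(set(t_ids) ^ set(c_ids)) or 'ordering differs'}"
            )
    return PairedPhenotype(treated, control, treated_ids)


def paired_from_expression(df: pd.DataFrame, gene_id: str) -> PairedPhenotype:
    """Extract one gene's PairedPhenotype from a paired expression table."""
    from .io import expression_individuals

    inds = expression_individuals(df)
    row = df.loc[gene_id]
    treated = np.array([row[(i, "treated")] for i in inds])
    control = np.array([row[(i, "control")] for i in inds])
    return PairedPhenotype(treated, control, np.array(inds))


def decompose(pheno: PairedPhenotype) -> tuple[np.ndarray, np.ndarray]:
    """Return (diff, avg); inverse of recompose."""
    return pheno.diff, pheno.avg


def recompose(diff: np.ndarray, avg: np.ndarray) -> PairedPhenotype:
    """Rebuild treated/control from (diff, avg): the exact linear inverse."""
    diff = np.asarray(diff, dtype=float)
    avg = np.asarray(avg, dtype=float)
    return PairedPhenotype(avg + diff / 2.0, avg - diff / 2.0)
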