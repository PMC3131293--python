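"""Frequentist analyses: differential expression, log-fold-change
association mapping, and permutation-based FDR.

The response phenotype is the per-individual log fold change
``d = y_T - y_C``.  Association scans take the minimum p-value across a
gene's tested SNPs; significance comes from an empirical null built by
permuting genotype labels relative to the paired phenotype rows (each
individual keeps its own treated/control pair).  Within one permutation
round the same individual reordering is applied to every gene, which
preserves the cross-gene correlation structure of the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

P_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def de_test(
    expr: np.ndarray,
    treatment: np.ndarray,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene two-sided t-test for the treatment coefficient.

    ``expr`` is genes x samples (typically quantile-normalized with both
    conditions pooled); ``treatment`` is the 0/1 indicator per sample.
    Each gene is fit by OLS on [1, treatment, covariates]; the design is
    shared across genes so the fit is vectorized.
    """
    Y = np.atleast_2d(np.asarray(expr, dtype=float))
    t = np.asarray(treatment, dtype=float)
    n = t.size
    cols = [np.ones(n), t]
    if covariates is not None and np.size(covariates) > 0:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        cols.extend(C.T)
    X = np.column_stack(cols)
    k = X.shape[1]
    if n <= k + 1:
        raise ValueError("need more samples than covariates + 2")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("rank-deficient design (collinear covariates?)")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ xtx_inv.T  # genes x k
    resid = Y - beta @ X.T
    dof = n - k
    sigma2 = np.einsum("ij,ij->i", resid, resid) / dof
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta[:, 1] / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    p = np.clip(p, P_FLOOR, 1.0)
    return pd.DataFrame({"beta": beta[:, 1], "t": tstat, "p": p})


# ---------------------------------------------------------------------------
# permutation machinery and empirical FDR
# ---------------------------------------------------------------------------

@dataclass
class PermutationNull:
    """One individual reordering per round, shared by every gene."""

    indices: np.ndarray  # n_perms x n_individuals
    seed: int
    min_p: np.ndarray | None = None  # genes x n_perms, filled by scan()

    def __post_init__(self) -> None:
        for row in self.indices:
            if not np.array_equal(np.sort(row), np.arange(row.size)):
                raise ValueError("each permutation must be a bijection")

    @property
    def n_perms(self) -> int:
        return self.indices.shape[0]


def permutation_null(n_individuals: int, n_perms: int, seed: int) -> PermutationNull:
    """Draw the shared permutation rounds from a master seed."""
    rng = np.random.default_rng(seed)
    if n_perms == 0:
        return PermutationNull(np.empty((0, n_individuals), dtype=int), seed)
    idx = np.stack([rng.permutation(n_individuals) for _ in range(n_perms)])
    return PermutationNull(indices=idx, seed=seed)


def empirical_fdr(
    p_obs: np.ndarray, p_perm: np.ndarray, pseudocount: float = 1.0
) -> np.ndarray:
    """Permutation-ratio FDR at each observed p-value.

    FDR(t) = [(pseudocount + total #{p_perm <= t}) / n_rounds]
             / max(1, #{p_obs <= t}),
    clipped to [0, 1] and made non-decreasing in t by a cumulative max
    over increasing thresholds.  The add-one pseudocount (the default)
    keeps the estimate away from an exact zero when the extreme observed
    p-value happens to beat every permutation value — the permutation
    analogue of never reporting a zero permutation p-value; pass
    ``pseudocount=0`` for the plain ratio.  ``p_perm`` is rounds x
    features (or any array whose first axis indexes rounds); returns one
    FDR per observed feature, aligned with ``p_obs``.
    """
    p_obs = np.asarray(p_obs, dtype=float)
    p_perm = np.atleast_2d(np.asarray(p_perm, dtype=float))
    n_rounds = p_perm.shape[0]
    flat = np.sort(p_perm.ravel())
    order = np.argsort(p_obs, kind="stable")
    sorted_obs = p_obs[order]
    n_obs_le = np.arange(1, sorted_obs.size + 1)
    n_perm_le = np.searchsorted(flat, sorted_obs, side="right")
    fdr = ((pseudocount + n_perm_le) / n_rounds) / np.maximum(1, n_obs_le)
    fdr = np.minimum(fdr, 1.0)
    fdr = np.maximum.accumulate(fdr)
    out = np.empty_like(fdr)
    out[order] = fdr
    return out


# ---------------------------------------------------------------------------
# association tests
# ---------------------------------------------------------------------------

def lfc_assoc(d: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Simple OLS of log fold change on dosage: (slope, two-sided p)."""
    d = np.asarray(d, dtype=float)
    x = np.asarray(x, dtype=float)
    keep = np.isfinite(d) & np.isfinite(x)
    d, x = d[keep], x[keep]
    if d.size < 5:
        raise ValueError("need at least 5 complete cases")
    if np.all(x == x[0]):
        raise ValueError("constant dosage")
    xc = x - x.mean()
    dc = d - d.mean()
    sxx = float(xc @ xc)
    slope = float(xc @ dc) / sxx
    resid = dc - slope * xc
    dof = d.size - 2
    s2 = float(resid @ resid) / dof
    if s2 == 0.0:
        return slope, P_FLOOR
    tstat = slope / np.sqrt(s2 / sxx)
    p = 2.0 * stats.t.sf(abs(tstat), dof)
    return slope, float(np.clip(p, P_FLOOR, 1.0))


def _minp_matrix(D: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-SNP p-values of columns of D (response sets) against
    columns of X (SNP dosages).  Returns (p matrix snps x responses,
    slopes, valid-SNP mask).  Requires complete data."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Dc = D - D.mean(axis=0)
    sxx = np.einsum("ij,ij->j", Xc, Xc)
    valid = sxx > 0
    sxx_safe = np.where(valid, sxx, 1.0)
    sxy = Xc.T @ Dc  # snps x responses
    slope = sxy / sxx_safe[:, None]
    sdd = np.einsum("ij,ij->j", Dc, Dc)
    ss_res = np.maximum(sdd[None, :] - sxy**2 / sxx_safe[:, None], 0.0)
    dof = n - 2
    s2 = ss_res / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(s2 > 0, sxy / sxx_safe[:, None] / np.sqrt(s2 / sxx_safe[:, None]), np.inf)
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    p = np.clip(p, P_FLOOR, 1.0)
    p[~valid] = np.nan
    return p, slope, valid


def scan(
    d_table: pd.DataFrame,
    gm,
    gene_snps: dict[str, np.ndarray],
    n_perms: int = 100,
    seed: int = 0,
    perms: PermutationNull | None = None,
) -> tuple[pd.DataFrame, PermutationNull]:
    """Min-p log-fold-change association scan with a permutation null.

    ``d_table`` is genes x individuals log fold changes; ``gene_snps``
    maps gene id -> SNP row indices in ``gm`` (from
    :func:`reqtl.io.map_cis_snps`, or an explicit candidate-region list,
    or every SNP for a genome-wide scan).  Returns the per-gene results
    (top SNP, min p, slope at top SNP, permutation FDR) and the filled
    :class:`PermutationNull`.
    """
    individuals = list(d_table.columns)
    n = len(individuals)
    if perms is None:
        perms = permutation_null(n, n_perms, seed)
    col_idx = {i: k for k, i in enumerate(gm.individuals)}
    gcols = np.array([col_idx[i] for i in individuals])
    # permuting genotype labels by sigma is equivalent, test-statistic-wise,
    # to permuting the phenotype by sigma^-1, which lets every round share
    # one vectorized fit
    inv_perms = np.argsort(perms.indices, axis=1)

    rows = []
    null_minp = np.full((len(d_table.index), perms.n_perms), np.nan)
    for gi, gene in enumerate(d_table.index):
        snp_idx = np.asarray(gene_snps.get(gene, ()), dtype=int)
        d = d_table.loc[gene].to_numpy(dtype=float)
        if snp_idx.size == 0:
            rows.append((gene, None, np.nan, np.nan, 0))
            continue
        X = gm.dosages[np.ix_(snp_idx, gcols)].T  # n x S
        if np.isnan(X).any() or np.isnan(d).any():
            p_obs, slope_obs, minp_perm = _scan_gene_incomplete(d, X, perms)
        else:
            # column 0 is the observed phenotype, the rest one column per round
            D = np.column_stack([d, d[inv_perms].T]) if perms.n_perms else d[:, None]
            p, slopes, valid = _minp_matrix(D, X)
            p_obs, slope_obs = p[:, 0], slopes[:, 0]
            minp_perm = (
                np.nanmin(p[:, 1:], axis=0)
                if np.any(valid) and perms.n_perms
                else np.full(perms.n_perms, np.nan)
            )
        if np.all(np.isnan(p_obs)):
            rows.append((gene, None, np.nan, np.nan, int(snp_idx.size)))
            continue
        best = int(np.nanargmin(p_obs))
        rows.append(
            (gene, gm.snp_ids[snp_idx[best]], float(p_obs[best]),
             float(slope_obs[best]), int(np.sum(np.isfinite(p_obs))))
        )
        null_minp[gi] = minp_perm
    perms.min_p = null_minp

    res = pd.DataFrame(
        rows, columns=["gene_id", "top_snp_id", "min_p", "slope", "n_snps_tested"]
    ).set_index("gene_id")
    tested = res["min_p"].notna().to_numpy()
    fdr = np.full(len(res), np.nan)
    if tested.any() and perms.n_perms > 0:
        fdr[tested] = empirical_fdr(
            res.loc[tested, "min_p"].to_numpy(), null_minp[tested].T
        )
    res["fdr"] = fdr
    return res, perms


def _scan_gene_incomplete(d, X, perms):
    """Per-SNP complete-case fallback when dosages/phenotypes have NaNs."""
    S = X.shape[1]
    p_obs = np.full(S, np.nan)
    slope_obs = np.full(S, np.nan)
    for s in range(S):
        try:
            slope_obs[s], p_obs[s] = lfc_assoc(d, X[:, s])
        except ValueError:
            continue
    minp_perm = np.full(perms.n_perms, np.nan)
    for r, perm in enumerate(perms.indices):
        ps = []
        for s in range(S):
            try:
                ps.append(lfc_assoc(d, X[perm, s])[1])
            except ValueError:
                continue
        minp_perm[r] = min(ps) if ps else np.nan
    return p_obs, slope_obs, minp_perm


def secretion_qtl(
    secretion_d: pd.DataFrame,
    gm,
    protein_genes: pd.DataFrame,
    window: int = 100_000,
    n_perms: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, PermutationNull]:
    """Map secretion-response QTLs near each protein's encoding gene.

    ``secretion_d`` is proteins x individuals corrected log fold change
    in secretion; ``protein_genes`` gives the encoding gene's coordinates
    per protein (same layout as gene annotations).  Identical machinery
    to :func:`scan` with proteins in place of genes.
    """
    from .io import map_cis_snps

    mapping = map_cis_snps(protein_genes, gm, window)
    return scan(secretion_d, gm, mapping, n_perms=n_perms, seed=seed)
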