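"""Population-by-treatment interaction analysis.

A population label behaves statistically like a haploid 0/1 "dosage", so
the same Bayes-factor engine and hierarchical EM that detect
genotype-by-treatment interactions detect genes whose transcriptional
response differs between two populations.  The module also predicts
between-population response differences from eQTN effect sizes and
allele-frequency differences (assuming Hardy-Weinberg within each
population), tallies response directions, and tests whether interaction
eQTLs are enriched among population-different genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .bf import DegenerateSnpError, snp_model_logbfs
from .config import DEFAULT_PRIOR_SD_GRID
from .hier import ModelPriors, em_fit, gene_posteriors
from .preprocess import PairedPhenotype, quantile_normalize_to_normal


def pop_interaction(
    phenos: dict[str, PairedPhenotype],
    pop: np.ndarray,
    prior_sd_grid: tuple[float, ...] = DEFAULT_PRIOR_SD_GRID,
    normalize: bool = True,
    em_kwargs: dict | None = None,
) -> tuple[pd.DataFrame, ModelPriors]:
    """Per-gene population-by-treatment posteriors.

    ``pop`` is the 0/1 population indicator per individual (both groups
    need at least 5 members).  Each gene's treated and control vectors
    are first quantile-normalized across all individuals (outlier
    protection), then fed to the Bayes-factor engine with the population
    indicator as the predictor; the gene-level BF is that single
    predictor's BF, and the EM over genes is fit separately from any
    genotype analysis.  Returns the posterior table (with response
    direction and which population responds more strongly) and the
    fitted priors.
    """
    pop = np.asarray(pop, dtype=float)
    if not set(np.unique(pop)) <= {0.0, 1.0}:
        raise ValueError("population indicator must be 0/1")
    if min((pop == 0).sum(), (pop == 1).sum()) < 5:
        raise ValueError("each population needs at least 5 individuals")

    gene_ids, lgbf_rows, directions, stronger = [], [], [], []
    for gene_id, pheno in phenos.items():
        if normalize:
            pheno_n = PairedPhenotype(
                quantile_normalize_to_normal(pheno.treated),
                quantile_normalize_to_normal(pheno.control),
            )
        else:
            pheno_n = pheno
        try:
            sbf = snp_model_logbfs(pheno_n, pop, prior_sd_grid, snp_id=gene_id,
                                   min_minor_count=0)
        except DegenerateSnpError:
            continue
        gene_ids.append(gene_id)
        lgbf_rows.append(sbf.log10_bf)
        d = pheno.diff  # direction from raw log fold change
        grand = float(np.mean(d))
        directions.append("up" if grand > 0 else "down")
        mean1 = float(np.mean(d[pop == 1]))
        mean0 = float(np.mean(d[pop == 0]))
        # "stronger" = larger response in the direction of the grand mean
        if grand > 0:
            stronger.append(1 if mean1 > mean0 else 0)
        else:
            stronger.append(1 if mean1 < mean0 else 0)

    lgbf = np.asarray(lgbf_rows)
    priors = em_fit(lgbf, **(em_kwargs or {}))
    post = gene_posteriors(lgbf, priors, gene_ids)
    post["direction"] = directions
    post["stronger_in"] = stronger
    return post.set_index("gene_id"), priors


def direction_tally(
    contrasts: pd.DataFrame,
    population: int = 1,
    threshold: float = 0.7,
) -> dict:
    """Among population-different genes (PP_interaction > threshold),
    count up-/down-regulated genes and the fraction of up-regulated ones
    whose response is stronger in ``population``."""
    sel = contrasts[contrasts["pp_interaction"] > threshold]
    if len(sel) == 0:
        raise ValueError("no genes pass the posterior threshold")
    n_up = int((sel["direction"] == "up").sum())
    n_down = int((sel["direction"] == "down").sum())
    up = sel[sel["direction"] == "up"]
    frac = float((up["stronger_in"] == population).mean()) if n_up else float("nan")
    return {"n_selected": len(sel), "n_up": n_up, "n_down": n_down,
            "frac_up_stronger": frac}


def predict_popdiff(
    beta: np.ndarray,
    freq_pop1: np.ndarray,
    freq_pop2: np.ndarray,
    observed_diff: np.ndarray | None = None,
) -> tuple[np.ndarray, dict | None]:
    """Predict per-gene population response differences from eQTN effects.

    The predicted difference is ``2 * beta * (f1 - f2)``: the per-copy
    effect of the eQTN on the response times the expected dosage
    difference under Hardy-Weinberg.  When observed mean-response
    differences are supplied, they are regressed on the predictions
    (simple OLS with intercept) and (r2, p, slope) are returned.
    """
    beta = np.asarray(beta, dtype=float)
    f1 = np.asarray(freq_pop1, dtype=float)
    f2 = np.asarray(freq_pop2, dtype=float)
    if np.any((f1 < 0) | (f1 > 1) | (f2 < 0) | (f2 > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    predicted = 2.0 * beta * (f1 - f2)
    if observed_diff is None:
        return predicted, None
    obs = np.asarray(observed_diff, dtype=float)
    if np.var(predicted) == 0:
        return predicted, {"r2": float("nan"), "p": float("nan"),
                           "slope": float("nan")}
    fit = stats.linregress(predicted, obs)
    return predicted, {"r2": fit.rvalue**2, "p": fit.pvalue, "slope": fit.slope}


def enrichment_or(table: np.ndarray) -> tuple[float, float]:
    """Odds ratio and two-sided Fisher exact p for a 2x2 count table.

    A continuity correction of 0.5 is added to every cell for the odds
    ratio iff any cell is zero; the exact p always uses the raw counts.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a 2x2 table of non-negative counts")
    cells = t.copy()
    if np.any(cells == 0):
        cells = cells + 0.5
    oddsratio = (cells[0, 0] * cells[1, 1]) / (cells[0, 1] * cells[1, 0])
    _, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
    return float(oddsratio), float(p)
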