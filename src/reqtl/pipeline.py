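"""End-to-end assembly of the Bayesian and frequentist mapping runs."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .bf import DegenerateSnpError, SnpBF, snp_model_logbfs
from .config import RunConfig
from .freq import scan
from .hier import (
    ModelPriors,
    bayesian_fdr,
    collapse_grid_bf,
    em_fit_grid,
    eqtn,
    gene_log10_bf_grid,
    gene_posteriors_grid,
    snp_interaction_bf,
)
from .io import GenotypeMatrix, expression_individuals, map_cis_snps
from .preprocess import paired_from_expression

logger = logging.getLogger(__name__)


def compute_snp_bfs(
    expr: pd.DataFrame,
    gm: GenotypeMatrix,
    gene_snps: dict[str, np.ndarray],
    config: RunConfig,
) -> tuple[dict[str, list[SnpBF]], pd.DataFrame]:
    """Per-gene SnpBF lists plus a flat (gene, SNP) table.

    SNPs that cannot be tested (constant dosage, too few complete cases
    or minor alleles) are skipped with the reason recorded in the table.
    """
    individuals = expression_individuals(expr)
    if not set(individuals) & set(gm.individuals):
        raise ValueError("no overlapping individual ids between expression and genotypes")
    gm = gm.subset_individuals([i for i in individuals if i in gm.individuals])
    maf = gm.maf()

    per_gene: dict[str, list[SnpBF]] = {}
    rows = []
    for gene in expr.index:
        pheno = paired_from_expression(expr, gene)
        bfs: list[SnpBF] = []
        for s in gene_snps.get(gene, ()):  # type: ignore[union-attr]
            if np.isfinite(maf[s]) and maf[s] < config.maf_min:
                continue
            snp_id = str(gm.snp_ids[s])
            try:
                sbf = snp_model_logbfs(
                    pheno, gm.dosages[s], config.prior_sd_grid, snp_id=snp_id
                )
            except DegenerateSnpError as exc:
                rows.append((gene, snp_id, gm.pos[s], np.nan, np.nan, np.nan,
                             np.nan, np.nan, np.nan, 0, str(exc)))
                continue
            bfs.append(sbf)
            rows.append(
                (gene, snp_id, gm.pos[s], *sbf.log10_bf, sbf.beta_treated,
                 sbf.beta_control, sbf.n_used, "")
            )
        per_gene[gene] = bfs
    table = pd.DataFrame(
        rows,
        columns=["gene_id", "snp_id", "pos", "log10_bf_M1", "log10_bf_M2",
                 "log10_bf_M3", "log10_bf_M4", "beta_treated", "beta_control",
                 "n_used", "skip_reason"],
    )
    return per_gene, table


def map_bayes(
    expr: pd.DataFrame,
    gm: GenotypeMatrix,
    genes: pd.DataFrame,
    config: RunConfig | None = None,
) -> dict:
    """The full hierarchical interaction-mapping run.

    Maps cis SNPs, computes per-SNP BFs, averages them into gene BFs,
    fits the genome-wide model proportions by EM, and returns per-gene
    posteriors with classifications, eQTNs, SNP-level interaction BFs
    and the posterior-based FDR at the configured threshold.
    """
    config = config or RunConfig()
    gene_snps = map_cis_snps(genes, gm, config.cis_window_bp)
    per_gene, snp_table = compute_snp_bfs(expr, gm, gene_snps, config)

    usable = [g for g, bfs in per_gene.items() if bfs]
    skipped = [g for g, bfs in per_gene.items() if not bfs]
    if skipped:
        logger.info("%d genes had no usable SNP and are excluded from EM", len(skipped))
    lgbf_grid = np.stack([gene_log10_bf_grid(per_gene[g]) for g in usable])
    priors, grid_w = em_fit_grid(
        lgbf_grid, tol=config.em_tolerance, max_iter=config.em_max_iter
    )
    post = gene_posteriors_grid(lgbf_grid, priors, grid_w, usable).set_index("gene_id")

    # collapse each SNP's grid BFs with the fitted grid weights for
    # eQTN picking and SNP-level interaction BFs
    import dataclasses as _dc

    collapsed = {
        g: [_dc.replace(s, log10_bf=collapse_grid_bf(s, grid_w)) for s in per_gene[g]]
        for g in usable
    }
    pos_by_id = dict(zip(gm.snp_ids, gm.pos))
    post["eqtn"] = [
        eqtn(collapsed[g], priors,
             positions=[pos_by_id[s.snp_id] for s in collapsed[g]])
        for g in usable
    ]
    post["n_snps"] = [len(per_gene[g]) for g in usable]

    snp_int_rows = []
    for g in usable:
        for s in collapsed[g]:
            snp_int_rows.append((g, s.snp_id, snp_interaction_bf(s, priors)))
    snp_int = pd.DataFrame(
        snp_int_rows, columns=["gene_id", "snp_id", "interaction_bf"]
    )

    n_sel, fdr = bayesian_fdr(
        post["pp_interaction"].to_numpy(), config.posterior_threshold
    )
    return {
        "posteriors": post,
        "priors": priors,
        "snp_table": snp_table,
        "snp_interaction": snp_int,
        "genes_without_snps": skipped,
        "n_selected": n_sel,
        "fdr_estimate": fdr,
    }


def map_lfc(
    expr: pd.DataFrame,
    gm: GenotypeMatrix,
    genes: pd.DataFrame,
    config: RunConfig | None = None,
):
    """Frequentist comparator: min-p log-fold-change scan with
    permutation FDR over the same cis windows."""
    config = config or RunConfig()
    gene_snps = map_cis_snps(genes, gm, config.cis_window_bp)
    individuals = [i for i in expression_individuals(expr) if i in gm.individuals]
    d_table = pd.DataFrame(
        {
            i: expr.xs((i, "treated"), axis=1) - expr.xs((i, "control"), axis=1)
            for i in individuals
        },
        index=expr.index,
    )
    return scan(
        d_table, gm, gene_snps, n_perms=config.n_permutations, seed=config.seed
    )
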