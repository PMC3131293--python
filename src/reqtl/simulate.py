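"""Synthetic genotype and paired-phenotype generator with known truth.

The generator is the forward model of the Bayes-factor engine's
likelihood.  For each individual *i* with dosage *x* at a gene's causal
SNP,

    y_C = beta_C * x + u_i + eps_C
    y_T = delta_g + beta_T * x + u_i + eps_T

with a shared individual component ``u ~ N(0, sigma_u2)`` that induces
the pairing correlation ``sigma_u2 / (sigma_u2 + sigma_e2)`` and
independent residuals ``eps ~ N(0, sigma_e2)``.  Each gene follows one
of the five interaction models drawn from ``pi_true``; model constraints
are honored exactly (an M2 gene has beta_C = 0, and so on).  Genotypes
are sampled per population under Hardy-Weinberg from configured
minor-allele-frequency ranges, with window SNPs tied to the causal SNP
by allele-copying LD.  Everything is a pure function of the config,
including its seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, orient_to_minor_allele, write_bed, write_vcf, write_expression

MODEL_NAMES = ("M0", "M1", "M2", "M3", "M4")


@dataclass
class SimConfig:
    """Study-shape and generative parameters.

    Defaults mirror a two-population panel of 57 + 57 individuals with
    paired treated/control measurements, 10 SNPs per cis window, a
    null-heavy model mixture, effect size 0.8 in units of the
    per-condition phenotype sd ``sqrt(sigma_u2 + sigma_e2)``, and pairing
    correlation 0.5.
    """

    n_per_pop: tuple[int, int] = (57, 57)
    pop_labels: tuple[str, str] = ("YRI", "TSI")
    n_genes: int = 500
    snps_per_window: int = 10
    maf_range: tuple[tuple[float, float], tuple[float, float]] = (
        (0.05, 0.5),
        (0.05, 0.5),
    )
    pi_true: tuple[float, ...] = (0.70, 0.20, 0.05, 0.03, 0.02)
    beta: float = 0.8               # units of sqrt(sigma_u2 + sigma_e2)
    effect_distribution: str = "normal"  # "normal": effects ~ N(0, (beta*sd_y)^2); "fixed": +/- beta*sd_y
    sigma_u2: float = 1.0           # shared individual component (pairing)
    sigma_e2: float = 1.0           # per-condition residual
    delta_sd: float = 0.5           # sd of the per-gene mean treatment shift
    covariate_effects: tuple[float, ...] = ()
    rho_ld: float = 0.5             # allele-copying probability to the causal SNP
    pop_response_effect: float = 0.0  # direct population x treatment shift (sd_y units)
    pop_response_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi_true, dtype=float)
        if pi.shape != (5,) or np.any(pi < 0) or not np.isclose(pi.sum(), 1.0):
            raise ValueError("pi_true must be a 5-component probability vector")
        if self.sigma_u2 <= 0 or self.sigma_e2 <= 0:
            raise ValueError("variance components must be positive")
        for lo, hi in self.maf_range:
            # frequencies are drawn from [lo, hi), so hi = 0.5 stays minor
            if not (0.0 < lo <= hi <= 0.5):
                raise ValueError("maf ranges must satisfy 0 < lo <= hi <= 0.5")
        if not (0.0 <= self.rho_ld <= 1.0):
            raise ValueError("rho_ld must lie in [0, 1]")

    @property
    def n_individuals(self) -> int:
        return sum(self.n_per_pop)

    @property
    def sd_y(self) -> float:
        """Per-condition phenotype sd at the null (effect-size unit)."""
        return float(np.sqrt(self.sigma_u2 + self.sigma_e2))


@dataclass
class SimTruth:
    """Per-gene generating model and effects."""

    table: pd.DataFrame  # indexed by gene_id

    def interacting(self) -> np.ndarray:
        return self.table["model"].isin(["M2", "M3", "M4"]).to_numpy()


@dataclass
class SimulatedStudy:
    expression: pd.DataFrame
    genotypes: GenotypeMatrix
    genes: pd.DataFrame
    covariates: pd.DataFrame
    truth: SimTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

GENE_SPACING = 1_000_000
GENE_LENGTH = 5_000


def _gene_layout(config: SimConfig) -> pd.DataFrame:
    starts = GENE_SPACING // 2 + GENE_SPACING * np.arange(config.n_genes)
    return pd.DataFrame(
        {
            "chrom": "1",
            "start": starts,
            "end": starts + GENE_LENGTH,
            "strand": "+",
        },
        index=pd.Index([f"gene{g:05d}" for g in range(config.n_genes)], name="gene_id"),
    )


def sim_genotypes(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Sample the SNP x individual dosage matrix for every cis window.

    Per window the central SNP is causal; every other SNP copies each of
    the causal SNP's two allele draws with probability ``rho_ld`` and
    otherwise redraws from its own population allele frequency.  Returns
    (genotypes, gene annotations, per-SNP truth frequencies).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = _gene_layout(config)
    n_pop = config.n_per_pop
    S = config.snps_per_window
    causal_offset = S // 2

    snp_ids, chroms, poss, freq_rows, dosage_rows, causal_ids = [], [], [], [], [], []
    pop_slices = [slice(0, n_pop[0]), slice(n_pop[0], n_pop[0] + n_pop[1])]
    for g, (gene_id, row) in enumerate(genes.iterrows()):
        center = (row.start + row.end) // 2
        positions = center - 50_000 + 10_000 * np.arange(S)
        freqs = np.stack(
            [rng.uniform(lo, hi, size=S) for (lo, hi) in config.maf_range]
        )  # pop x S
        # two allele draws per individual for every SNP, with LD copying
        alleles = np.empty((S, config.n_individuals, 2), dtype=np.int8)
        for p, sl in enumerate(pop_slices):
            n = n_pop[p]
            own = rng.random((S, n, 2)) < freqs[p, :, None, None]
            causal = own[causal_offset]
            copy = rng.random((S, n, 2)) < config.rho_ld
            copy[causal_offset] = True
            alleles[:, sl, :] = np.where(copy, causal[None], own)
        dos = alleles.sum(axis=2).astype(float)
        for s in range(S):
            snp_ids.append(f"{gene_id}_snp{s:02d}")
            chroms.append("1")
            poss.append(int(positions[s]) + 1)  # 1-based VCF position
            freq_rows.append((snp_ids[-1], gene_id, s == causal_offset,
                              freqs[0, s], freqs[1, s]))
        dosage_rows.append(dos)
        causal_ids.append(f"{gene_id}_snp{causal_offset:02d}")

    dosages = np.concatenate(dosage_rows, axis=0)
    dosages, flipped = orient_to_minor_allele(dosages)
    # truth frequencies must describe the allele the oriented dosage counts
    freq_rows = [
        (sid, gid, causal, 1.0 - f0 if flp else f0, 1.0 - f1 if flp else f1)
        for (sid, gid, causal, f0, f1), flp in zip(freq_rows, flipped)
    ]
    individuals = [
        f"{config.pop_labels[p]}{i:03d}"
        for p in (0, 1)
        for i in range(n_pop[p])
    ]
    populations = np.array(
        [config.pop_labels[0]] * n_pop[0] + [config.pop_labels[1]] * n_pop[1]
    )
    n_snps = len(snp_ids)
    gm = GenotypeMatrix(
        snp_ids=np.array(snp_ids),
        chrom=np.array(chroms),
        pos=np.array(poss, dtype=int),
        ref=np.array(["A"] * n_snps),
        alt=np.array(["G"] * n_snps),
        dosages=dosages,
        individuals=individuals,
        populations=populations,
        flipped=flipped,
    )
    snp_truth = pd.DataFrame(
        freq_rows, columns=["snp_id", "gene_id", "causal", "freq_pop0", "freq_pop1"]
    ).set_index("snp_id")
    genes = genes.copy()
    genes["causal_snp"] = causal_ids
    return gm, genes, snp_truth


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _draw_effects(
    config: SimConfig, models: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-condition true effects consistent with each gene's model.

    Under the default "normal" distribution each gene's effect is drawn
    from the analysis model's own effect prior, N(0, (beta*sd_y)^2) —
    the generative inverse of the Bayes-factor likelihood (M4 draws the
    two condition effects independently).  "fixed" instead uses a
    constant magnitude beta*sd_y with random sign, handy for moment
    checks on slopes.
    """
    scale = config.beta * config.sd_y
    n = models.size
    if config.effect_distribution == "normal":
        draw = rng.normal(0.0, scale, size=n)
    elif config.effect_distribution == "fixed":
        draw = rng.choice([-1.0, 1.0], size=n) * scale
    else:
        raise ValueError(f"unknown effect_distribution {config.effect_distribution!r}")
    beta_t = np.zeros(n)
    beta_c = np.zeros(n)
    m1 = models == 1
    beta_t[m1] = beta_c[m1] = draw[m1]
    m2 = models == 2
    beta_t[m2] = draw[m2]
    m3 = models == 3
    beta_c[m3] = draw[m3]
    m4 = models == 4
    if config.effect_distribution == "normal":
        beta_t[m4] = rng.normal(0.0, scale, size=int(m4.sum()))
    else:
        beta_t[m4] = draw[m4]
    beta_c[m4] = rng.normal(0.0, scale, size=int(m4.sum())) if config.effect_distribution == "normal" else rng.choice([-1.0, 1.0], size=int(m4.sum())) * scale
    return beta_t, beta_c


def sim_paired_expression(
    gm: GenotypeMatrix,
    genes: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Draw the paired expression table given genotypes and gene truth."""
    n = config.n_individuals
    snp_row = {s: k for k, s in enumerate(gm.snp_ids)}
    pop0_mask = (gm.populations == config.pop_labels[0]).astype(float)

    cov_term = np.zeros(n)
    if covariates is not None and config.covariate_effects:
        Z = covariates.to_numpy(dtype=float)
        cov_term = Z @ np.asarray(config.covariate_effects, dtype=float)

    treated = np.empty((config.n_genes, n))
    control = np.empty((config.n_genes, n))
    su = np.sqrt(config.sigma_u2)
    se = np.sqrt(config.sigma_e2)
    for g, (gene_id, row) in enumerate(genes.iterrows()):
        t = truth.loc[gene_id]
        x = gm.dosages[snp_row[row.causal_snp]]
        u = rng.normal(0.0, su, size=n)
        eps_c = rng.normal(0.0, se, size=n)
        eps_t = rng.normal(0.0, se, size=n)
        base = u + cov_term
        control[g] = t.beta_control * x + base + eps_c
        treated[g] = t.delta + t.beta_treated * x + base + eps_t
        if t.pop_effect != 0.0:
            treated[g] += t.pop_effect * pop0_mask
    cols = pd.MultiIndex.from_tuples(
        [(i, c) for i in gm.individuals for c in ("treated", "control")],
        names=["individual", "condition"],
    )
    data = np.empty((config.n_genes, 2 * n))
    data[:, 0::2] = treated
    data[:, 1::2] = control
    return pd.DataFrame(data, index=genes.index, columns=cols).sort_index(axis=1)


def simulate_dataset(config: SimConfig) -> SimulatedStudy:
    """Generate a full in-memory study bundle with truth labels."""
    rng = np.random.default_rng(config.seed)
    gm, genes, snp_truth = sim_genotypes(config, rng)

    models = rng.choice(5, size=config.n_genes, p=np.asarray(config.pi_true))
    beta_t, beta_c = _draw_effects(config, models, rng)
    delta = rng.normal(0.0, config.delta_sd, size=config.n_genes)
    pop_eff = np.zeros(config.n_genes)
    if config.pop_response_fraction > 0:
        hit = rng.random(config.n_genes) < config.pop_response_fraction
        pop_eff[hit] = config.pop_response_effect * config.sd_y

    causal = snp_truth[snp_truth["causal"]].reset_index().set_index("gene_id")
    f0 = causal.loc[genes.index, "freq_pop0"].to_numpy()
    f1 = causal.loc[genes.index, "freq_pop1"].to_numpy()
    # expected response difference (pop0 - pop1): genotype-driven plus direct
    pop_diff = 2.0 * (beta_t - beta_c) * (f0 - f1) + pop_eff

    truth_table = pd.DataFrame(
        {
            "model": [MODEL_NAMES[m] for m in models],
            "causal_snp": genes["causal_snp"],
            "beta_treated": beta_t,
            "beta_control": beta_c,
            "delta": delta,
            "pop_effect": pop_eff,
            "pop_response_diff": pop_diff,
        },
        index=genes.index,
    )

    n_cov = len(config.covariate_effects)
    cov = pd.DataFrame(
        rng.normal(size=(config.n_individuals, n_cov)),
        index=pd.Index(gm.individuals, name="individual"),
        columns=[f"cov{j}" for j in range(n_cov)],
    )
    expr = sim_paired_expression(gm, genes, truth_table, config, rng, cov)
    return SimulatedStudy(
        expression=expr,
        genotypes=gm,
        genes=genes.drop(columns=["causal_snp"]),
        covariates=cov,
        truth=SimTruth(truth_table),
        config=config,
    )


def sim_study(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete fixture bundle in the formats the readers consume.

    Produces expression.tsv (wide paired table), genotypes.vcf,
    genes.bed, covariates.tsv, populations.tsv, truth.tsv and
    manifest.json, all byte-reproducible from the config seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = simulate_dataset(config)
    paths = {
        "expression": out / "expression.tsv",
        "genotypes": out / "genotypes.vcf",
        "genes": out / "genes.bed",
        "covariates": out / "covariates.tsv",
        "populations": out / "populations.tsv",
        "truth": out / "truth.tsv",
        "manifest": out / "manifest.json",
    }
    write_expression(study.expression, paths["expression"])
    write_vcf(study.genotypes, paths["genotypes"])
    write_bed(study.genes, paths["genes"])
    study.covariates.to_csv(paths["covariates"], sep="\t", float_format="%.17g")
    pd.Series(
        study.genotypes.populations, index=study.genotypes.individuals, name="population"
    ).rename_axis("individual").to_csv(paths["populations"], sep="\t")
    study.truth.table.to_csv(paths["truth"], sep="\t", float_format="%.17g")
    cfg = dataclasses.asdict(config)
    paths["manifest"].write_text(json.dumps({"sim_config": cfg}, indent=2, default=list) + "\n")
    return paths
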