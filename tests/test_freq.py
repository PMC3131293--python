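import numpy as np
import pandas as pd
import pytest
from scipy import stats

from reqtl.config import RunConfig
from reqtl.freq import (
    de_test,
    empirical_fdr,
    lfc_assoc,
    permutation_null,
    scan,
    secretion_qtl,
)
from reqtl.pipeline import map_lfc
from reqtl.simulate import SimConfig, simulate_dataset


class TestDeTest:
    def test_identical_conditions_give_p_one(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(3, 10))
        expr = np.concatenate([vals, vals], axis=1)
        treatment = np.array([1.0] * 10 + [0.0] * 10)
        res = de_test(expr, treatment)
        np.testing.assert_allclose(res["t"], 0.0, atol=1e-10)
        np.testing.assert_allclose(res["p"], 1.0, atol=1e-9)

    def test_duplicated_treatment_column_rejected(self):
        rng = np.random.default_rng(1)
        t = np.array([1.0] * 5 + [0.0] * 5)
        with pytest.raises(ValueError, match="rank"):
            de_test(rng.normal(size=(2, 10)), t, covariates=t[:, None])

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        n = 24
        t = np.array([1.0] * 12 + [0.0] * 12)
        C = rng.normal(size=(n, 2))
        Y = rng.normal(size=(5, n)) + 0.4 * t
        res = de_test(Y, t, C)
        X = np.column_stack([np.ones(n), t, C])
        xtx_inv = np.linalg.inv(X.T @ X)
        for g in range(5):
            beta = xtx_inv @ X.T @ Y[g]
            resid = Y[g] - X @ beta
            dof = n - X.shape[1]
            se = np.sqrt(resid @ resid / dof * xtx_inv[1, 1])
            p = 2 * stats.t.sf(abs(beta[1] / se), dof)
            assert res["p"].iloc[g] == pytest.approx(p, abs=1e-10)


class TestEmpiricalFDR:
    def test_plain_ratio_examples(self):
        # empty null tail below the strong observed p
        fdr = empirical_fdr(
            np.array([1e-6, 0.5]), np.array([[0.3, 0.6]]), pseudocount=0
        )
        assert fdr[0] == 0.0
        # at t=0.5: one permutation value <= 0.5, two observed
        assert fdr[1] == pytest.approx(0.5)

    def test_pseudocount_guards_zero(self):
        fdr = empirical_fdr(np.array([1e-6, 0.5]), np.array([[0.3, 0.6]]))
        assert fdr[0] == pytest.approx(1.0)  # (1+0)/1 / 1

    def test_global_null_fdr_near_one(self):
        rng = np.random.default_rng(3)
        obs = rng.uniform(size=2000)
        perm = rng.uniform(size=(10, 2000))
        fdr = empirical_fdr(obs, perm)
        assert np.median(fdr) > 0.9

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        obs = rng.uniform(size=300) ** 2
        perm = rng.uniform(size=(5, 300))
        fdr = empirical_fdr(obs, perm)
        order = np.argsort(obs)
        assert np.all(np.diff(fdr[order]) >= -1e-12)


class TestLfcAssoc:
    def test_perfect_fit(self):
        x = np.array([0.0, 1.0, 2.0, 1.0, 0.0, 2.0])
        slope, p = lfc_assoc(2.0 * x, x)
        assert slope == pytest.approx(2.0)
        assert p <= 1e-300

    def test_orthogonal_gives_p_one(self):
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        d = np.array([1.0, 1.0, -2.0, -2.0, 1.0, 1.0])
        slope, p = lfc_assoc(d, x)
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_ols_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.binomial(2, 0.4, 40).astype(float)
        d = 0.3 * x + rng.normal(size=40)
        slope, p = lfc_assoc(d, x)
        ref = stats.linregress(x, d)
        assert slope == pytest.approx(ref.slope, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_constant_dosage_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            lfc_assoc(np.arange(6.0), np.ones(6))


class TestPermutationNull:
    def test_rounds_are_bijections_shared_across_genes(self):
        perms = permutation_null(20, 7, seed=1)
        assert perms.indices.shape == (7, 20)
        for row in perms.indices:
            assert np.array_equal(np.sort(row), np.arange(20))

    def test_seed_reproducibility(self):
        a = permutation_null(15, 4, seed=9).indices
        b = permutation_null(15, 4, seed=9).indices
        np.testing.assert_array_equal(a, b)


@pytest.fixture(scope="module")
def scan_inputs():
    study = simulate_dataset(
        SimConfig(n_genes=40, n_per_pop=(25, 25), snps_per_window=4, seed=3)
    )
    inds = study.genotypes.individuals
    d = pd.DataFrame(
        {
            i: study.expression.xs((i, "treated"), axis=1)
            - study.expression.xs((i, "control"), axis=1)
            for i in inds
        },
        index=study.expression.index,
    )
    from reqtl.io import map_cis_snps

    gene_snps = map_cis_snps(study.genes, study.genotypes, 100_000)
    return study, d, gene_snps


class TestScan:
    def test_single_snp_min_p_equals_lfc_assoc(self, scan_inputs):
        study, d, gene_snps = scan_inputs
        gene = d.index[0]
        one = {gene: gene_snps[gene][:1]}
        res, _ = scan(d.loc[[gene]], study.genotypes, one, n_perms=3, seed=0)
        x = study.genotypes.dosages[gene_snps[gene][0]]
        slope, p = lfc_assoc(d.loc[gene].to_numpy(), x)
        assert res.loc[gene, "min_p"] == pytest.approx(p, rel=1e-10)
        assert res.loc[gene, "slope"] == pytest.approx(slope, rel=1e-10)

    def test_min_p_invariant_to_snp_order(self, scan_inputs):
        study, d, gene_snps = scan_inputs
        rev = {g: idx[::-1] for g, idx in gene_snps.items()}
        a, _ = scan(d, study.genotypes, gene_snps, n_perms=2, seed=0)
        b, _ = scan(d, study.genotypes, rev, n_perms=2, seed=0)
        np.testing.assert_allclose(a["min_p"], b["min_p"], rtol=1e-12)

    def test_self_consistency_with_permuted_genotypes(self, scan_inputs):
        # pre-permuting the genotype labels with round r's reordering makes
        # the observed min-p equal that round's null min-p
        study, d, gene_snps = scan_inputs
        res, perms = scan(d, study.genotypes, gene_snps, n_perms=3, seed=7)
        r = 1
        gm_perm = study.genotypes.subset_individuals(
            [study.genotypes.individuals[k] for k in perms.indices[r]]
        )
        gm_perm.individuals = list(study.genotypes.individuals)
        res2, _ = scan(d, gm_perm, gene_snps, n_perms=0, seed=7)
        np.testing.assert_allclose(
            res2["min_p"].to_numpy(), perms.min_p[:, r], rtol=1e-9
        )

    def test_permutation_matrix_has_one_row_per_round(self, scan_inputs):
        study, d, gene_snps = scan_inputs
        _, perms = scan(d, study.genotypes, gene_snps, n_perms=5, seed=2)
        assert perms.indices.shape[0] == 5
        assert perms.min_p.shape == (len(d), 5)

    def test_empty_scope_reported_na(self, scan_inputs):
        study, d, gene_snps = scan_inputs
        gene = d.index[0]
        res, _ = scan(
            d.loc[[gene]], study.genotypes, {gene: np.empty(0, int)}, n_perms=2, seed=0
        )
        assert np.isnan(res.loc[gene, "min_p"])
        assert res.loc[gene, "n_snps_tested"] == 0

    def test_true_signals_enriched_at_low_fdr(self):
        # 500 genes, ~10% with strong treated-only effects
        study = simulate_dataset(
            SimConfig(
                n_genes=500, snps_per_window=3, seed=21,
                pi_true=(0.9, 0.0, 0.1, 0.0, 0.0), beta=1.2,
                effect_distribution="fixed",
            )
        )
        res, _ = map_lfc(
            study.expression, study.genotypes, study.genes,
            RunConfig(seed=21, n_permutations=20),
        )
        hits = res[res["fdr"] < 0.1]
        assert len(hits) > 5
        truth = study.truth.table
        frac_hits = truth.loc[hits.index, "model"].eq("M2").mean()
        base_rate = truth["model"].eq("M2").mean()
        assert frac_hits / base_rate >= 5.0


class TestSecretionQTL:
    def test_equals_scan_on_relabeled_inputs(self, scan_inputs):
        study, d, _ = scan_inputs
        proteins = d.iloc[:5].rename(index=lambda g: f"prot_{g}")
        protein_genes = study.genes.iloc[:5].rename(index=lambda g: f"prot_{g}")
        res, _ = secretion_qtl(
            proteins, study.genotypes, protein_genes, window=100_000,
            n_perms=4, seed=5,
        )
        from reqtl.io import map_cis_snps

        ref, _ = scan(
            proteins, study.genotypes,
            map_cis_snps(protein_genes, study.genotypes, 100_000),
            n_perms=4, seed=5,
        )
        pd.testing.assert_frame_equal(res, ref)

    def test_recovers_planted_secretion_qtl(self):
        study = simulate_dataset(
            SimConfig(
                n_genes=10, n_per_pop=(50, 50), snps_per_window=3, seed=8,
                pi_true=(0.0, 0.0, 1.0, 0.0, 0.0), beta=1.0,
                effect_distribution="fixed",
            )
        )
        inds = study.genotypes.individuals
        d = pd.DataFrame(
            {
                i: study.expression.xs((i, "treated"), axis=1)
                - study.expression.xs((i, "control"), axis=1)
                for i in inds
            },
            index=study.expression.index,
        )
        res, _ = secretion_qtl(
            d, study.genotypes, study.genes, window=100_000, n_perms=20, seed=8
        )
        assert (res["fdr"] < 0.2).mean() > 0.5
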