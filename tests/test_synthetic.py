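"""Generator: determinism, marginal moments, ModZ and GWAS/eQTL planting."""

import numpy as np
import pytest
from scipy.stats import kstest

from skinsynergy import synthetic, twas
from skinsynergy.io_formats import EqtlModel


def test_seed_mandatory_and_fraction_validation():
    with pytest.raises(ValueError):
        synthetic.SimConfig(fraction_de=1.2)
    with pytest.raises(ValueError):
        synthetic.SimConfig(seed=None)


def test_same_seed_bitwise_identical_counts():
    cfg = synthetic.SimConfig(n_genes=100, cell_types=("keratinocyte",), seed=4)
    a, _ = synthetic.simulate_counts(cfg)
    b, _ = synthetic.simulate_counts(cfg)
    np.testing.assert_array_equal(a.counts, b.counts)


def test_poisson_limit_column_means():
    # alpha = 0, no effects: column means ~ mu0 * sf within 3 sqrt(mu0/n)
    cfg = synthetic.SimConfig(
        n_genes=50, cell_types=("keratinocyte",), n_replicates=50,
        fraction_de=0.0, dispersion_log_mean=-30.0, dispersion_log_sd=0.0,
        mu0_log_mean=float(np.log(1000.0)), mu0_log_sd=0.0,
        size_factor_log_sd=0.0, seed=1,
    )
    expt, truth = synthetic.simulate_counts(cfg)
    col_means = expt.counts.mean(axis=0)
    sd = np.sqrt(1000.0 / 50)
    within = np.abs(col_means - 1000.0) < 3 * sd
    # ~0.3% of columns may exceed 3 SD by chance (200 columns here)
    assert within.mean() >= 0.98
    assert abs(col_means.mean() - 1000.0) < 3 * sd / np.sqrt(col_means.size)


def test_planted_log2fc_recovered_by_monte_carlo():
    # one gene with lfc_cga = 1 (log2): empirical CGA/control ratio ~ 2
    cfg = synthetic.SimConfig(
        n_genes=200, cell_types=("keratinocyte",), n_replicates=200,
        fraction_de=1.0, fraction_synergy_of_de=0.0, lfc_location=1.0,
        lfc_sd=0.0, dispersion_log_mean=float(np.log(0.05)),
        dispersion_log_sd=0.0, size_factor_log_sd=0.0, seed=1,
    )
    expt, truth = synthetic.simulate_counts(cfg)
    ctrl = np.array([s.treatment == "control" for s in expt.samples])
    cga = np.array([s.treatment == "CGA" for s in expt.samples])
    ratio = np.log2(
        expt.counts[:, cga].mean(axis=1) / expt.counts[:, ctrl].mean(axis=1)
    )
    observed = ratio * np.sign(truth.lfc_cga)
    assert observed.mean() == pytest.approx(1.0, abs=0.05)


def test_nb_marginal_variance_matches_parameterization():
    # Var = mu + alpha mu^2 within Monte-Carlo error over 500 replicates
    cfg = synthetic.SimConfig(
        n_genes=500, cell_types=("keratinocyte",), n_replicates=125,
        fraction_de=0.0, dispersion_log_mean=float(np.log(0.3)),
        dispersion_log_sd=0.0, mu0_log_mean=float(np.log(100.0)),
        mu0_log_sd=0.0, size_factor_log_sd=0.0, seed=2,
    )
    expt, truth = synthetic.simulate_counts(cfg)
    v = expt.counts.var(axis=1, ddof=1).mean()
    expected = 100.0 + 0.3 * 100.0**2
    assert v == pytest.approx(expected, rel=0.05)


class TestModZ:
    def test_concordant_up_gene_positive_at_all_doses(self):
        cfg = synthetic.SimConfig(n_genes=100, cell_types=("keratinocyte",), seed=3)
        rng = np.random.default_rng(3)
        truth = synthetic.simulate_truth(cfg, rng)
        modz = synthetic.simulate_modz(truth, seed=3)
        conc = truth.cmap_concordant
        signs = np.sign(truth.lfc_cga[conc])[:, None]
        assert np.all(np.sign(modz.to_numpy()[conc]) == signs)
        assert np.all(np.abs(modz.to_numpy()[conc]) > 2.0)

    def test_null_genes_standard_normal(self):
        cfg = synthetic.SimConfig(
            n_genes=1000, cell_types=("keratinocyte",), fraction_cmap_of_de=0.0,
            seed=3,
        )
        rng = np.random.default_rng(3)
        truth = synthetic.simulate_truth(cfg, rng)
        modz = synthetic.simulate_modz(truth, seed=3)
        stat = kstest(modz.iloc[:, 0].to_numpy(), "norm")
        assert stat.pvalue > 0.01

    def test_seed_determinism(self):
        cfg = synthetic.SimConfig(n_genes=50, cell_types=("keratinocyte",), seed=3)
        rng = np.random.default_rng(3)
        truth = synthetic.simulate_truth(cfg, rng)
        a = synthetic.simulate_modz(truth, seed=9)
        b = synthetic.simulate_modz(truth, seed=9)
        assert a.equals(b)

    def test_empty_doses_rejected(self):
        cfg = synthetic.SimConfig(n_genes=10, cell_types=("keratinocyte",), seed=3)
        rng = np.random.default_rng(3)
        truth = synthetic.simulate_truth(cfg, rng)
        with pytest.raises(ValueError, match="doses"):
            synthetic.simulate_modz(truth, doses=(), seed=1)


class TestGwasEqtl:
    def test_identity_ld_reproduces_target_exactly(self):
        w = np.array([0.5, -1.0, 2.0])
        z = synthetic.solve_gwas_z(w, np.eye(3), 4.0)
        model = EqtlModel(
            gene_id="G", variant_ids=["a", "b", "c"], weights=w, ld=np.eye(3)
        )
        assert twas.twas_z(model, z) == pytest.approx(4.0, abs=1e-9)

    def test_proximity_flags_match_planted_truth(self):
        cfg = synthetic.SimConfig(
            n_genes=20, cell_types=("keratinocyte",), fraction_de=0.5,
            fraction_gwas_of_de=0.5, seed=6,
        )
        rng = np.random.default_rng(6)
        truth = synthetic.simulate_truth(cfg, rng)
        ann = synthetic.simulate_annotation(truth, seed=6)
        gwas, _ = synthetic.simulate_gwas_and_eqtl(truth, ann, seed=6)
        from skinsynergy.prioritization import gwas_proximity

        for i, gid in enumerate(truth.gene_ids):
            flag, _, _ = gwas_proximity(ann[gid], gwas)
            assert flag == bool(truth.has_gwas_locus[i]), gid

    def test_gene_without_locus_has_no_near_significant_variant(self):
        cfg = synthetic.SimConfig(
            n_genes=30, cell_types=("keratinocyte",), fraction_gwas_of_de=0.0,
            seed=6,
        )
        rng = np.random.default_rng(6)
        truth = synthetic.simulate_truth(cfg, rng)
        ann = synthetic.simulate_annotation(truth, seed=6)
        gwas, _ = synthetic.simulate_gwas_and_eqtl(truth, ann, seed=6)
        sig = [g for g in gwas if g.pvalue < 5e-8]
        for gid in truth.gene_ids:
            a = ann[gid]
            for v in sig:
                if v.chrom == a.chrom:
                    d = min(abs(v.pos - a.start), abs(v.pos - a.end))
                    assert d > 500_000
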