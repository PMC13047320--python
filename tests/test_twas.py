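"""TWAS statistic, per-group BH, reliability filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from skinsynergy import twas
from skinsynergy.io_formats import EqtlModel, GwasSummary
from scipy.stats import norm


def _model(weights, ld=None, eqtl_z=None, gid="G1"):
    w = np.asarray(weights, dtype=float)
    k = w.size
    return EqtlModel(
        gene_id=gid,
        variant_ids=[f"v{gid}_{i}" for i in range(k)],
        weights=w,
        ld=np.eye(k) if ld is None else np.asarray(ld, dtype=float),
        eqtl_z=eqtl_z if eqtl_z is None else np.asarray(eqtl_z, dtype=float),
    )


class TestStatistic:
    def test_single_variant_identity(self):
        assert twas.twas_z(_model([1.0]), np.array([3.0])) == pytest.approx(3.0)

    def test_two_variant_hand_computation(self):
        z = twas.twas_z(_model([1.0, 1.0]), np.array([2.0, 2.0]))
        assert z == pytest.approx(4.0 / np.sqrt(2.0), abs=1e-6)

    def test_unit_weights_identity_ld_equals_mean_times_sqrt_k(self):
        rng = np.random.default_rng(20)
        zs = rng.normal(size=7)
        stat = twas.twas_z(_model(np.ones(7)), zs)
        assert stat == pytest.approx(zs.mean() * np.sqrt(7), abs=1e-10)

    def test_misaligned_z_raises(self):
        with pytest.raises(twas.AlignmentError):
            twas.twas_z(_model([1.0, 1.0]), np.array([1.0]))

    def test_degenerate_quadratic_form_returns_nan(self):
        # w orthogonal to LD row space: LD = outer product, w in null space
        ld = np.array([[1.0, -1.0], [-1.0, 1.0]])
        stat = twas.twas_z(_model([1.0, 1.0], ld=ld), np.array([1.0, 1.0]))
        assert np.isnan(stat)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance_and_sign_equivariance(self, c):
        rng = np.random.default_rng(22)
        w = rng.normal(size=4)
        z = rng.normal(size=4)
        base = twas.twas_z(_model(w), z)
        assert twas.twas_z(_model(c * w), z) == pytest.approx(base, rel=1e-9)
        assert twas.twas_z(_model(-w), z) == pytest.approx(-base, rel=1e-9)


class TestGroups:
    def _gwas(self, model, zs):
        return [
            GwasSummary(
                vid, "chr1", 1000 + i,
                pvalue=float(max(2 * norm.sf(abs(z)), 1e-300)), zscore=float(z),
            )
            for i, (vid, z) in enumerate(zip(model.variant_ids, zs))
        ]

    def test_bh_within_group_hand_computation(self):
        # build three single-variant genes with z giving p ~ [0.001, 0.04, 0.9]
        zs = [norm.isf(p / 2) for p in (0.001, 0.04, 0.9)]
        models = [_model([1.0], gid=f"g{i}") for i in range(3)]
        gwas = []
        for m, z in zip(models, zs):
            gwas += self._gwas(m, [z])
        res = twas.run_targeted_twas(
            [twas.TwasGroup("skin", "age", models, gwas)]
        )
        np.testing.assert_allclose(
            res["padj"], [0.003, 0.06, 0.9], rtol=1e-6
        )

    def test_groups_independent(self):
        zs = [3.29, 2.05, 0.13]
        models = [_model([1.0], gid=f"g{i}") for i in range(3)]
        gwas = []
        for m, z in zip(models, zs):
            gwas += self._gwas(m, [z])
        res = twas.run_targeted_twas(
            [
                twas.TwasGroup("skin", "age", models, gwas),
                twas.TwasGroup("leg", "age", models, gwas),
            ]
        )
        a = res[res["tissue"] == "skin"]["padj"].to_numpy()
        b = res[res["tissue"] == "leg"]["padj"].to_numpy()
        np.testing.assert_allclose(a, b)

    def test_gene_without_variants_skipped(self):
        models = [_model([1.0], gid="g0"), _model([1.0], gid="missing")]
        gwas = self._gwas(models[0], [1.0])
        res = twas.run_targeted_twas([twas.TwasGroup("s", "t", models, gwas)])
        assert list(res["gene_id"]) == ["g0"]
        assert res.attrs["skipped"] == [("s", "t", "missing")]

    def test_null_simulation_fdr_controlled(self):
        rng = np.random.default_rng(23)
        k = 3
        ld = 0.3 ** np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
        chol = np.linalg.cholesky(ld)
        models, gwas = [], []
        for i in range(500):
            w = rng.normal(size=k)
            z = chol @ rng.normal(size=k)  # z ~ MVN(0, LD)
            m = _model(w, ld=ld, gid=f"g{i}")
            models.append(m)
            gwas += self._gwas(m, z)
        res = twas.run_targeted_twas([twas.TwasGroup("s", "t", models, gwas)])
        frac = (res["padj"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 500)
        assert frac <= 0.05 + 3 * se


class TestReliability:
    def test_both_above_three_reliable(self):
        m = _model([1.0, 0.5], eqtl_z=[3.5, 1.0])
        zmap = {m.variant_ids[0]: 3.2, m.variant_ids[1]: 0.5}
        assert twas.reliability_filter(m, zmap) is True

    def test_gwas_below_three_not_reliable(self):
        m = _model([1.0, 0.5], eqtl_z=[3.5, 1.0])
        zmap = {m.variant_ids[0]: 2.9, m.variant_ids[1]: 0.5}
        assert twas.reliability_filter(m, zmap) is False

    def test_negative_scores_reliable_only_in_abs_mode(self):
        m = _model([1.0], eqtl_z=[-4.0])
        zmap = {m.variant_ids[0]: -4.0}
        assert twas.reliability_filter(m, zmap, mode="signed") is False
        assert twas.reliability_filter(m, zmap, mode="abs") is True

    def test_missing_eqtl_z_undefined(self):
        m = _model([1.0])
        assert twas.reliability_filter(m, {m.variant_ids[0]: 5.0}) is None

    def test_top_variant_is_largest_absolute_eqtl_z(self):
        m = _model([1.0, 1.0], eqtl_z=[2.0, -5.0])
        zmap = {m.variant_ids[0]: 9.0, m.variant_ids[1]: 9.0}
        # top is the second variant (|−5| > 2); signed mode fails on eqtl z
        assert twas.reliability_filter(m, zmap) is False
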