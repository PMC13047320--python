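"""Evidence integration: GWAS proximity, four-source OR, regulon filter."""

import numpy as np
import pandas as pd
import pytest

from skinsynergy import prioritization as pr
from skinsynergy.io_formats import GeneAnnotation, GwasSummary


def _gene(gid="G1", chrom="chr1", start=1_000_000, end=1_020_000, strand="+"):
    return GeneAnnotation(gid, gid, "protein_coding", chrom, start, end, strand)


def _variant(vid, pos, p=1e-9, chrom="chr1"):
    return GwasSummary(vid, chrom, pos, p)


class TestProximity:
    def test_variant_inside_gene_distance_zero(self):
        flag, vid, d = pr.gwas_proximity(_gene(), [_variant("v", 1_010_000)])
        assert flag and vid == "v" and d == 0

    def test_window_boundary_inclusive_and_strict(self):
        at = pr.gwas_proximity(_gene(), [_variant("v", 1_020_000 + 500_000)])
        beyond = pr.gwas_proximity(_gene(), [_variant("v", 1_020_000 + 500_001)])
        assert at[0] and not beyond[0]

    def test_non_significant_variant_ignored(self):
        flag, vid, _ = pr.gwas_proximity(
            _gene(), [_variant("v", 1_010_000, p=1e-6)]
        )
        assert not flag and vid == ""

    def test_tie_broken_by_smaller_p(self):
        variants = [
            _variant("worse", 1_000_000 - 100, p=1e-8),
            _variant("better", 1_020_000 + 100, p=1e-12),
        ]
        _, vid, d = pr.gwas_proximity(_gene(), variants)
        assert vid == "better" and d == 100

    def test_strand_independence(self):
        v = [_variant("v", 1_300_000)]
        a = pr.gwas_proximity(_gene(strand="+"), v)
        b = pr.gwas_proximity(_gene(strand="-"), v)
        assert a == b

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(14)
        genes = []
        for i in range(50):
            start = int(rng.integers(1, 5 * 10**7))
            genes.append(
                GeneAnnotation(
                    f"g{i}", f"g{i}", "protein_coding",
                    f"chr{rng.integers(1, 4)}", start, start + 20_000, "+",
                )
            )
        variants = [
            _variant(f"v{i}", int(rng.integers(1, 5 * 10**7)),
                     p=float(rng.choice([1e-9, 1e-6])),
                     chrom=f"chr{rng.integers(1, 4)}")
            for i in range(200)
        ]
        for g in genes:
            flag, _, _ = pr.gwas_proximity(g, variants)
            brute = any(
                v.pvalue < 5e-8
                and v.chrom == g.chrom
                and (
                    g.start <= v.pos <= g.end
                    or min(abs(v.pos - g.start), abs(v.pos - g.end)) <= 500_000
                )
                for v in variants
            )
            assert flag == brute, g.gene_id


class TestEvidence:
    def _ann(self, syms):
        return {s: _gene(s) for s in syms}

    def test_single_source_suffices(self):
        recs = pr.integrate_evidence(
            ["a"], aging_genes={"a"}, gwas=[], pathway_members=set(),
            drug_table=pd.DataFrame(columns=["gene", "drug"]),
            annotation=self._ann(["a"]),
        )
        assert recs[0].is_ardeg
        assert recs[0].in_aging_db
        assert not recs[0].near_gwas_locus

    def test_zero_evidence_not_ardeg(self):
        recs = pr.integrate_evidence(
            ["a"], set(), [], set(),
            pd.DataFrame(columns=["gene", "drug"]), self._ann(["a"]),
        )
        assert not recs[0].is_ardeg

    def test_monotone_adding_resource_never_unflags(self):
        base = pr.integrate_evidence(
            ["a", "b"], {"a"}, [], set(),
            pd.DataFrame(columns=["gene", "drug"]), self._ann(["a", "b"]),
        )
        more = pr.integrate_evidence(
            ["a", "b"], {"a"}, [], {"b"},
            pd.DataFrame({"gene": ["a"], "drug": ["tretinoin"]}),
            self._ann(["a", "b"]),
        )
        for r0, r1 in zip(base, more):
            assert (not r0.is_ardeg) or r1.is_ardeg

    def test_planted_truth_recovered(self):
        syms = [f"g{i}" for i in range(40)]
        rng = np.random.default_rng(15)
        planted = {s for s in syms if rng.uniform() < 0.3}
        recs = pr.integrate_evidence(
            syms, planted, [], set(),
            pd.DataFrame(columns=["gene", "drug"]), self._ann(syms),
        )
        assert {r.gene_id for r in recs if r.is_ardeg} == planted


class TestRegulons:
    def _table(self):
        return pd.DataFrame(
            {
                "tf": ["TF1", "TF1", "TF2", "TF1"],
                "target": ["t1", "t2", "t3", "t4"],
                "confidence": ["A", "B", "A", "A"],
            }
        )

    def test_grade_b_dropped_at_min_a(self):
        edges, _ = pr.build_regulons(
            {"TF1", "TF2", "t1", "t2", "t3", "t4"}, self._table()
        )
        kept = {(e.tf_symbol, e.target_symbol) for e in edges}
        assert kept == {("TF1", "t1"), ("TF2", "t3"), ("TF1", "t4")}

    def test_endpoints_must_be_in_gene_set(self):
        edges, _ = pr.build_regulons({"TF1", "t1"}, self._table())
        assert [(e.tf_symbol, e.target_symbol) for e in edges] == [("TF1", "t1")]

    def test_unknown_grade_rejected(self):
        bad = pd.DataFrame({"tf": ["x"], "target": ["y"], "confidence": ["Z"]})
        with pytest.raises(ValueError, match="Z"):
            pr.build_regulons({"x", "y"}, bad)

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(16)
        syms = [f"g{i}" for i in range(30)]
        table = pd.DataFrame(
            {
                "tf": rng.choice(syms, 100),
                "target": rng.choice(syms, 100),
                "confidence": rng.choice(["A", "B", "C"], 100),
            }
        )
        keep = set(rng.choice(syms, 15, replace=False))
        edges, _ = pr.build_regulons(keep, table)
        brute = {
            (r.tf, r.target, r.confidence)
            for r in table.itertuples()
            if r.confidence == "A" and r.tf in keep and r.target in keep
        }
        assert {(e.tf_symbol, e.target_symbol, e.confidence) for e in edges} == brute

    def test_sign_concordance_summary(self):
        edges, summary = pr.build_regulons(
            {"TF1", "t1", "t4"}, self._table(),
            log2fc={"TF1": -1.0, "t1": -0.5, "t4": 0.5},
        )
        row = summary[summary["tf"] == "TF1"]
        assert row["sign_concordance"].iloc[0] == pytest.approx(0.5)
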