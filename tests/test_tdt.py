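import numpy as np
import pandas as pd
import pytest

from trioscan.core import (
    ConsequenceClass,
    Thresholds,
    Trio,
    TrioCohort,
    VariantAnnotation,
)
from trioscan.panels import ExpressionTable, GenePanel
from trioscan.tdt import (
    TransmissionCount,
    count_transmissions,
    run_tdt,
    select_parental_variants,
    tdt_test,
)

from conftest import make_callset, make_site


def expressed_table(genes):
    cols = ["4wpc", "5wpc", "6wpc", "7wpc", "8wpc"]
    df = pd.DataFrame(5.0, index=list(genes), columns=cols)
    df.index.name = "gene"
    return ExpressionTable(df)


TRIO = Trio("P1", "FA1", "MO1")
SAMPLES = ["P1", "FA1", "MO1"]
COHORT = TrioCohort(trios=[TRIO], cases={"P1"}, controls=set())


def ann(gene="G1", consequence="missense_variant", af=0.0001):
    return VariantAnnotation(gene, consequence, "SNV", af, 25.0)


class TestSelectParentalVariants:
    def make(self, gts, annotation, qual=400.0):
        site = make_site(qual=qual, gts=gts)
        cs = make_callset(SAMPLES, [site])
        expr = expressed_table([annotation.gene])
        return select_parental_variants(cs, {site.key: annotation}, COHORT, expr)

    def test_het_parent_included(self):
        out = self.make((0, 1, 0), ann())
        assert len(out) == 1 and out[0].parent == "FA1"

    def test_hom_alt_parent_excluded(self):
        assert self.make((1, 2, 0), ann()) == []

    def test_inframe_indel_excluded(self):
        a = VariantAnnotation("G1", "inframe_insertion", "inframe_indel", 0.0, 10.0)
        assert self.make((0, 1, 0), a) == []

    def test_af_above_cutoff_excluded(self):
        assert self.make((0, 1, 0), ann(af=0.002)) == []

    def test_low_qual_excluded(self):
        assert self.make((0, 1, 0), ann(), qual=250.0) == []

    def test_unexpressed_gene_excluded(self):
        site = make_site(gts=(0, 1, 0))
        cs = make_callset(SAMPLES, [site])
        expr = expressed_table(["OTHER"])  # G1 unknown -> excluded
        assert select_parental_variants(cs, {site.key: ann()}, COHORT, expr) == []


class TestCountTransmissions:
    def run(self, gts):
        site = make_site(gts=gts)
        cs = make_callset(SAMPLES, [site])
        expr = expressed_table(["G1"])
        pvs = select_parental_variants(cs, {site.key: ann()}, COHORT, expr)
        counts = count_transmissions(pvs, cs)
        if not counts:
            return (0, 0)
        tc = counts[("G1", ConsequenceClass.missense)]
        return (tc.b, tc.c)

    def test_father_het_child_het(self):
        assert self.run((1, 1, 0)) == (1, 0)

    def test_father_het_child_homref(self):
        assert self.run((0, 1, 0)) == (0, 1)

    def test_double_het_child_het_splits(self):
        # allele-level: one transmitted, one untransmitted
        assert self.run((1, 1, 1)) == (1, 1)

    def test_double_het_child_homalt_two_transmissions(self):
        assert self.run((2, 1, 1)) == (2, 0)

    def test_double_het_child_homref_two_nontransmissions(self):
        assert self.run((0, 1, 1)) == (0, 2)

    def test_het_father_homalt_mother(self):
        # mother's allele is forced alt; child het means father did NOT transmit
        assert self.run((1, 1, 2)) == (0, 1)
        assert self.run((2, 1, 2)) == (1, 0)

    def test_child_missing_uninformative(self):
        assert self.run((-1, 1, 0)) == (0, 0)

    def test_panel_aggregation_and_additivity(self):
        sites = [
            make_site(pos=100, gts=(1, 1, 0)),
            make_site(pos=200, gts=(0, 1, 0)),
            make_site(pos=300, gts=(1, 1, 0)),
        ]
        cs = make_callset(SAMPLES, sites)
        anns = {
            sites[0].key: ann("GA"),
            sites[1].key: ann("GA"),
            sites[2].key: ann("GB"),
        }
        expr = expressed_table(["GA", "GB"])
        pvs = select_parental_variants(cs, anns, COHORT, expr)
        gene_counts = count_transmissions(pvs, cs)
        panels = [GenePanel("both", frozenset({"GA", "GB"}))]
        panel_counts = count_transmissions(pvs, cs, panels)
        tc = panel_counts[("both", ConsequenceClass.missense)]
        ga = gene_counts[("GA", ConsequenceClass.missense)]
        gb = gene_counts[("GB", ConsequenceClass.missense)]
        assert (tc.b, tc.c) == (ga.b + gb.b, ga.c + gb.c)


class TestTdtTest:
    def test_perfect_balance_chi2(self):
        stat, p = tdt_test(TransmissionCount("u", ConsequenceClass.LOF, 5, 5), "chi2")
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_binomial_five_zero(self):
        # two-sided exact: 2 * 0.5^5 = 0.0625
        _, p = tdt_test(TransmissionCount("u", ConsequenceClass.LOF, 5, 0), "binomial")
        assert p == pytest.approx(0.0625)

    def test_chi2_ten_zero(self):
        stat, _ = tdt_test(TransmissionCount("u", ConsequenceClass.LOF, 10, 0), "chi2")
        assert stat == pytest.approx(10.0)

    def test_zero_informative_raises(self):
        with pytest.raises(ValueError):
            tdt_test(TransmissionCount("u", ConsequenceClass.LOF, 0, 0))

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            tdt_test(TransmissionCount("u", ConsequenceClass.LOF, 3, 2), "fbat")


class TestRunTdt:
    def build(self, n_trios=8, gts_fn=None, af=0.0001):
        samples, trios = [], []
        for i in range(n_trios):
            trios.append(Trio(f"P{i}", f"F{i}", f"M{i}"))
            samples.extend((f"P{i}", f"F{i}", f"M{i}"))
        cohort = TrioCohort(
            trios=trios, cases={t.proband for t in trios}, controls=set()
        )
        gts = []
        for i in range(n_trios):
            gts.extend(gts_fn(i))
        site = make_site(gts=tuple(gts))
        cs = make_callset(samples, [site])
        anns = {site.key: ann("G1", af=af)}
        return cs, anns, cohort, expressed_table(["G1"])

    def test_gating_below_five(self):
        # 4 informative alleles -> untested
        cs, anns, cohort, expr = self.build(
            gts_fn=lambda i: (1, 1, 0) if i < 4 else (0, 0, 0)
        )
        th = Thresholds(recurrence=100)  # recurrence not under test here
        res = run_tdt(cs, anns, cohort, expr, consequence_class="missense", thresholds=th)
        assert len(res) == 1
        assert res[0].tested is False and res[0].p is None
        assert (res[0].b, res[0].c) == (4, 0)

    def test_single_tested_unit_q_equals_p(self):
        cs, anns, cohort, expr = self.build(
            gts_fn=lambda i: (1, 1, 0) if i < 5 else (0, 0, 0)
        )
        res = run_tdt(cs, anns, cohort, expr, consequence_class="missense")
        tested = [r for r in res if r.tested]
        assert len(tested) == 1
        assert tested[0].q == pytest.approx(tested[0].p)

    def test_tau_one_distortion_gives_zero_untransmitted(self):
        """With tau=1 every het-parent allele is transmitted: c == 0."""
        from trioscan.core import read_annotations, read_callset, read_pedigree
        from trioscan.panels import read_expression
        from trioscan.synthetic import SimConfig, simulate_cohort, write_fixture_bundle
        import tempfile
        from pathlib import Path

        cfg = SimConfig(
            n_trios=25,
            n_controls=0,
            n_genes=6,
            carrier_freq=0.3,
            denovo_rate=0.0,
            distortion_genes={"GENE0001": 1.0},
            unexpressed_fraction=0.0,
            n_common_variants=0,
            seed=5,
        )
        sim = simulate_cohort(cfg)
        with tempfile.TemporaryDirectory() as d:
            write_fixture_bundle(sim, Path(d) / "fix")
            cs = read_callset(Path(d) / "fix" / "callset.vcf")
            anns = read_annotations(Path(d) / "fix" / "annotations.tsv")
            cohort = read_pedigree(Path(d) / "fix" / "pedigree.tsv")
            expr = read_expression(Path(d) / "fix" / "expression.tsv")
        th = Thresholds(recurrence=1000)  # common in cohort by design
        for cclass in ("LOF", "missense"):
            pvs = [
                pv
                for pv in select_parental_variants(cs, anns, cohort, expr, th)
                if pv.gene == "GENE0001" and pv.consequence_class.value == cclass
            ]
            counts = count_transmissions(pvs, cs)
            for (unit, _), tc in counts.items():
                assert unit == "GENE0001"
                assert tc.c == 0
                assert tc.b > 0

    def test_deterministic_lexicographic_order(self):
        samples = ["P0", "F0", "M0"]
        trio = Trio("P0", "F0", "M0")
        cohort = TrioCohort(trios=[trio], cases={"P0"}, controls=set())
        sites = [make_site(pos=100 + i, gts=(1, 1, 0)) for i in range(6)]
        cs = make_callset(samples, sites)
        anns = {
            s.key: ann(gene, af=0.0001)
            for s, gene in zip(sites, ["GB", "GA", "GC", "GA", "GB", "GA"])
        }
        expr = expressed_table(["GA", "GB", "GC"])
        th = Thresholds(recurrence=100)
        res = run_tdt(cs, anns, cohort, expr, consequence_class="missense", thresholds=th)
        assert [r.unit for r in res] == sorted(r.unit for r in res)
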