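"""Instrument-selection cascade: unit rules and end-to-end behaviour."""

import pytest

from pqtlmr.instruments import (
    build_instruments,
    classify_cis_trans,
    cross_replicate,
    heterogeneity_z,
    in_mhc,
    multi_aptamer_filter,
    select_best_source,
    significant_union,
)
from pqtlmr.simulate import (
    SimScenario,
    make_layout,
    scenario_library,
    simulate_aptamer_panel,
    simulate_protein_gwas,
    simulate_reference_panel,
)
from pqtlmr.sumstats import GeneAnnotation, SumStats

from conftest import make_assoc


def _ss(label, assocs):
    ss = SumStats(study_label=label, trait_label="P1", trait_type="quantitative")
    for a in assocs:
        ss.add(a)
    return ss


class TestSignificantUnion:
    def test_union_semantics(self):
        a = _ss("A", [make_assoc(pval=1e-9)])
        b = _ss("B", [make_assoc(pval=0.3)])
        assert significant_union(a, b) == ["1:100:A:G"]

    def test_strict_inequality_at_threshold(self):
        a = _ss("A", [make_assoc(pval=5e-8)])
        b = _ss("B", [make_assoc(pval=5e-8)])
        assert significant_union(a, b) == []

    def test_significant_only_in_second_study(self):
        a = _ss("A", [make_assoc(pval=0.2)])
        b = _ss("B", [make_assoc(pval=4e-8)])
        assert significant_union(a, b) == ["1:100:A:G"]


class TestCrossReplicate:
    def test_replicates_with_consistent_direction(self):
        a = make_assoc(beta=0.30, pval=1e-12)
        b = make_assoc(beta=0.05, pval=0.03)
        assert cross_replicate(a, b) is True

    def test_opposite_direction_fails(self):
        a = make_assoc(beta=0.30)
        b = make_assoc(beta=-0.05, pval=0.001)
        assert cross_replicate(a, b) is False

    def test_p_exactly_005_fails(self):
        a = make_assoc(beta=0.30)
        b = make_assoc(beta=0.05, pval=0.05)
        assert cross_replicate(a, b) is False

    def test_swapped_alleles_aligned_before_comparison(self):
        a = make_assoc(beta=0.30)
        b = make_assoc(ea="G", oa="A", beta=-0.05, pval=0.01)  # same direction once flipped
        assert cross_replicate(a, b) is True

    def test_allele_set_mismatch_hard_error(self):
        with pytest.raises(ValueError, match="allele sets differ"):
            cross_replicate(make_assoc(ea="A", oa="G"), make_assoc(ea="A", oa="C"))


class TestHeterogeneityZ:
    def test_arithmetic(self):
        z = heterogeneity_z(make_assoc(beta=0.5, se=0.1), make_assoc(beta=0.2, se=0.1))
        assert z == pytest.approx(2.1213, abs=1e-4)

    def test_identical_records_zero(self):
        a = make_assoc(beta=0.5, se=0.1)
        assert heterogeneity_z(a, a) == 0.0

    def test_large_difference_exceeds_screen(self):
        z = heterogeneity_z(make_assoc(beta=0.6, se=0.1), make_assoc(beta=0.0, se=0.1))
        assert z == pytest.approx(4.2426, abs=1e-4)
        assert abs(z) >= 3.0


GENE = GeneAnnotation("P1", "GENE1", "1", 1_000_000, 1_050_000)


class TestCisTrans:
    @pytest.mark.parametrize(
        "chrom,pos,expected",
        [
            ("1", 500_000, "cis"),    # inclusive lower boundary
            ("1", 499_999, "trans"),
            ("1", 1_550_000, "cis"),  # inclusive upper boundary
            ("1", 1_550_001, "trans"),
            ("2", 1_020_000, "trans"),
        ],
    )
    def test_window(self, chrom, pos, expected):
        v = make_assoc(chrom=chrom, pos=pos)
        assert classify_cis_trans(v, GENE) == expected


class TestMhc:
    @pytest.mark.parametrize(
        "chrom,pos,expected",
        [
            ("6", 30_000_000, True),
            ("6", 26_000_000, True),
            ("6", 34_000_000, True),
            ("6", 25_999_999, False),
            ("7", 30_000_000, False),
        ],
    )
    def test_bounds(self, chrom, pos, expected):
        assert in_mhc(make_assoc(chrom=chrom, pos=pos)) is expected


class TestMultiAptamer:
    def test_five_or_more_excluded(self):
        amap = {"k1": {f"P{i}" for i in range(5)}, "k2": {f"P{i}" for i in range(4)}, "k3": {"P1"}}
        assert multi_aptamer_filter(amap) == {"k1"}


class TestBestSource:
    def test_argmin(self):
        a, b = make_assoc(pval=1e-10), make_assoc(pval=1e-8)
        rec, src = select_best_source(a, b, "deCODE", "Fenland")
        assert rec is a and src == "deCODE"

    def test_tie_goes_to_first_study(self):
        a, b = make_assoc(pval=1e-9), make_assoc(pval=1e-9)
        _, src = select_best_source(a, b, "deCODE", "Fenland")
        assert src == "deCODE"

    def test_single_study_passthrough(self):
        b = make_assoc(pval=1e-9)
        rec, src = select_best_source(None, b, "A", "B")
        assert rec is b and src == "B"

    def test_both_absent_hard_error(self):
        with pytest.raises(ValueError):
            select_best_source(None, None)


class TestBuildInstruments:
    def _run(self, seed=0, **kw):
        scn = scenario_library("null", seed=seed)
        layout = make_layout(scn)
        panel = simulate_reference_panel(scn, layout)
        sa, sb = simulate_protein_gwas(scn, layout)
        return build_instruments(sa, sb, layout.gene, panel, **kw), scn, layout

    def test_recovers_planted_cis_variants(self):
        iset, scn, layout = self._run(seed=1)
        causal_keys = {layout.keys[i] for i, _ in scn.causal_cis}
        assert {pq.key for pq in iset.cis} == causal_keys
        assert iset.trans == []

    def test_audit_sums_to_union(self):
        iset, _, _ = self._run(seed=2)
        assert iset.check_audit()

    def test_mhc_placement_empties_cis_list(self):
        scn = SimScenario(chrom="6", pos_start=29_000_000, seed=3)
        layout = make_layout(scn)
        panel = simulate_reference_panel(scn, layout)
        sa, sb = simulate_protein_gwas(scn, layout)
        iset = build_instruments(sa, sb, layout.gene, panel)
        assert iset.cis == []
        assert iset.audit["lost_mhc"] > 0

    def test_correlated_pair_clumped_to_one(self):
        # two causal variants in the same LD block at rho ~ 0.9
        scn = SimScenario(rho=0.9, causal_cis=((2, 0.02), (3, 0.02)), seed=4)
        layout = make_layout(scn)
        panel = simulate_reference_panel(scn, layout)
        sa, sb = simulate_protein_gwas(scn, layout)
        iset = build_instruments(sa, sb, layout.gene, panel)
        assert len(iset.cis) == 1
        assert iset.audit["lost_clumped"] > 0

    def test_multi_aptamer_variant_excluded_end_to_end(self):
        from pqtlmr.instruments import build_aptamer_map

        scn = scenario_library("multi_aptamer", seed=5)
        studies, genes, panel = simulate_aptamer_panel(scn)
        amap = build_aptamer_map(studies)
        shared_key = make_layout(scn).keys[scn.causal_cis[0][0]]
        assert len(amap[shared_key]) == 5
        for pid, (sa, sb) in studies.items():
            iset = build_instruments(sa, sb, genes[pid], panel, amap)
            assert shared_key not in {pq.key for pq in iset.all_instruments}

    def test_single_strong_replicated_pqtl_recovery_rate(self):
        """A single large-effect cis-pQTL is recovered in >= 95% of seeds."""
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            scn = SimScenario(
                n_variants=8, block_size=8, causal_cis=((4, 0.05),), n_panel=4000, seed=seed
            )
            layout = make_layout(scn)
            panel = simulate_reference_panel(scn, layout)
            sa, sb = simulate_protein_gwas(scn, layout)
            iset = build_instruments(sa, sb, layout.gene, panel)
            hits += [pq.key for pq in iset.cis] == [layout.keys[4]]
        assert hits >= 0.95 * n_seeds
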