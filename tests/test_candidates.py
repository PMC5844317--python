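import pandas as pd
import pytest

from balancerscan import MappingZone, MmpDatabase
from balancerscan import candidates as cand
from balancerscan import effects as fx
from balancerscan import filters as flt
from balancerscan import io
from balancerscan import simulate as sim


class TestAssignZone:
    zone = MappingZone("zA", "chr5", 1000, 2000)

    def test_containment(self):
        assert cand.assign_zone(("chr5", 1500), [self.zone]) == ["zA"]

    def test_closed_interval_boundaries(self):
        assert cand.assign_zone(("chr5", 2000), [self.zone]) == ["zA"]
        assert cand.assign_zone(("chr5", 2001), [self.zone]) == []
        assert cand.assign_zone(("chr5", 999), [self.zone]) == []

    def test_overlapping_deficiencies_both_reported(self):
        other = MappingZone("zB", "chr5", 1400, 2400)
        assert cand.assign_zone(("chr5", 1500), [self.zone, other]) == ["zA", "zB"]


class TestMmpTerminationCheck:
    def make_db(self, classes):
        db = MmpDatabase()
        for i, cls in enumerate(classes):
            db.add("chr1", 100 + i, "A", "G", cls, "g1")
        return db

    def test_missense_only_is_consistent(self):
        assert cand.mmp_termination_check("g1", self.make_db(["missense"] * 5))

    def test_any_chain_termination_fails(self):
        check = cand.mmp_termination_check(
            "g1", self.make_db(["missense"] * 5 + ["nonsense"])
        )
        assert not check and check.reason == "chain_terminating_present"

    def test_absent_gene_is_no_data(self):
        check = cand.mmp_termination_check("g2", self.make_db(["missense"]))
        assert not check and check.reason == "no_data"


class TestPairAlleles:
    def make(self, hits):
        return {
            g: cand.CandidateGene(g, strains=set(strains))
            for g, strains in hits.items()
        }

    def test_shared_gene_flagged(self):
        cands = self.make({"gX": {"S1", "S2"}})
        conflicts = cand.pair_alleles(cands, {"S1": "grp", "S2": "grp"})
        assert cands["gX"].second_allele and not conflicts

    def test_disjoint_genes_conflict(self):
        cands = self.make({"gX": {"S1"}, "gY": {"S2"}})
        conflicts = cand.pair_alleles(cands, {"S1": "grp", "S2": "grp"})
        assert set(conflicts) == {"gX", "gY"}
        assert not cands["gX"].second_allele

    def test_singleton_group_unflagged(self):
        cands = self.make({"gX": {"S1"}})
        assert cand.pair_alleles(cands, {"S1": "grp"}) == []
        assert not cands["gX"].second_allele


@pytest.fixture(scope="module")
def reference_module(reference, zones, dup_config, dup_cohort):
    genome, genes = reference
    cohort, truths, mmp = dup_cohort
    return genome, genes, zones, cohort, truths, mmp, dup_config


@pytest.fixture(scope="module")
def identified(reference_module):
    genome, genes, zones, cohort, truths, mmp, config = reference_module
    filtered, _ = flt.run_cascade(cohort, config, mmp)
    effects = fx.annotate_cohort(filtered, genome, genes)
    results, summary = cand.identify(
        filtered, effects, zones, mmp,
        groups=sim.groups_from_truth(truths),
        known_lethals={t.target_gene for t in truths},
        strain_zones=sim.strain_zones_from_truth(truths),
    )
    return filtered, truths, results, summary


class TestIdentify:
    def test_surviving_truth_genes_reach_high_confidence(self, identified):
        filtered, truths, results, _ = identified
        surviving_keys = {c.key for c in filtered.all_calls()}
        tiers = {c.gene_id: c.tier for c in results}
        for t in truths:
            if t.lethal_variant in surviving_keys:
                assert tiers[t.target_gene] == "identified_high_confidence"

    def test_without_zones_tiers_capped_at_candidate(self, reference_module):
        genome, genes, zones, cohort, truths, mmp, config = reference_module
        filtered, _ = flt.run_cascade(cohort, config, mmp)
        effects = fx.annotate_cohort(filtered, genome, genes)
        results, _ = cand.identify(
            filtered, effects, [], mmp,
            groups=sim.groups_from_truth(truths),
            known_lethals={t.target_gene for t in truths},
        )
        assert results  # candidates still produced
        assert all(c.tier != "identified_high_confidence" for c in results)

    def test_deterministic(self, reference_module):
        genome, genes, zones, cohort, truths, mmp, config = reference_module
        filtered, _ = flt.run_cascade(cohort, config, mmp)
        effects = fx.annotate_cohort(filtered, genome, genes)
        kwargs = dict(
            groups=sim.groups_from_truth(truths),
            known_lethals={t.target_gene for t in truths},
            strain_zones=sim.strain_zones_from_truth(truths),
        )
        r1, s1 = cand.identify(filtered, effects, zones, mmp, **kwargs)
        r2, s2 = cand.identify(filtered, effects, zones, mmp, **kwargs)
        assert [(c.gene_id, c.tier) for c in r1] == [
            (c.gene_id, c.tier) for c in r2
        ]
        assert s1.equals(s2)

    def test_summary_counts_additive(self, identified):
        _, _, _, summary = identified
        by = summary.set_index("alleles")
        assert (
            by.loc["single_allele", "genes"]
            + by.loc["two_or_more_alleles", "genes"]
            == by.loc["total", "genes"]
        )

    def test_high_confidence_invariant(self, identified):
        _, _, results, _ = identified
        for c in results:
            if c.tier == "identified_high_confidence":
                assert c.zone_concordant and c.secondary_evidence


class TestAggregateIdentified:
    def test_packaged_tally_totals_sixty_two(self):
        assert cand.aggregate_identified(io.load_identification_tally()) == 62

    def test_inconsistent_region_rejected(self):
        bad = pd.DataFrame(
            dict(region=["r1"], single_allele_identified=[3],
                 two_allele_identified=[4], total_identified=[8])
        )
        with pytest.raises(ValueError, match="r1"):
            cand.aggregate_identified(bad)
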