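"""Zone assignment and multi-evidence candidate-gene identification.

A filtered variant supports a gene when its consequence is coding or
splice-disrupting. Five lines of evidence are accumulated per gene as boolean
flags: concordance with the strain's genetically mapped zone, a second
independent allele in the same complementation group, absence of
chain-terminating alleles in the MMP-style database, a known lethal-phenotype
annotation, and experimental validation. A gene is identified with high
confidence when it is zone-concordant and at least one further line of
evidence supports it; genes hit outside their strain's mapped zone are kept
as candidates (zone assignments can be wrong), never discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .effects import VariantEffect
from .io import CohortTable, MappingZone, MmpDatabase, VariantKey

logger = logging.getLogger(__name__)

TIERS = ("identified_high_confidence", "candidate", "unresolved")

#: Consequence classes that make a variant count as hitting a gene.
DAMAGING = frozenset(
    {"missense", "nonsense", "start_loss", "stop_loss",
     "splice_donor", "splice_acceptor"}
)


@dataclass
class MmpCheck:
    consistent: bool
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.consistent


@dataclass
class CandidateGene:
    gene_id: str
    strains: set[str] = field(default_factory=set)
    variants: list[tuple[str, VariantKey, str]] = field(default_factory=list)
    zone_concordant: bool = False
    second_allele: bool = False
    mmp_consistent: bool = False
    known_lethal_annotation: bool = False
    validated_experimentally: bool = False
    tier: str = "unresolved"
    notes: list[str] = field(default_factory=list)

    @property
    def secondary_evidence(self) -> bool:
        return (
            self.second_allele
            or self.mmp_consistent
            or self.known_lethal_annotation
            or self.validated_experimentally
        )

    def any_evidence(self) -> bool:
        return self.zone_concordant or self.secondary_evidence


def assign_zone(variant, zones: list[MappingZone]) -> list[str]:
    """All zone ids whose interval contains the variant position.

    Zones may overlap (deficiencies do), so more than one id can come back;
    an empty list means the position is outside every zone.
    """
    chrom = getattr(variant, "chromosome", None) or variant[0]
    pos = getattr(variant, "position", None) or variant[1]
    return [z.zone_id for z in zones if z.contains(chrom, pos)]


def mmp_termination_check(gene_id: str, mmp: MmpDatabase) -> MmpCheck:
    """Essentiality-consistent MMP pattern: missense present, no truncations.

    A viable-strain mutation catalogue should recover missense alleles of an
    essential gene but select against nonsense/splice alleles. A gene absent
    from the catalogue is uninformative and fails the check with reason
    ``no_data``.
    """
    classes = mmp.gene_index().get(gene_id)
    if not classes:
        return MmpCheck(False, "no_data")
    if "missense" not in classes:
        return MmpCheck(False, "no_missense_records")
    if classes & {"nonsense", "splice"}:
        return MmpCheck(False, "chain_terminating_present")
    return MmpCheck(True)


def pair_alleles(
    candidates: dict[str, CandidateGene],
    groups: dict[str, str] | None,
) -> list[str]:
    """Set second-allele flags from complementation groups; return conflicts.

    A gene carried by >=2 strains of one group gains mutual validation. A
    multi-strain group whose strains hit only disjoint genes is a conflict:
    its genes are demoted to candidate downstream.
    """
    conflicts: list[str] = []
    if not groups:
        return conflicts
    strains_by_group: dict[str, set[str]] = {}
    for strain, group in groups.items():
        strains_by_group.setdefault(group, set()).add(strain)
    for group, strains in strains_by_group.items():
        if len(strains) < 2:
            continue
        hit_genes = {
            g.gene_id: g.strains & strains
            for g in candidates.values()
            if g.strains & strains
        }
        shared = [gid for gid, s in hit_genes.items() if len(s) >= 2]
        for gid in shared:
            candidates[gid].second_allele = True
        n_hit_strains = len(set().union(*hit_genes.values())) if hit_genes else 0
        if not shared and n_hit_strains >= 2:
            logger.warning(
                "complementation group %s: alleles hit disjoint genes %s",
                group, sorted(hit_genes),
            )
            for gid in hit_genes:
                candidates[gid].notes.append(f"allele_conflict:{group}")
                conflicts.append(gid)
    return conflicts


def identify(
    cohort_filtered: CohortTable,
    effects: dict[tuple[str, VariantKey], list[VariantEffect]],
    zones: list[MappingZone],
    mmp: MmpDatabase,
    groups: dict[str, str] | None = None,
    known_lethals: set[str] | None = None,
    *,
    strain_zones: dict[str, str] | None = None,
    validated: set[str] | None = None,
) -> tuple[list[CandidateGene], pd.DataFrame]:
    """Assemble per-gene evidence and assign confidence tiers.

    ``strain_zones`` maps each strain to its genetically determined zone;
    without it (or without zones) no gene can be zone-concordant, capping all
    tiers at candidate. Deterministic given its inputs.
    """
    known_lethals = known_lethals or set()
    validated = validated or set()
    candidates: dict[str, CandidateGene] = {}

    for call in cohort_filtered.all_calls():
        for effect in effects.get((call.strain_id, call.key), []):
            if effect.consequence not in DAMAGING or effect.gene_id is None:
                continue
            cand = candidates.setdefault(effect.gene_id,
                                         CandidateGene(effect.gene_id))
            cand.strains.add(call.strain_id)
            cand.variants.append((call.strain_id, call.key, effect.consequence))
            if zones and strain_zones:
                mapped = strain_zones.get(call.strain_id)
                if mapped and mapped in assign_zone(call, zones):
                    cand.zone_concordant = True

    for cand in candidates.values():
        cand.mmp_consistent = bool(mmp_termination_check(cand.gene_id, mmp))
        cand.known_lethal_annotation = cand.gene_id in known_lethals
        cand.validated_experimentally = cand.gene_id in validated

    conflicted = set(pair_alleles(candidates, groups))

    for cand in candidates.values():
        if (
            cand.zone_concordant
            and cand.secondary_evidence
            and cand.gene_id not in conflicted
        ):
            cand.tier = "identified_high_confidence"
        elif cand.any_evidence() or cand.gene_id in conflicted:
            cand.tier = "candidate"
        else:
            cand.tier = "unresolved"

    ordered = sorted(candidates.values(), key=lambda c: c.gene_id)
    return ordered, identification_summary(ordered, cohort_filtered)


def identification_summary(
    candidates: list[CandidateGene], cohort: CohortTable | None = None
) -> pd.DataFrame:
    """Screen-bookkeeping layout: per-tier gene counts by allele multiplicity."""
    rows = []
    for n_alleles, label in ((1, "single_allele"), (2, "two_or_more_alleles")):
        subset = [
            c for c in candidates
            if (len(c.strains) >= 2) == (n_alleles == 2)
        ]
        rows.append(
            dict(
                alleles=label,
                genes=len(subset),
                identified=sum(
                    c.tier == "identified_high_confidence" for c in subset
                ),
                candidate=sum(c.tier == "candidate" for c in subset),
            )
        )
    frame = pd.DataFrame(rows)
    total = dict(
        alleles="total",
        genes=frame.genes.sum(),
        identified=frame.identified.sum(),
        candidate=frame.candidate.sum(),
    )
    frame = pd.concat([frame, pd.DataFrame([total])], ignore_index=True)
    if cohort is not None:
        hit = set().union(*(c.strains for c in candidates)) if candidates else set()
        frame.attrs["unresolved_strains"] = sorted(set(cohort.strains) - hit)
    return frame


def aggregate_identified(tally: pd.DataFrame) -> int:
    """Total genes identified across regions of a per-region tally table.

    Checks internal additivity (single-allele + two-allele identified counts
    must equal each region's printed total) before summing.
    """
    per_region = (
        tally["single_allele_identified"] + tally["two_allele_identified"]
    )
    mismatch = per_region != tally["total_identified"]
    if mismatch.any():
        bad = tally.loc[mismatch, "region"].tolist()
        raise ValueError(f"inconsistent per-region tallies for {bad}")
    return int(per_region.sum())


def recovery_against_truth(candidates: list[CandidateGene], truths) -> float:
    """Fraction of truth target genes identified at high confidence."""
    target = {t.target_gene for t in truths}
    high = {
        c.gene_id for c in candidates if c.tier == "identified_high_confidence"
    }
    return len(target & high) / len(target) if target else float("nan")
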