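"""The filtration cascade applied to cohort variant tables.

Four per-variant predicates, applied in the reporting order
VAF window -> MMP database -> background recurrence -> strand support.
Background recurrence is always computed on the raw cohort, before any other
filter, so the final set is the intersection of the four predicates and does
not depend on the order in which they are applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .balancer import BalancerConfig
from .errors import BalancerScanError
from .io import CohortTable, MmpDatabase, VariantCall, VariantKey

STEPS = ("vaf_window", "mmp", "background", "strand_support")


@dataclass
class FilterReport:
    """Per-step, per-strain survivor counts plus one removal reason per call."""

    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    removal_reasons: dict[tuple[str, VariantKey], str] = field(default_factory=dict)

    def step_totals(self) -> dict[str, int]:
        return {step: sum(per.values()) for step, per in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        """Table-style layout: one row per strain, one column per step."""
        frame = pd.DataFrame(self.counts)
        frame.index.name = "strain_id"
        frame.loc["mean_per_strain"] = frame.mean(axis=0)
        return frame

    def check_consistent(self) -> None:
        """Counts must be non-increasing and sum-consistent with reasons."""
        totals = self.step_totals()
        ordered = ["input", *STEPS]
        for a, b in zip(ordered, ordered[1:]):
            if totals[b] > totals[a]:
                raise BalancerScanError(
                    f"survivor count increased from {a} to {b}"
                )
        removed = totals["input"] - totals[STEPS[-1]]
        if removed != len(self.removal_reasons):
            raise BalancerScanError(
                f"{removed} calls removed but {len(self.removal_reasons)} "
                "removal reasons recorded"
            )


def vaf_predicate(window: tuple[float, float]):
    low, high = window
    return lambda call: low <= call.vaf <= high


def mmp_predicate(mmp: MmpDatabase):
    keys = mmp.keys()
    return lambda call: call.key not in keys


def background_predicate(cohort: CohortTable, min_recurrence: int = 2):
    """Predicate from the RAW cohort's recurrence index.

    A variant seen at identical (chrom, pos, ref, alt) in >= ``min_recurrence``
    distinct strains is presumed to come from the shared starting strain and
    is removed from every strain.
    """
    if min_recurrence < 2:
        raise ValueError("min_recurrence must be >= 2")
    recurrent = {
        key for key, n in cohort.recurrence().items() if n >= min_recurrence
    }
    return lambda call: call.key not in recurrent


def support_predicate(min_reads_per_strand: int = 8):
    return lambda call: (
        call.alt_forward >= min_reads_per_strand
        and call.alt_reverse >= min_reads_per_strand
    )


def filter_vaf(cohort: CohortTable, window: tuple[float, float]) -> CohortTable:
    """Keep calls whose VAF lies inside the inclusive window."""
    return cohort.filtered(vaf_predicate(window))


def filter_mmp(cohort: CohortTable, mmp: MmpDatabase) -> CohortTable:
    """Drop calls whose exact (chrom, pos, ref, alt) occurs in the database."""
    return cohort.filtered(mmp_predicate(mmp))


def filter_background(cohort: CohortTable, min_recurrence: int = 2) -> CohortTable:
    """Drop calls recurring in >= min_recurrence strains of this cohort."""
    return cohort.filtered(background_predicate(cohort, min_recurrence))


def filter_support(cohort: CohortTable, min_reads_per_strand: int = 8) -> CohortTable:
    """Keep calls with enough alt-supporting reads on BOTH strands."""
    return cohort.filtered(support_predicate(min_reads_per_strand))


def run_cascade(
    cohort: CohortTable,
    config: BalancerConfig,
    mmp: MmpDatabase,
    *,
    min_recurrence: int = 2,
    min_reads_per_strand: int = 8,
) -> tuple[CohortTable, FilterReport]:
    """Apply the full cascade with per-step bookkeeping.

    Every removed call is charged to exactly one primary reason: the first
    step of the reporting order whose predicate it fails.
    """
    predicates = {
        "vaf_window": vaf_predicate(config.vaf_window),
        "mmp": mmp_predicate(mmp),
        "background": background_predicate(cohort, min_recurrence),
        "strand_support": support_predicate(min_reads_per_strand),
    }
    report = FilterReport()
    report.counts["input"] = cohort.counts_per_strain()
    current = cohort
    for step in STEPS:
        pred = predicates[step]
        survivors: dict[str, list[VariantCall]] = {}
        for strain in current.strains:
            kept = []
            for call in current.calls(strain):
                if pred(call):
                    kept.append(call)
                else:
                    report.removal_reasons[(strain, call.key)] = step
            survivors[strain] = kept
        current = CohortTable(survivors)
        report.counts[step] = current.counts_per_strain()
    report.check_consistent()
    return current, report
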