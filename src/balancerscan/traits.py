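"""Downstream characterization of essential-gene traits.

Conservation tallies over clade-presence flags, paralog-based duplicability,
protein-interaction connectivity, developmental expression summaries,
group-proportion comparisons by Fisher's exact test, conservation of the
100-residue window around a missense site in a multiple alignment, and the
N-terminal bias statistic for nonsense mutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError

logger = logging.getLogger(__name__)

CONSERVATION_CATEGORIES = ("N", "N+I+M", "N+I+M+F", "other")


def conservation_category(n: bool, i: bool, m: bool, f: bool) -> str:
    if n and not i and not m and not f:
        return "N"
    if n and i and m and not f:
        return "N+I+M"
    if n and i and m and f:
        return "N+I+M+F"
    return "other"


def conservation_tally(records: pd.DataFrame) -> dict[str, int]:
    """Counts per conservation category from clade-presence flags N/I/M/F."""
    counts = dict.fromkeys(CONSERVATION_CATEGORIES, 0)
    for row in records.itertuples(index=False):
        cat = conservation_category(
            bool(row.N), bool(row.I), bool(row.M), bool(row.F)
        )
        if cat == "other":
            logger.warning("unexpected clade combination for %s", row[0])
        counts[cat] += 1
    return counts


def conservation_percentages(counts: dict[str, int]) -> dict[str, float]:
    total = sum(counts.values())
    return {k: 100.0 * v / total for k, v in counts.items()} if total else {}


# ------------------------------------------------------------------ paralogs

def classify_duplicability(
    paralogs: pd.DataFrame,
    pid_threshold: float = 50.0,
    evalue_threshold: float = 1e-20,
    genes: list[str] | None = None,
) -> dict[str, str]:
    """'duplicate' iff the gene has a pair with PID >= and e-value <= thresholds.

    ``genes`` fixes the classified universe; genes without any qualifying pair
    (including genes absent from the pair table) are singletons.
    """
    strong = paralogs[
        (paralogs["percent_identity"] >= pid_threshold)
        & (paralogs["e_value"] <= evalue_threshold)
    ]
    duplicated = set(strong["gene_a"]) | set(strong["gene_b"])
    if genes is None:
        genes = sorted(set(paralogs["gene_a"]) | set(paralogs["gene_b"]))
    return {g: ("duplicate" if g in duplicated else "singleton") for g in genes}


# ------------------------------------------------------------------ Fisher

def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table of nonnegative counts.

    Sums hypergeometric probabilities of all tables with the same margins
    whose probability does not exceed the observed table's.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be nonnegative")
    n_total = a + b + c + d
    if n_total == 0:
        raise DegenerateInputError("all-zero 2x2 table")
    row1, col1 = a + b, a + c
    support = np.arange(max(0, col1 - (n_total - row1)), min(row1, col1) + 1)
    pmf = stats.hypergeom.pmf(support, n_total, row1, col1)
    p_obs = pmf[support == a][0]
    return float(np.clip(pmf[pmf <= p_obs * (1 + 1e-9)].sum(), 0.0, 1.0))


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def group_proportion_compare(
    trait: dict[str, bool],
    groups: pd.DataFrame,
    reference: str = "G1",
) -> pd.DataFrame:
    """Proportion of trait-positive genes per group, Fisher vs the reference.

    The contingency layout per comparison is (trait-positive, trait-negative)
    x (reference group, other group), restricted to genes the trait covers.
    Groups with no covered genes are skipped with a warning.
    """
    per_group: dict[str, tuple[int, int]] = {}
    for name, sub in groups.groupby("group"):
        covered = [g for g in sub["gene_id"] if g in trait]
        pos = sum(bool(trait[g]) for g in covered)
        per_group[name] = (pos, len(covered) - pos)
    if reference not in per_group or sum(per_group[reference]) == 0:
        raise DegenerateInputError(f"reference group {reference!r} is empty")

    rows = []
    ref_pos, ref_neg = per_group[reference]
    for name in sorted(per_group):
        pos, neg = per_group[name]
        if pos + neg == 0:
            logger.warning("group %s covers no genes; comparison skipped", name)
            continue
        row = dict(
            group=name,
            n=pos + neg,
            proportion=pos / (pos + neg),
            p_value=np.nan,
            stars="",
        )
        if name != reference:
            p = fisher_exact_2x2([[ref_pos, ref_neg], [pos, neg]])
            row["p_value"] = p
            row["stars"] = significance_stars(p)
        rows.append(row)
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ connectivity

CONNECTIVITY_BINS = ("1", "2-5", "6-10", ">10")


def _bin_interactors(count: int) -> str | None:
    if count <= 0:
        return None
    if count == 1:
        return "1"
    if count <= 5:
        return "2-5"
    if count <= 10:
        return "6-10"
    return ">10"


def connectivity_summary(
    interactions: pd.DataFrame,
    groups: pd.DataFrame,
    reference: str = "G1",
) -> pd.DataFrame:
    """Binned interactor distributions per group plus hub-fraction tests.

    Bins follow the hub convention (1, 2-5, 6-10, >10 partners); genes with
    zero recorded interactors are excluded from the bins and reported.
    The >10 (hub) fraction of each group is compared with the reference by
    Fisher's exact test on the (hub, non-hub) x (group, reference) table.
    """
    if interactions.empty:
        logger.warning("empty interaction table")
    counts = dict(zip(interactions.get("gene_id", []),
                      interactions.get("interactors", [])))
    rows = []
    per_group_hub: dict[str, tuple[int, int]] = {}
    for name, sub in groups.groupby("group"):
        binned = {b: 0 for b in CONNECTIVITY_BINS}
        n_zero = 0
        covered = 0
        for g in sub["gene_id"]:
            if g not in counts:
                continue
            label = _bin_interactors(int(counts[g]))
            if label is None:
                n_zero += 1
                continue
            covered += 1
            binned[label] += 1
        hub = binned[">10"]
        per_group_hub[name] = (hub, covered - hub)
        row = dict(group=name, n=covered, n_zero_interactors=n_zero)
        for b in CONNECTIVITY_BINS:
            row[f"frac_{b}"] = binned[b] / covered if covered else 0.0
        rows.append(row)
    frame = pd.DataFrame(rows)
    p_values, star = [], []
    for row in frame.itertuples(index=False):
        if row.group == reference or frame.empty:
            p_values.append(np.nan)
            star.append("")
            continue
        ref_hub = per_group_hub.get(reference, (0, 0))
        grp_hub = per_group_hub[row.group]
        if sum(ref_hub) == 0 or sum(grp_hub) == 0:
            p_values.append(np.nan)
            star.append("")
            continue
        p = fisher_exact_2x2([list(ref_hub), list(grp_hub)])
        p_values.append(p)
        star.append(significance_stars(p))
    frame["hub_p_vs_" + reference] = p_values
    frame["stars"] = star
    return frame


# ------------------------------------------------------------------ expression

def expression_summary(
    matrix: pd.DataFrame,
    groups: pd.DataFrame,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, float | None]]:
    """Per-stage, per-group log2-RPKM quartiles and a linear trend slope.

    Columns of ``matrix`` are developmental stages in temporal order; values
    are RPKM, transformed as log2(RPKM + pseudocount). The slope is the OLS
    slope of per-stage medians against the stage index; with a single stage
    it is undefined (None).
    """
    log = np.log2(matrix + pseudocount)
    stages = list(matrix.columns)
    rows = []
    slopes: dict[str, float | None] = {}
    for name, sub in groups.groupby("group"):
        members = [g for g in sub["gene_id"] if g in log.index]
        missing = len(sub) - len(members)
        medians = []
        for si, stage in enumerate(stages):
            values = log.loc[members, stage].dropna()
            med = float(values.median()) if len(values) else np.nan
            medians.append(med)
            rows.append(
                dict(group=name, stage=stage, stage_index=si,
                     n=len(values), n_missing=missing, median=med,
                     q1=float(values.quantile(0.25)) if len(values) else np.nan,
                     q3=float(values.quantile(0.75)) if len(values) else np.nan)
            )
        if len(stages) < 2:
            slopes[name] = None
        else:
            x = np.arange(len(stages), dtype=float)
            y = np.asarray(medians, dtype=float)
            ok = ~np.isnan(y)
            slopes[name] = (
                float(np.polyfit(x[ok], y[ok], 1)[0]) if ok.sum() >= 2 else None
            )
    return pd.DataFrame(rows), slopes


# ------------------------------------------------------------------ alignment window

@dataclass
class WindowConservation:
    columns: np.ndarray          # alignment column indices (1-based) in window
    identities: np.ndarray       # per-column identity fraction vs reference
    window_mean: float
    conserved: bool


def window_conservation(
    alignment,
    mutated_position: int,
    window: int = 100,
    threshold: float = 0.7,
) -> WindowConservation:
    """Conservation of the residue window around a mutated alignment column.

    ``alignment`` is a list of aligned sequences (strings or SeqRecords); the
    first row is the reference. The window covers 50 columns upstream of the
    mutated column, the column itself, and 49 downstream (clipped at the
    alignment ends). Per-column identity is the fraction of non-reference
    rows carrying the reference residue, with gapped rows excluded from the
    denominator.
    """
    seqs = [str(getattr(rec, "seq", rec)).upper() for rec in alignment]
    if len(seqs) < 2:
        raise ValueError("alignment needs a reference and at least one ortholog")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("alignment rows have unequal lengths")
    if not 1 <= mutated_position <= length:
        raise IndexError(
            f"mutated column {mutated_position} outside alignment of "
            f"length {length}"
        )
    half_up = window // 2
    lo = max(0, mutated_position - 1 - half_up)
    hi = min(length, mutated_position + (window - half_up - 1))
    cols = np.arange(lo, hi)
    reference = seqs[0]
    identities = np.empty(len(cols))
    for k, col in enumerate(cols):
        ref_res = reference[col]
        residues = [s[col] for s in seqs[1:] if s[col] != "-"]
        if ref_res == "-" or not residues:
            identities[k] = np.nan
            continue
        identities[k] = sum(r == ref_res for r in residues) / len(residues)
    mean = float(np.nanmean(identities))
    return WindowConservation(
        columns=cols + 1,
        identities=identities,
        window_mean=mean,
        conserved=mean >= threshold,
    )


# ------------------------------------------------------------------ nonsense position

@dataclass
class RankComparison:
    class_means: dict[str, float]
    n: dict[str, int]
    statistic: float | None
    p_value: float | None
    skipped: bool = False
    reason: str | None = None


def nonsense_position_stat(
    effects,
    n_permutations: int = 10_000,
    seed: int = 0,
    classes: tuple[str, str] = ("nonsense", "missense"),
) -> RankComparison:
    """Mean relative CDS position per class and a permutation rank test.

    Compares the relative positions of the two classes (by default nonsense
    vs missense) with a two-sided rank-sum statistic whose null distribution
    is generated by ``n_permutations`` seeded label permutations. A class
    with fewer than two observations skips the comparison.
    """
    positions: dict[str, list[float]] = {}
    for e in effects:
        if e.relative_position is not None:
            positions.setdefault(e.consequence, []).append(e.relative_position)
    means = {
        cls: float(np.mean(vals)) for cls, vals in positions.items() if vals
    }
    counts = {cls: len(vals) for cls, vals in positions.items()}
    x = positions.get(classes[0], [])
    y = positions.get(classes[1], [])
    if len(x) < 2 or len(y) < 2:
        return RankComparison(
            class_means=means, n=counts, statistic=None, p_value=None,
            skipped=True, reason=f"need >=2 observations in each of {classes}",
        )
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    n1 = len(x)
    expected = n1 * (len(combined) + 1) / 2.0
    observed = float(ranks[:n1].sum())
    rng = np.random.default_rng(seed)
    perm = np.tile(ranks, (n_permutations, 1))
    perm = rng.permuted(perm, axis=1)
    perm_stats = perm[:, :n1].sum(axis=1)
    extreme = np.abs(perm_stats - expected) >= abs(observed - expected) - 1e-12
    p = (1.0 + int(extreme.sum())) / (n_permutations + 1.0)
    return RankComparison(
        class_means=means, n=counts, statistic=observed, p_value=float(p)
    )
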