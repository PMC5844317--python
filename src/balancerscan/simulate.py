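"""Synthetic balanced-lethal screen: genome, strains, and trait tables.

The simulator emulates the statistical structure of a whole-genome-sequenced
balancer screen: a small reference genome with intron-containing gene models,
a designated balanced region subdivided into genetic mapping zones, a cohort
of strains each carrying exactly one true lethal SNV in a balanced-region gene
(read counts binomially sampled at the genotype-determined expected VAF),
shared background variants inherited from the common starting strain, a
sprinkle of strain-private neutral calls, and an MMP-style population-variant
database biased against chain-terminating alleles in essential genes.

All randomness flows from a single ``numpy`` generator seeded by the caller;
re-running with the same arguments reproduces identical outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import effects as fx
from .balancer import BalancerConfig, expected_vaf
from .errors import ConfigurationError, SizingError
from .genome import GeneModel, ReferenceGenome, revcomp
from .io import CohortTable, MappingZone, MmpDatabase, VariantCall

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in _STOPS
]
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: Mean genome coverages of the two screen designs.
DEFAULT_DEPTH = {"duplication": 25, "translocation": 31}

_MIN_GENE_GAP = 60  # bp kept free on both sides of every gene


@dataclass
class StrainTruth:
    """Ground-truth record for one simulated strain."""

    strain_id: str
    lethal_variant: tuple[str, int, str, str]
    target_gene: str
    zone_id: str
    group_id: str
    consequence: str
    background_variant_ids: list = field(default_factory=list)
    mean_depth: float = 25.0


# ------------------------------------------------------------------ reference

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _build_gene_structure(rng: np.random.Generator) -> tuple[str, list[tuple[int, int]]]:
    """One gene on the plus strand: sequence and relative exon intervals.

    The CDS starts with ATG, contains no internal stop, ends with a stop, and
    is split over 1-3 exons separated by GT..AG introns. Relative coordinates
    are 1-based within the returned gene sequence; exons equal the CDS (the
    simulated models carry no UTRs).
    """
    n_codons = int(rng.integers(40, 140))  # 120-420 nt of CDS
    body = "".join(
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons - 2)
    )
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    cds = "ATG" + body + stop
    max_exons = min(3, len(cds) // 40)
    n_exons = int(rng.integers(1, max_exons + 1))
    # cut the CDS into n_exons chunks of >= 20 nt
    cuts = sorted(rng.choice(np.arange(20, len(cds) - 20), n_exons - 1, replace=False)) \
        if n_exons > 1 else []
    chunks, prev = [], 0
    for cut in list(cuts) + [len(cds)]:
        chunks.append(cds[prev:cut])
        prev = cut
    parts: list[str] = []
    rel_exons: list[tuple[int, int]] = []
    pos = 0
    for i, chunk in enumerate(chunks):
        if i:
            intron = "GT" + _random_seq(rng, int(rng.integers(16, 76))) + "AG"
            parts.append(intron)
            pos += len(intron)
        rel_exons.append((pos + 1, pos + len(chunk)))
        parts.append(chunk)
        pos += len(chunk)
    return "".join(parts), rel_exons


def simulate_reference(
    seed: int,
    n_chromosomes: int = 2,
    chrom_length: int = 100_000,
    n_genes: int = 40,
) -> tuple[ReferenceGenome, list[GeneModel]]:
    """Simulate a reference genome with non-overlapping intron-containing genes.

    The first chromosome (or its first half, if there is only one) is the
    designated balanced region; genes are distributed both inside and outside
    it. Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{i + 1}" for i in range(n_chromosomes)]

    structures = [_build_gene_structure(rng) for _ in range(n_genes)]
    strands = ["+-"[i] for i in rng.integers(0, 2, n_genes)]
    per_chrom: dict[str, list[int]] = {c: [] for c in chrom_names}
    for gi in range(n_genes):
        per_chrom[chrom_names[gi % n_chromosomes]].append(gi)

    genes: list[GeneModel] = []
    chromosomes: dict[str, str] = {}
    for chrom in chrom_names:
        idxs = per_chrom[chrom]
        lengths = [len(structures[i][0]) for i in idxs]
        needed = sum(lengths) + _MIN_GENE_GAP * (len(idxs) + 1)
        if needed > chrom_length:
            raise SizingError(
                f"{chrom}: {len(idxs)} genes need {needed} bp (gene bodies plus "
                f"{_MIN_GENE_GAP} bp gaps) but chrom_length is {chrom_length}"
            )
        extra = chrom_length - needed
        gaps = rng.multinomial(extra, [1.0 / (len(idxs) + 1)] * (len(idxs) + 1))
        pieces: list[str] = []
        cursor = 0
        for slot, gi in enumerate(idxs):
            gap = int(gaps[slot]) + _MIN_GENE_GAP
            pieces.append(_random_seq(rng, gap))
            cursor += gap
            gene_seq, rel_exons = structures[gi]
            length = len(gene_seq)
            start = cursor + 1  # 1-based genomic start of the gene body
            if strands[gi] == "+":
                exons = [(start + s - 1, start + e - 1) for s, e in rel_exons]
                pieces.append(gene_seq)
            else:
                exons = sorted(
                    (start + length - e, start + length - s) for s, e in rel_exons
                )
                pieces.append(revcomp(gene_seq))
            cursor += length
            genes.append(
                GeneModel(
                    gene_id=f"g{gi + 1:04d}",
                    chromosome=chrom,
                    strand=strands[gi],
                    exons=exons,
                    cds=list(exons),
                )
            )
        pieces.append(_random_seq(rng, int(gaps[-1]) + _MIN_GENE_GAP))
        chromosomes[chrom] = "".join(pieces)

    if n_chromosomes >= 2:
        region = (chrom_names[0], 1, chrom_length)
    else:
        region = (chrom_names[0], 1, chrom_length // 2)
    genome = ReferenceGenome(chromosomes, balanced_region=region)
    for gene in genes:
        gene.validate_against(genome)
    genes.sort(key=lambda g: (g.chromosome, g.span))
    return genome, genes


def balanced_genes(genome: ReferenceGenome, genes: list[GeneModel]) -> list[GeneModel]:
    chrom, start, end = genome.balanced_region
    return [
        g for g in genes
        if g.chromosome == chrom and start <= g.span[0] and g.span[1] <= end
    ]


def make_zones(
    genome: ReferenceGenome, genes: list[GeneModel], n_zones: int = 14
) -> list[MappingZone]:
    """Subdivide the balanced region into contiguous mapping zones.

    Zone boundaries fall in the gaps between genes so that every
    balanced-region gene belongs to exactly one zone, mirroring zones defined
    by deficiency breakpoints between genes.
    """
    inside = balanced_genes(genome, genes)
    if not inside:
        raise ConfigurationError("no genes inside the balanced region")
    n_zones = min(n_zones, len(inside))
    chrom, region_start, region_end = genome.balanced_region
    splits = np.array_split(np.arange(len(inside)), n_zones)
    zones: list[MappingZone] = []
    prev_end = region_start - 1
    for zi, idxs in enumerate(splits):
        members = [inside[i] for i in idxs]
        if zi == n_zones - 1:
            end = region_end
        else:
            last = members[-1].span[1]
            nxt = inside[idxs[-1] + 1].span[0]
            end = (last + nxt) // 2
        zones.append(
            MappingZone(
                zone_id=f"zone{zi + 1:02d}",
                chromosome=chrom,
                start=prev_end + 1,
                end=end,
                gene_ids=tuple(g.gene_id for g in members),
            )
        )
        prev_end = end
    return zones


# ------------------------------------------------------------------ cohort

def sample_site_reads(
    rng: np.random.Generator,
    mean_depth: float,
    true_vaf: float,
    depth_model: str = "poisson",
) -> tuple[int, int, int]:
    """(depth, alt_forward, alt_reverse) for one site.

    Depth is Poisson around the mean (or fixed), alt reads binomial at the
    true VAF, and the strand split symmetric Binomial(alt, 1/2).
    """
    if depth_model == "poisson":
        depth = max(1, int(rng.poisson(mean_depth)))
    elif depth_model == "fixed":
        depth = max(1, int(round(mean_depth)))
    else:
        raise ValueError(f"unknown depth model {depth_model!r}")
    alt = int(rng.binomial(depth, true_vaf))
    fwd = int(rng.binomial(alt, 0.5))
    return depth, fwd, alt - fwd


def sample_lethal_vafs(
    n: int,
    mean_depth: float,
    config: BalancerConfig,
    seed: int,
    depth_model: str = "fixed",
) -> np.ndarray:
    """Empirical VAFs of ``n`` independent simulated lethal sites."""
    rng = np.random.default_rng(seed)
    vaf = expected_vaf(config)
    out = np.empty(n)
    for i in range(n):
        depth, fwd, rev = sample_site_reads(rng, mean_depth, vaf, depth_model)
        out[i] = (fwd + rev) / depth
    return out


def _transition_alt(ref: str) -> str:
    return _TRANSITION[ref]


_MMP_CLASS = {
    "missense": "missense",
    "nonsense": "nonsense",
    "start_loss": "other",
    "stop_loss": "other",
    "splice_donor": "splice",
    "splice_acceptor": "splice",
    "synonymous": "other",
    "intronic": "other",
    "utr": "other",
    "intergenic": "other",
}


def _coding_site(
    rng: np.random.Generator,
    gene: GeneModel,
    genome: ReferenceGenome,
    genes: list[GeneModel],
    used: set,
    want: set[str] | None = None,
    tries: int = 300,
) -> tuple[int, str, str, str] | None:
    """Random EMS-like SNV in the gene's CDS, optionally of a wanted class.

    Returns (position, ref, alt, consequence) or None if no site of the
    wanted class was found within the try budget.
    """
    starts = np.array([s for s, _ in gene.cds])
    sizes = np.array([e - s + 1 for s, e in gene.cds])
    cum = np.concatenate([[0], np.cumsum(sizes)])
    splice_pos = [
        p
        for s, e in gene.introns()
        if e - s + 1 >= 4
        for p in (s, s + 1, e - 1, e)
    ]
    for _ in range(tries):
        if splice_pos and rng.random() < 0.10:
            pos = int(splice_pos[rng.integers(0, len(splice_pos))])
        else:
            k = int(rng.integers(0, cum[-1]))
            iv = int(np.searchsorted(cum, k, side="right")) - 1
            pos = int(starts[iv] + (k - cum[iv]))
        if (gene.chromosome, pos) in used:
            continue
        ref = genome.base(gene.chromosome, pos)
        alt = _transition_alt(ref)
        effect = fx.annotate_call(gene.chromosome, pos, ref, alt, genome, genes)
        cls = effect[0].consequence if effect else "intergenic"
        if want is None or cls in want:
            return pos, ref, alt, cls
    return None


def simulate_mmp(
    rng: np.random.Generator,
    genome: ReferenceGenome,
    genes: list[GeneModel],
    essential: set[str],
    used: set,
    leak_rate: float = 0.0,
    mean_missense: float = 4.0,
    mean_chain_terminating: float = 1.5,
) -> MmpDatabase:
    """Population-variant database from a viable-strain screen.

    Essential genes receive missense records only (a chain-terminating record
    leaks through with probability ``leak_rate`` per gene, default 0); other
    genes receive missense plus nonsense/splice records.
    """
    db = MmpDatabase()
    for gene in genes:
        n_mis = 1 + int(rng.poisson(mean_missense - 1))
        for _ in range(n_mis):
            site = _coding_site(rng, gene, genome, genes, used, {"missense"})
            if site:
                pos, ref, alt, _ = site
                used.add((gene.chromosome, pos))
                db.add(gene.chromosome, pos, ref, alt, "missense", gene.gene_id)
        allow_ct = (gene.gene_id not in essential) or (rng.random() < leak_rate)
        if allow_ct:
            for _ in range(int(rng.poisson(mean_chain_terminating))):
                site = _coding_site(
                    rng, gene, genome, genes, used,
                    {"nonsense", "splice_donor", "splice_acceptor"},
                )
                if site:
                    pos, ref, alt, cls = site
                    used.add((gene.chromosome, pos))
                    db.add(gene.chromosome, pos, ref, alt, _MMP_CLASS[cls],
                           gene.gene_id)
    return db


def simulate_cohort(
    genome: ReferenceGenome,
    genes: list[GeneModel],
    zones: list[MappingZone],
    config: BalancerConfig,
    n_strains: int,
    n_background: int = 15,
    seed: int = 0,
    *,
    mean_depth: float | None = None,
    pair_fraction: float = 0.5,
    depth_model: str = "poisson",
    mmp_leak_rate: float = 0.0,
    private_rate: float = 3.0,
) -> tuple[CohortTable, list[StrainTruth], MmpDatabase]:
    """Simulate a cohort of balanced-lethal strains with truth labels.

    Each strain carries exactly one lethal coding SNV in a balanced-region
    gene; a fraction ``pair_fraction`` of target genes is hit in two strains
    forming one complementation group (two independent alleles). Background
    variants are shared by >=2 strains at identical (chrom, pos, ref, alt);
    private neutral variants are strain-specific. Lethal and private sites
    are globally unique across strains, so truth classes never overlap.
    """
    if n_strains < 1:
        raise ConfigurationError("n_strains must be >= 1")
    if mean_depth is None:
        mean_depth = DEFAULT_DEPTH[config.kind]
    rng = np.random.default_rng(seed)
    evaf = expected_vaf(config)

    inside = balanced_genes(genome, genes)
    zone_of_gene: dict[str, str] = {}
    for zone in zones:
        for gid in zone.gene_ids:
            zone_of_gene.setdefault(gid, zone.zone_id)
    unzoned = [g.gene_id for g in inside if g.gene_id not in zone_of_gene]
    if unzoned:
        raise ConfigurationError(
            f"zones do not cover balanced-region genes: {unzoned[:5]}"
        )

    n_pairs = int(round(n_strains * pair_fraction / (1.0 + pair_fraction)))
    n_singles = n_strains - 2 * n_pairs
    n_targets = n_pairs + n_singles
    if n_targets > len(inside):
        raise ConfigurationError(
            f"need {n_targets} target genes but only {len(inside)} lie in the "
            "balanced region"
        )
    order = rng.permutation(len(inside))
    targets = [inside[i] for i in order[:n_targets]]
    # first n_pairs target genes get two strains each
    assignment: list[GeneModel] = []
    for gi, gene in enumerate(targets):
        assignment.extend([gene] * (2 if gi < n_pairs else 1))
    rng.shuffle(assignment)  # strain order does not encode pairing

    used: set[tuple[str, int]] = set()
    strains = [f"S{i + 1:03d}" for i in range(n_strains)]
    truths: list[StrainTruth] = []
    calls_by_strain: dict[str, list[VariantCall]] = {s: [] for s in strains}

    for strain, gene in zip(strains, assignment):
        site = _coding_site(
            rng, gene, genome, genes, used,
            {"missense", "nonsense", "start_loss", "splice_donor",
             "splice_acceptor"},
        )
        if site is None:  # pragma: no cover - tiny genes only
            raise ConfigurationError(f"could not place a lethal SNV in {gene.gene_id}")
        pos, ref, alt, cls = site
        used.add((gene.chromosome, pos))
        depth, fwd, rev = sample_site_reads(rng, mean_depth, evaf, depth_model)
        calls_by_strain[strain].append(
            VariantCall(strain, gene.chromosome, pos, ref, alt, depth, fwd, rev)
        )
        truths.append(
            StrainTruth(
                strain_id=strain,
                lethal_variant=(gene.chromosome, pos, ref, alt),
                target_gene=gene.gene_id,
                zone_id=zone_of_gene[gene.gene_id],
                group_id=f"grp_{gene.gene_id}",
                consequence=cls,
                mean_depth=mean_depth,
            )
        )

    # shared background variants from the common starting strain
    chrom_names = list(genome.chromosomes)
    background_keys: list[tuple[str, int, str, str]] = []
    for _ in range(n_background):
        while True:
            chrom = chrom_names[rng.integers(0, len(chrom_names))]
            pos = int(rng.integers(1, len(genome.chromosomes[chrom]) + 1))
            if (chrom, pos) not in used:
                break
        used.add((chrom, pos))
        ref = genome.base(chrom, pos)
        alt = _transition_alt(ref)
        key = (chrom, pos, ref, alt)
        background_keys.append(key)
        n_carriers = int(rng.integers(2, n_strains + 1)) if n_strains > 2 else 2
        carriers = rng.choice(n_strains, size=n_carriers, replace=False)
        for ci in carriers:
            depth, fwd, rev = sample_site_reads(rng, mean_depth, evaf, depth_model)
            calls_by_strain[strains[ci]].append(
                VariantCall(strains[ci], chrom, pos, ref, alt, depth, fwd, rev)
            )
    for truth in truths:
        truth.background_variant_ids = list(background_keys)

    # strain-private neutral variants at globally unique sites
    private_keys: set[tuple[str, int, str, str]] = set()
    for strain in strains:
        for _ in range(int(rng.poisson(private_rate))):
            while True:
                chrom = chrom_names[rng.integers(0, len(chrom_names))]
                pos = int(rng.integers(1, len(genome.chromosomes[chrom]) + 1))
                if (chrom, pos) not in used:
                    break
            used.add((chrom, pos))
            ref = genome.base(chrom, pos)
            alt = _transition_alt(ref)
            true_p = float(rng.uniform(0.05, 1.0))
            depth, fwd, rev = sample_site_reads(rng, mean_depth, true_p, depth_model)
            calls_by_strain[strain].append(
                VariantCall(strain, chrom, pos, ref, alt, depth, fwd, rev)
            )
            private_keys.add((chrom, pos, ref, alt))

    essential = {t.target_gene for t in truths}
    mmp = simulate_mmp(rng, genome, genes, essential, used, leak_rate=mmp_leak_rate)

    cohort = CohortTable(calls_by_strain)
    return cohort, truths, mmp


# ------------------------------------------------------------------ truth views

def truth_frame(truths: list[StrainTruth]) -> pd.DataFrame:
    rows = []
    for t in truths:
        chrom, pos, ref, alt = t.lethal_variant
        rows.append(
            dict(strain_id=t.strain_id, chrom=chrom, pos=pos, ref=ref, alt=alt,
                 target_gene=t.target_gene, zone_id=t.zone_id,
                 group_id=t.group_id, consequence=t.consequence,
                 mean_depth=t.mean_depth)
        )
    return pd.DataFrame(rows)


def groups_from_truth(truths: list[StrainTruth]) -> dict[str, str]:
    return {t.strain_id: t.group_id for t in truths}


def strain_zones_from_truth(truths: list[StrainTruth]) -> dict[str, str]:
    return {t.strain_id: t.zone_id for t in truths}


def truth_classes(
    truths: list[StrainTruth], cohort: CohortTable
) -> dict[str, set[tuple[str, int, str, str]]]:
    """Partition of all simulated variant keys into truth classes."""
    lethal = {t.lethal_variant for t in truths}
    background = set(truths[0].background_variant_ids) if truths else set()
    everything = {c.key for c in cohort.all_calls()}
    return {
        "lethal": lethal,
        "background": background,
        "private_neutral": everything - lethal - background,
    }


# ------------------------------------------------------------------ trait tables

def simulate_gene_groups(
    sizes: dict[str, int], seed: int = 0, prefix: str = "tg"
) -> pd.DataFrame:
    """Disjoint gene groups (e.g. G1..G4) with the given sizes."""
    rows, i = [], 0
    for group, n in sizes.items():
        for _ in range(n):
            rows.append(dict(gene_id=f"{prefix}{i:05d}", group=group))
            i += 1
    return pd.DataFrame(rows)


def simulate_interaction_table(
    groups: pd.DataFrame,
    mean_by_group: dict[str, float],
    dispersion: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Negative-binomial interactor counts per gene, group-shifted means."""
    rng = np.random.default_rng(seed)
    counts = []
    for row in groups.itertuples(index=False):
        mu = mean_by_group[row.group]
        p = dispersion / (dispersion + mu)
        counts.append(int(rng.negative_binomial(dispersion, p)))
    return pd.DataFrame({"gene_id": groups.gene_id, "interactors": counts})


def simulate_paralog_table(
    groups: pd.DataFrame,
    duplicate_fraction_by_group: dict[str, float],
    seed: int = 0,
) -> pd.DataFrame:
    """All-against-all protein-comparison pairs above reporting thresholds.

    Genes drawn as duplicates get one partner pair at PID >= 50 and
    e-value <= 1e-20; the rest receive either no pair or a weak pair that
    fails the thresholds.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i, row in enumerate(groups.itertuples(index=False)):
        frac = duplicate_fraction_by_group[row.group]
        if rng.random() < frac:
            rows.append(
                dict(gene_a=row.gene_id, gene_b=f"par{i:05d}",
                     percent_identity=float(rng.uniform(50.0, 95.0)),
                     e_value=10.0 ** float(rng.uniform(-120, -20)))
            )
        elif rng.random() < 0.5:
            rows.append(
                dict(gene_a=row.gene_id, gene_b=f"par{i:05d}",
                     percent_identity=float(rng.uniform(15.0, 49.0)),
                     e_value=10.0 ** float(rng.uniform(-18, -2)))
            )
    return pd.DataFrame(rows)


def simulate_expression_matrix(
    groups: pd.DataFrame,
    n_stages: int = 23,
    base_rpkm: float = 8.0,
    multiplier_by_group: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene x developmental-stage RPKM matrix with group-scaled expression."""
    rng = np.random.default_rng(seed)
    multiplier_by_group = multiplier_by_group or {}
    stages = [f"stage{i + 1:02d}" for i in range(n_stages)]
    data = {}
    mult = groups.group.map(lambda g: multiplier_by_group.get(g, 1.0)).to_numpy()
    for stage in stages:
        noise = rng.lognormal(mean=0.0, sigma=0.5, size=len(groups))
        data[stage] = base_rpkm * mult * noise
    frame = pd.DataFrame(data, index=groups.gene_id)
    frame.index.name = "gene_id"
    return frame
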