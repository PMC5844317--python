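"""Reading and writing the pipeline's file formats.

Variant tables are VCF 4.2 with per-sample FORMAT fields ``DP`` (total site
depth), ``ADF`` and ``ADR`` (alt-supporting forward / reverse read counts).
The VAF is always recomputed from those counts, never trusted from the file.
Genomes are FASTA, gene models GFF3, mapping zones a BED-like TSV
(half-open ``[start, end)`` on disk, converted to 1-based closed in memory),
and the MMP-style population-variant database a plain TSV.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import CohortError, FormatError, IntervalError
from .genome import GeneModel, ReferenceGenome

logger = logging.getLogger(__name__)

# ADF/ADR hold alt-supporting counts only (Number=A); htslib would otherwise
# warn that the reserved tags are conventionally Number=R.
pysam.set_verbosity(0)

VariantKey = tuple[str, int, str, str]

_REQUIRED_FORMAT_FIELDS = ("DP", "ADF", "ADR")


@dataclass(frozen=True)
class VariantCall:
    """One biallelic SNV observation in one strain, with strand-split support."""

    strain_id: str
    chromosome: str
    position: int
    ref: str
    alt: str
    depth: int
    alt_forward: int
    alt_reverse: int

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.locus}")
        if self.alt_forward + self.alt_reverse > self.depth:
            raise ValueError(
                f"ADF+ADR exceeds DP at {self.locus} in {self.strain_id}"
            )
        if min(self.depth, self.alt_forward, self.alt_reverse) < 0:
            raise ValueError(f"negative read counts at {self.locus}")

    @property
    def locus(self) -> str:
        return f"{self.chromosome}:{self.position}"

    @property
    def alt_depth(self) -> int:
        return self.alt_forward + self.alt_reverse

    @property
    def vaf(self) -> float:
        return self.alt_depth / self.depth if self.depth else 0.0

    @property
    def key(self) -> VariantKey:
        return (self.chromosome, self.position, self.ref, self.alt)


class CohortTable:
    """Per-strain variant calls plus a cohort-level index by variant key."""

    def __init__(self, calls_by_strain: dict[str, list[VariantCall]] | None = None):
        self._calls: dict[str, list[VariantCall]] = {}
        if calls_by_strain:
            for strain, calls in calls_by_strain.items():
                self._calls[strain] = list(calls)

    @classmethod
    def from_calls(cls, calls: list[VariantCall]) -> "CohortTable":
        table = cls()
        for call in calls:
            table.add(call)
        return table

    def add(self, call: VariantCall) -> None:
        self._calls.setdefault(call.strain_id, []).append(call)

    def add_strain(self, strain_id: str, calls: list[VariantCall]) -> None:
        if strain_id in self._calls:
            raise CohortError(f"duplicate strain id {strain_id!r}")
        self._calls[strain_id] = list(calls)

    @property
    def strains(self) -> list[str]:
        return list(self._calls)

    def calls(self, strain_id: str) -> list[VariantCall]:
        return self._calls[strain_id]

    def all_calls(self) -> list[VariantCall]:
        return [c for calls in self._calls.values() for c in calls]

    def __len__(self) -> int:
        return sum(len(c) for c in self._calls.values())

    def counts_per_strain(self) -> dict[str, int]:
        return {s: len(c) for s, c in self._calls.items()}

    def index(self) -> dict[VariantKey, set[str]]:
        """Variant key -> set of strain ids carrying it."""
        idx: dict[VariantKey, set[str]] = defaultdict(set)
        for strain, calls in self._calls.items():
            for call in calls:
                idx[call.key].add(strain)
        return dict(idx)

    def recurrence(self) -> Counter:
        """Variant key -> number of distinct strains carrying it."""
        return Counter({k: len(s) for k, s in self.index().items()})

    def filtered(self, predicate) -> "CohortTable":
        """New table keeping calls where ``predicate(call)`` is true.

        Strains are preserved even when all their calls are removed, so the
        per-strain bookkeeping downstream never loses a strain.
        """
        return CohortTable(
            {s: [c for c in calls if predicate(c)] for s, calls in self._calls.items()}
        )

    def multiset(self) -> Counter:
        """(strain, key) multiset, for order-insensitive comparisons."""
        return Counter((c.strain_id, c.key) for c in self.all_calls())


@dataclass(frozen=True)
class MappingZone:
    """A genetically defined interval (1-based closed) holding candidate genes."""

    zone_id: str
    chromosome: str
    start: int
    end: int
    gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise IntervalError(
                f"zone {self.zone_id}: start {self.start} > end {self.end}"
            )

    def contains(self, chromosome: str, position: int) -> bool:
        return chromosome == self.chromosome and self.start <= position <= self.end


@dataclass
class MmpDatabase:
    """Population-variant records from a viable-strain mutagenesis catalogue.

    Essential genes are expected to show missense records but lack
    chain-terminating (nonsense / splice) alleles in such a catalogue, since
    strains carrying those would not have been viable.
    """

    records: list[tuple[str, int, str, str, str, str]] = field(default_factory=list)
    # each record: (chrom, pos, ref, alt, consequence_class, gene_id)

    CLASSES = ("missense", "nonsense", "splice", "other")

    def add(self, chrom, pos, ref, alt, consequence, gene_id="") -> None:
        if consequence not in self.CLASSES:
            raise ValueError(f"unknown consequence class {consequence!r}")
        self.records.append((chrom, int(pos), ref, alt, consequence, gene_id))

    def keys(self) -> set[VariantKey]:
        return {(c, p, r, a) for c, p, r, a, _, _ in self.records}

    def gene_index(self) -> dict[str, set[str]]:
        idx: dict[str, set[str]] = defaultdict(set)
        for _, _, _, _, cons, gene in self.records:
            if gene:
                idx[gene].add(cons)
        return dict(idx)

    def to_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["chrom", "pos", "ref", "alt", "consequence", "gene_id"])
            for rec in self.records:
                w.writerow(rec)

    @classmethod
    def from_tsv(cls, path) -> "MmpDatabase":
        db = cls()
        frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        for row in frame.itertuples(index=False):
            db.add(row.chrom, row.pos, row.ref, row.alt, row.consequence,
                   getattr(row, "gene_id", "") or "")
        return db


# ---------------------------------------------------------------- VCF

def write_strain_vcf(path, strain_id: str, calls: list[VariantCall],
                     genome: ReferenceGenome | None = None) -> None:
    """Write one strain's calls as an uncompressed single-sample VCF 4.2."""
    header = pysam.VariantHeader()
    contigs = (
        {name: len(seq) for name, seq in genome.chromosomes.items()}
        if genome
        else {c.chromosome: None for c in calls}
    )
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.formats.add("DP", 1, "Integer", "Total read depth at the site")
    header.formats.add("ADF", "A", "Integer", "Alt-supporting forward reads")
    header.formats.add("ADR", "A", "Integer", "Alt-supporting reverse reads")
    header.add_sample(strain_id)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for call in sorted(calls, key=lambda c: (c.chromosome, c.position, c.alt)):
            rec = vcf.new_record(
                contig=call.chromosome,
                start=call.position - 1,
                stop=call.position,
                alleles=(call.ref, call.alt),
            )
            sample = rec.samples[strain_id]
            sample["DP"] = call.depth
            sample["ADF"] = (call.alt_forward,)
            sample["ADR"] = (call.alt_reverse,)
            vcf.write(rec)


def read_strain_vcf(path) -> tuple[str, list[VariantCall]]:
    """Parse a single-sample VCF; multi-allelic rows are split per alt allele."""
    path = str(path)
    with pysam.VariantFile(path) as vcf:
        for name in _REQUIRED_FORMAT_FIELDS:
            if name not in vcf.header.formats:
                raise FormatError(
                    f"{path}: required FORMAT field {name!r} missing from header"
                )
        if len(vcf.header.samples) != 1:
            raise FormatError(
                f"{path}: expected exactly one sample, found "
                f"{len(vcf.header.samples)}"
            )
        strain_id = vcf.header.samples[0]
        calls: list[VariantCall] = []
        for rec in vcf:
            sample = rec.samples[strain_id]
            for name in _REQUIRED_FORMAT_FIELDS:
                if name not in sample or sample[name] is None:
                    raise FormatError(
                        f"{path}: FORMAT field {name!r} missing at record "
                        f"{rec.chrom}:{rec.pos}"
                    )
            depth = int(sample["DP"])
            adf, adr = sample["ADF"], sample["ADR"]
            alts = rec.alts or ()
            if len(adf) != len(alts) or len(adr) != len(alts):
                raise FormatError(
                    f"{path}: ADF/ADR arity does not match ALT alleles at "
                    f"{rec.chrom}:{rec.pos}"
                )
            for alt, f, r in zip(alts, adf, adr):
                if len(rec.ref) != 1 or len(alt) != 1:
                    logger.warning(
                        "skipping non-SNV record %s:%s (%s>%s)",
                        rec.chrom, rec.pos, rec.ref, alt,
                    )
                    continue
                calls.append(
                    VariantCall(
                        strain_id=strain_id,
                        chromosome=rec.chrom,
                        position=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        depth=depth,
                        alt_forward=int(f),
                        alt_reverse=int(r),
                    )
                )
    return strain_id, calls


def read_cohort(paths) -> CohortTable:
    """Read a list of single-strain VCFs into one cohort table."""
    table = CohortTable()
    for path in paths:
        strain_id, calls = read_strain_vcf(path)
        table.add_strain(strain_id, calls)
    return table


def write_cohort(directory, cohort: CohortTable,
                 genome: ReferenceGenome | None = None) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for strain in cohort.strains:
        path = directory / f"{strain}.vcf"
        write_strain_vcf(path, strain, cohort.calls(strain), genome)
        paths.append(path)
    return paths


# ---------------------------------------------------------------- FASTA / GFF3

def write_fasta(path, genome: ReferenceGenome) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.chromosomes.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> ReferenceGenome:
    chroms = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    if not chroms:
        raise FormatError(f"{path}: no FASTA records found")
    return ReferenceGenome(chroms)


def write_gff3(path, genes: list[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            start, end = gene.span
            base = (gene.chromosome, "balancerscan")
            fh.write(
                "\t".join(map(str, (*base, "gene", start, end, ".", gene.strand,
                                    ".", f"ID={gene.gene_id}"))) + "\n"
            )
            fh.write(
                "\t".join(map(str, (*base, "mRNA", start, end, ".", gene.strand, ".",
                                    f"ID={gene.transcript_id};Parent={gene.gene_id}")))
                + "\n"
            )
            for i, (s, e) in enumerate(gene.exons, 1):
                fh.write(
                    "\t".join(map(str, (*base, "exon", s, e, ".", gene.strand, ".",
                                        f"ID={gene.transcript_id}.exon{i};"
                                        f"Parent={gene.transcript_id}"))) + "\n"
                )
            phase = 0
            cds_iv = gene.cds if gene.strand == "+" else gene.cds[::-1]
            for s, e in cds_iv:
                fh.write(
                    "\t".join(map(str, (*base, "CDS", s, e, ".", gene.strand, phase,
                                        f"ID={gene.transcript_id}.cds;"
                                        f"Parent={gene.transcript_id}"))) + "\n"
                )
                phase = (3 - ((e - s + 1) - phase) % 3) % 3


def read_gff3(path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = sorted(
                (f.start, f.end) for f in db.children(mrna, featuretype="exon")
            )
            cds = sorted(
                (f.start, f.end) for f in db.children(mrna, featuretype="CDS")
            )
            genes.append(
                GeneModel(
                    gene_id=gene.id,
                    chromosome=gene.seqid,
                    strand=gene.strand,
                    exons=exons,
                    cds=cds,
                    transcript_id=mrna.id,
                )
            )
    return sorted(genes, key=lambda g: (g.chromosome, g.span))


# ---------------------------------------------------------------- zones

def write_zones(path, zones: list[MappingZone]) -> None:
    """Write zones BED-style: half-open [start, end) coordinates on disk."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["chrom", "start", "end", "zone_id", "gene_ids"])
        for z in sorted(zones, key=lambda z: (z.chromosome, z.start)):
            w.writerow([z.chromosome, z.start - 1, z.end, z.zone_id,
                        ",".join(z.gene_ids)])


def read_zones(path) -> list[MappingZone]:
    """Read a BED-like zone TSV, converting to 1-based closed intervals."""
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str, "zone_id": str})
    if frame.empty:
        logger.warning("zone file %s contains no zones", path)
        return []
    zones: list[MappingZone] = []
    seen: set[str] = set()
    for row in frame.itertuples(index=False):
        if row.start >= row.end:
            raise IntervalError(
                f"zone {row.zone_id}: start {row.start} >= end {row.end}"
            )
        if row.zone_id in seen:
            raise IntervalError(f"duplicate zone_id {row.zone_id!r}")
        seen.add(row.zone_id)
        gene_ids = ()
        if isinstance(getattr(row, "gene_ids", None), str) and row.gene_ids:
            gene_ids = tuple(row.gene_ids.split(","))
        zones.append(
            MappingZone(
                zone_id=row.zone_id,
                chromosome=row.chrom,
                start=int(row.start) + 1,
                end=int(row.end),
                gene_ids=gene_ids,
            )
        )
    return sorted(zones, key=lambda z: (z.chromosome, z.start))


# ---------------------------------------------------------------- packaged tables

def _packaged(name: str) -> pd.DataFrame:
    with resources.files("balancerscan.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_conservation_table() -> pd.DataFrame:
    """Curated 60-gene table: lethal name, gene, function, conservation clades."""
    return _packaged("essential_gene_conservation.csv")


def load_identification_tally() -> pd.DataFrame:
    """Per-region identification bookkeeping of the two balanced screens."""
    return _packaged("identification_tally.csv")


# ---------------------------------------------------------------- truth sidecar

def write_truth(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
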