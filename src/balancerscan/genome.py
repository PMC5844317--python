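"""Reference genome and gene-model containers shared across the pipeline.

Coordinates are 1-based closed intervals throughout, matching VCF/GFF3
conventions. Gene models carry exon and CDS intervals in genomic order; for
minus-strand genes the spliced CDS is the reverse complement of the
concatenated genomic CDS intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a CDS with the standard nuclear code ('*' for stops)."""
    return str(Seq(cds).translate())


@dataclass
class ReferenceGenome:
    """Chromosome name -> upper-case ACGT sequence.

    ``balanced_region`` optionally names the (chromosome, start, end) interval
    held over the balancer; the simulator sets it, file round-trips may not.
    """

    chromosomes: dict[str, str]
    balanced_region: tuple[str, int, int] | None = None

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} has empty sequence")
            if set(seq) - set("ACGT"):
                raise ValueError(f"chromosome {name!r} contains non-ACGT characters")

    def base(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return self.chromosomes[chrom][pos - 1]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of the 1-based closed interval [start, end]."""
        return self.chromosomes[chrom][start - 1 : end]


@dataclass
class GeneModel:
    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.transcript_id:
            self.transcript_id = self.gene_id + ".1"
        for name, ivs in (("exons", self.exons), ("cds", self.cds)):
            for s, e in ivs:
                if s > e:
                    raise ValueError(f"{name} interval ({s}, {e}) is inverted")
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(f"{name} intervals overlap or are unsorted")
        for cs, ce in self.cds:
            if not any(es <= cs and ce <= ee for es, ee in self.exons):
                raise ValueError(f"CDS interval ({cs}, {ce}) not nested in an exon")
        if self.cds_length % 3 != 0:
            raise ValueError("total CDS length not divisible by 3")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def cds_sequence(self, genome: ReferenceGenome) -> str:
        """Spliced CDS in translation orientation (5' -> 3' of the mRNA)."""
        seq = "".join(genome.fetch(self.chromosome, s, e) for s, e in self.cds)
        return revcomp(seq) if self.strand == "-" else seq

    def cds_position(self, pos: int) -> int | None:
        """1-based position within the spliced CDS, or None if not coding."""
        offset = 0
        intervals = self.cds if self.strand == "+" else self.cds[::-1]
        for s, e in intervals:
            if s <= pos <= e:
                within = (pos - s) if self.strand == "+" else (e - pos)
                return offset + within + 1
            offset += e - s + 1
        return None

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, in genomic order."""
        return [
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    def validate_against(self, genome: ReferenceGenome) -> None:
        """Check the coding invariants: ATG start, stop end, no internal stop."""
        protein = translate(self.cds_sequence(genome))
        if not self.cds_sequence(genome).startswith("ATG"):
            raise ValueError(f"{self.gene_id}: CDS does not start with ATG")
        if not protein.endswith("*"):
            raise ValueError(f"{self.gene_id}: CDS does not end with a stop codon")
        if "*" in protein[:-1]:
            raise ValueError(f"{self.gene_id}: internal stop codon in CDS")
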