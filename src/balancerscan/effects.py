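"""CDS-level consequence annotation of SNVs against gene models.

Each variant is classified per overlapping transcript into missense, nonsense,
start_loss, stop_loss, splice_donor/acceptor (the canonical GT/AG dinucleotide
positions), synonymous, utr, intronic or intergenic, with the codon and
amino-acid change and the 1-based position within the spliced CDS. The
relative CDS position of a stop gain equals the truncation fraction used by
the N-terminal nonsense-position statistic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .errors import FormatError
from .genome import GeneModel, ReferenceGenome, revcomp, translate
from .io import VariantCall

#: Reporting severity, most severe first.
SEVERITY = (
    "nonsense",
    "splice_donor",
    "splice_acceptor",
    "start_loss",
    "stop_loss",
    "missense",
    "synonymous",
    "utr",
    "intronic",
    "intergenic",
)
_RANK = {name: i for i, name in enumerate(SEVERITY)}


@dataclass(frozen=True)
class VariantEffect:
    gene_id: str | None
    transcript_id: str | None
    consequence: str
    codon_change: str | None = None
    aa_change: str | None = None
    cds_position: int | None = None
    relative_position: float | None = None
    most_severe: bool = False


@dataclass(frozen=True)
class NextAtg:
    """Location of the next downstream ATG after a lost start codon."""

    found: bool
    in_frame: bool
    offset_codons: int | None


def _splice_role(gene: GeneModel, pos: int) -> str | None:
    """'splice_donor'/'splice_acceptor' if pos hits a canonical 2-bp site."""
    for s, e in gene.introns():
        if e - s + 1 < 4 or not (s <= pos <= e):
            continue
        five_prime = {s, s + 1}    # genomic left end of the intron
        three_prime = {e - 1, e}   # genomic right end
        if gene.strand == "+":
            donor, acceptor = five_prime, three_prime
        else:
            donor, acceptor = three_prime, five_prime
        if pos in donor:
            return "splice_donor"
        if pos in acceptor:
            return "splice_acceptor"
        return None
    return None


def _annotate_transcript(
    chrom: str, pos: int, ref: str, alt: str,
    gene: GeneModel, genome: ReferenceGenome,
) -> VariantEffect:
    cds_pos = gene.cds_position(pos)
    if cds_pos is None:
        role = _splice_role(gene, pos)
        if role:
            return VariantEffect(gene.gene_id, gene.transcript_id, role)
        for s, e in gene.introns():
            if s <= pos <= e:
                return VariantEffect(gene.gene_id, gene.transcript_id, "intronic")
        return VariantEffect(gene.gene_id, gene.transcript_id, "utr")

    cds_seq = gene.cds_sequence(genome)
    ref_tx = ref if gene.strand == "+" else revcomp(ref)
    alt_tx = alt if gene.strand == "+" else revcomp(alt)
    codon_idx = (cds_pos - 1) // 3
    within = (cds_pos - 1) % 3
    ref_codon = cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
    assert ref_codon[within] == ref_tx
    alt_codon = ref_codon[:within] + alt_tx + ref_codon[within + 1 :]
    ref_aa, alt_aa = translate(ref_codon), translate(alt_codon)

    if alt_aa == "*" and ref_aa != "*":
        consequence = "nonsense"
    elif codon_idx == 0 and alt_codon != "ATG":
        consequence = "start_loss"
    elif ref_aa == "*":
        consequence = "stop_loss"
    elif ref_aa == alt_aa:
        consequence = "synonymous"
    else:
        consequence = "missense"

    return VariantEffect(
        gene_id=gene.gene_id,
        transcript_id=gene.transcript_id,
        consequence=consequence,
        codon_change=f"{ref_codon}>{alt_codon}",
        aa_change=f"{ref_aa}{codon_idx + 1}{alt_aa}",
        cds_position=cds_pos,
        relative_position=cds_pos / len(cds_seq),
    )


def annotate_call(
    chrom: str, pos: int, ref: str, alt: str,
    genome: ReferenceGenome, genes: list[GeneModel],
) -> list[VariantEffect]:
    """One effect per overlapping transcript, most severe first and flagged."""
    if genome.base(chrom, pos) != ref:
        raise FormatError(
            f"reference mismatch at {chrom}:{pos}: variant claims ref {ref!r} "
            f"but genome has {genome.base(chrom, pos)!r}"
        )
    hits = [
        g for g in genes
        if g.chromosome == chrom and g.span[0] <= pos <= g.span[1]
    ]
    if not hits:
        return [VariantEffect(None, None, "intergenic", most_severe=True)]
    effects = sorted(
        (_annotate_transcript(chrom, pos, ref, alt, g, genome) for g in hits),
        key=lambda e: _RANK[e.consequence],
    )
    effects[0] = VariantEffect(**{**effects[0].__dict__, "most_severe": True})
    return effects


def annotate(
    variant: VariantCall, genome: ReferenceGenome, genes: list[GeneModel]
) -> list[VariantEffect]:
    return annotate_call(
        variant.chromosome, variant.position, variant.ref, variant.alt,
        genome, genes,
    )


def annotate_cohort(cohort, genome, genes) -> dict[tuple, list[VariantEffect]]:
    """(strain, variant key) -> effects for every call in the cohort."""
    out = {}
    for call in cohort.all_calls():
        out[(call.strain_id, call.key)] = annotate(call, genome, genes)
    return out


def next_inframe_atg(gene: GeneModel, genome: ReferenceGenome) -> NextAtg:
    """Scan the CDS downstream of the original start for the next ATG.

    After a start-loss mutation, translation could reinitiate at the next
    ATG; an out-of-frame ATG implies no wild-type product.
    """
    cds = gene.cds_sequence(genome)
    idx = cds.find("ATG", 1)
    if idx < 0:
        return NextAtg(found=False, in_frame=False, offset_codons=None)
    in_frame = idx % 3 == 0
    return NextAtg(
        found=True,
        in_frame=in_frame,
        offset_codons=idx // 3 if in_frame else None,
    )


def effect_tally(effects) -> Counter:
    """Multiset counts of consequence classes."""
    return Counter(e.consequence for e in effects)
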