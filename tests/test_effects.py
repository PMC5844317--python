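import numpy as np
import pytest

from balancerscan import GeneModel, ReferenceGenome
from balancerscan import effects as fx
from balancerscan import simulate as sim
from balancerscan.errors import FormatError
from balancerscan.genome import revcomp

from oracles import classify_cds_snv, revcomp as oracle_revcomp


def mini_gene(cds_seq, strand="+", pad=5, introns=None):
    """Single-chromosome genome holding one gene built from a CDS string.

    ``introns`` optionally lists (after_base, intron_seq) insertions, where
    after_base is a 1-based CDS offset after which the intron goes.
    """
    pieces, rel_exons, cursor, prev = [], [], 0, 0
    introns = sorted(introns or [])
    for after, iseq in introns:
        chunk = cds_seq[prev:after]
        rel_exons.append((cursor + 1, cursor + len(chunk)))
        cursor += len(chunk)
        pieces.append(chunk)
        pieces.append(iseq)
        cursor += len(iseq)
        prev = after
    chunk = cds_seq[prev:]
    rel_exons.append((cursor + 1, cursor + len(chunk)))
    pieces.append(chunk)
    body = "".join(pieces)
    left = "C" * pad
    if strand == "+":
        chrom = left + body + left
        exons = [(pad + s, pad + e) for s, e in rel_exons]
    else:
        chrom = left + revcomp(body) + left
        L = len(body)
        exons = sorted((pad + L - e + 1, pad + L - s + 1) for s, e in rel_exons)
    genome = ReferenceGenome({"chr1": chrom})
    gene = GeneModel("g1", "chr1", strand, exons, list(exons))
    return genome, gene


class TestMiniGeneOracles:
    def test_stop_gain_second_codon(self):
        genome, gene = mini_gene("ATGAAATGA")
        # CDS position 4 (codon 2, base 1): AAA -> TAA
        pos = 5 + 4
        eff = fx.annotate_call("chr1", pos, "A", "T", genome, [gene])[0]
        assert eff.consequence == "nonsense"
        assert eff.aa_change == "K2*"
        assert eff.codon_change == "AAA>TAA"
        assert eff.relative_position == pytest.approx(4 / 9)

    def test_start_codon_atg_to_ata(self):
        genome, gene = mini_gene("ATGAAATGA")
        eff = fx.annotate_call("chr1", 5 + 3, "G", "A", genome, [gene])[0]
        assert eff.consequence == "start_loss"
        assert eff.codon_change == "ATG>ATA"

    def test_splice_sites_flanking_an_exon(self):
        genome, gene = mini_gene(
            "ATGAAAAAATGA", introns=[(6, "GTCCCCAG")]
        )
        (intron_start, intron_end), = gene.introns()
        donor = fx.annotate_call(
            "chr1", intron_start, "G", "A", genome, [gene]
        )[0]
        acceptor = fx.annotate_call(
            "chr1", intron_end, "G", "A", genome, [gene]
        )[0]
        deep = fx.annotate_call(
            "chr1", intron_start + 3, "C", "T", genome, [gene]
        )[0]
        assert donor.consequence == "splice_donor"
        assert acceptor.consequence == "splice_acceptor"
        assert deep.consequence == "intronic"

    def test_reverse_strand_mirror(self):
        """The reverse-complemented construction gives identical calls."""
        fwd_genome, fwd_gene = mini_gene("ATGAAATGA", strand="+")
        rev_genome, rev_gene = mini_gene("ATGAAATGA", strand="-")
        L = len(fwd_genome.chromosomes["chr1"])
        pos_fwd = 5 + 4
        pos_rev = L - pos_fwd + 1
        eff_f = fx.annotate_call("chr1", pos_fwd, "A", "T", fwd_genome, [fwd_gene])[0]
        eff_r = fx.annotate_call("chr1", pos_rev, "T", "A", rev_genome, [rev_gene])[0]
        assert (eff_f.consequence, eff_f.aa_change, eff_f.cds_position) == (
            eff_r.consequence, eff_r.aa_change, eff_r.cds_position
        )

    def test_reference_mismatch_rejected(self):
        genome, gene = mini_gene("ATGAAATGA")
        with pytest.raises(FormatError, match="reference mismatch"):
            fx.annotate_call("chr1", 5 + 4, "C", "T", genome, [gene])

    def test_intergenic_when_no_gene_overlaps(self):
        genome, gene = mini_gene("ATGAAATGA")
        eff = fx.annotate_call("chr1", 1, "C", "A", genome, [gene])
        assert [e.consequence for e in eff] == ["intergenic"]


def _oracle_cds_position(gene, pos):
    offset = 0
    ivs = gene.cds if gene.strand == "+" else list(reversed(gene.cds))
    for s, e in ivs:
        if s <= pos <= e:
            return offset + (pos - s if gene.strand == "+" else e - pos) + 1
        offset += e - s + 1
    return None


class TestRandomGeneEquivalence:
    def test_matches_brute_force_translation(self):
        """Random CDS SNVs on both strands vs an independent codon oracle."""
        genome, genes = sim.simulate_reference(42, 2, 120_000, 260)
        rng = np.random.default_rng(99)
        n_checked = {"+": 0, "-": 0}
        for gene in genes:
            cds_seq = gene.cds_sequence(genome)
            for _ in range(3):
                s, e = gene.cds[rng.integers(0, len(gene.cds))]
                pos = int(rng.integers(s, e + 1))
                ref = genome.base(gene.chromosome, pos)
                alt = "ACGT"[rng.integers(0, 4)]
                if alt == ref:
                    continue
                cds_pos = _oracle_cds_position(gene, pos)
                alt_tx = alt if gene.strand == "+" else oracle_revcomp(alt)
                want_cons, want_aa = classify_cds_snv(cds_seq, cds_pos, alt_tx)
                eff = [
                    e for e in fx.annotate_call(
                        gene.chromosome, pos, ref, alt, genome, genes
                    )
                    if e.gene_id == gene.gene_id
                ][0]
                assert eff.consequence == want_cons
                assert eff.aa_change == want_aa
                assert eff.cds_position == cds_pos
                assert eff.relative_position == pytest.approx(
                    cds_pos / len(cds_seq)
                )
                n_checked[gene.strand] += 1
        assert min(n_checked.values()) > 50  # both strands exercised


class TestNextInframeAtg:
    def test_in_frame_at_codon_three(self):
        genome, gene = mini_gene("ATGAAAATGAAATGA")
        res = fx.next_inframe_atg(gene, genome)
        assert res.found and res.in_frame and res.offset_codons == 2

    def test_out_of_frame_atg(self):
        genome, gene = mini_gene("ATGCATGCATAA")
        res = fx.next_inframe_atg(gene, genome)
        assert res.found and not res.in_frame and res.offset_codons is None

    def test_no_downstream_atg(self):
        genome, gene = mini_gene("ATGAAACCCTAA")
        res = fx.next_inframe_atg(gene, genome)
        assert not res.found and res.offset_codons is None


class TestEffectTally:
    def test_toy_counts(self):
        effs = [fx.VariantEffect("g", "t", "missense")] * 6 + [
            fx.VariantEffect("g", "t", "nonsense")
        ] * 4
        tally = fx.effect_tally(effs)
        assert tally == {"missense": 6, "nonsense": 4}
        assert fx.effect_tally([]) == {}

    def test_matches_simulator_truth_classes(self, reference, dup_cohort):
        genome, genes = reference
        _, truths, _ = dup_cohort
        from collections import Counter
        want = Counter(t.consequence for t in truths)
        got = Counter()
        for t in truths:
            chrom, pos, ref, alt = t.lethal_variant
            effs = fx.annotate_call(chrom, pos, ref, alt, genome, genes)
            target = [e for e in effs if e.gene_id == t.target_gene][0]
            got[target.consequence] += 1
        assert got == want
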