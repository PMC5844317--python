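"""Independent brute-force oracles used only by the test suite.

Everything here is written from first principles (own codon table, integer
hypergeometric enumeration, binomial sums via math.comb) so that agreement
with the package is a genuine two-route check.
"""

from __future__ import annotations

import math

# Standard nuclear genetic code, written out by hand.
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def translate(cds: str) -> str:
    return "".join(CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds), 3))


def classify_cds_snv(cds_seq: str, cds_pos: int, alt_tx: str) -> tuple[str, str]:
    """(consequence, aa_change) of a substitution in a spliced CDS.

    ``cds_pos`` is 1-based within the CDS; ``alt_tx`` is the alternate base
    already in transcript orientation.
    """
    idx = cds_pos - 1
    codon_idx, within = divmod(idx, 3)
    ref_codon = cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
    alt_codon = ref_codon[:within] + alt_tx + ref_codon[within + 1 :]
    ref_aa = CODON_TABLE[ref_codon]
    alt_aa = CODON_TABLE[alt_codon]
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
    return consequence, f"{ref_aa}{codon_idx + 1}{alt_aa}"


def binom_pmf(k: int, n: int, p: float) -> float:
    return math.comb(n, k) * p**k * (1 - p) ** (n - k)


def binom_sum(n: int, p: float, lo: int, hi: int) -> float:
    return sum(binom_pmf(k, n, p) for k in range(lo, hi + 1))


def fisher_two_sided(table) -> float:
    """Exhaustive hypergeometric enumeration with exact integer arithmetic."""
    (a, b), (c, d) = table
    n_total = a + b + c + d
    row1, col1 = a + b, a + c
    denom = math.comb(n_total, col1)
    num_obs = math.comb(row1, a) * math.comb(n_total - row1, c)
    total = 0
    for k in range(max(0, col1 - (n_total - row1)), min(row1, col1) + 1):
        num_k = math.comb(row1, k) * math.comb(n_total - row1, col1 - k)
        if num_k <= num_obs:
            total += num_k
    return total / denom
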