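"""Balancer genotype configurations and the expected heterozygous allele ratio.

A genetic balancer (a free duplication or a reciprocal translocation) lets a
recessive lethal mutation be propagated heterozygously. The balanced genotype
fixes the copy number of mutant and wild-type alleles over the balanced region,
and hence the variant allele frequency (VAF) expected in pooled whole-genome
sequencing of the strain:

* duplication-balanced (e.g. an sDp3-style free duplication): two mutant
  chromosomal copies over one wild-type duplication copy -> VAF 2/3;
* translocation-balanced (e.g. an eT1-style reciprocal translocation): one
  mutant and one wild-type allele -> VAF 1/2.

Populations of balanced strains can also contain balancer homozygotes, which
carry no mutant allele. DNA from those animals dilutes the mutant signal; we
model it as a linear pooling mixture with contamination fraction ``c``.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: Default VAF selection windows, inclusive at both bounds.
DUPLICATION_WINDOW = (0.40, 0.90)
TRANSLOCATION_WINDOW = (0.20, 1.00)


@dataclass(frozen=True)
class BalancerConfig:
    """Copy configuration of a balanced genotype over the balanced region.

    Parameters
    ----------
    kind:
        ``"duplication"`` or ``"translocation"``.
    mutant_copies, wildtype_copies:
        Allele copy counts in the balanced (mutation-carrying) genotype.
    contamination:
        Fraction ``c`` in [0, 1] of sequenced DNA that comes from balancer
        homozygotes, which carry only wild-type copies of the region.
    vaf_window:
        Inclusive ``(low, high)`` VAF selection window used downstream.
    """

    kind: str
    mutant_copies: int
    wildtype_copies: int
    contamination: float = 0.0
    vaf_window: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kind not in ("duplication", "translocation"):
            raise ValueError(f"unknown balancer kind: {self.kind!r}")
        if not 0.0 <= self.contamination <= 1.0:
            raise ValueError(
                f"contamination must lie in [0, 1], got {self.contamination}"
            )
        if self.mutant_copies < 1 or self.wildtype_copies < 0:
            raise ValueError("copy counts must be positive")
        if self.vaf_window is None:
            default = (
                DUPLICATION_WINDOW
                if self.kind == "duplication"
                else TRANSLOCATION_WINDOW
            )
            object.__setattr__(self, "vaf_window", default)
        low, high = self.vaf_window
        if not 0.0 <= low < high <= 1.0:
            raise ValueError(f"invalid VAF window {self.vaf_window}")

    @classmethod
    def duplication(cls, contamination: float = 0.0, **kw) -> "BalancerConfig":
        """2 mutant : 1 wild-type copies; default window 40-90%."""
        return cls("duplication", 2, 1, contamination, **kw)

    @classmethod
    def translocation(cls, contamination: float = 0.0, **kw) -> "BalancerConfig":
        """1 mutant : 1 wild-type copy; default window 20-100%."""
        return cls("translocation", 1, 1, contamination, **kw)


def expected_vaf(config: BalancerConfig) -> float:
    """Expected variant allele frequency under the linear DNA-pooling model.

    A fraction ``1 - c`` of the DNA comes from balanced animals contributing
    ``m`` mutant and ``w`` wild-type region copies; a fraction ``c`` comes from
    balancer homozygotes contributing two wild-type copies and no mutant copy:

        VAF = m(1 - c) / ((m + w)(1 - c) + 2c)

    For a duplication (m=2, w=1) at c=0 this is 2/3; for a translocation
    (m=1, w=1) it is (1 - c)/2, i.e. 1/2 at c=0 and 0 when all sequenced DNA
    is from balancer homozygotes.
    """
    m, w, c = config.mutant_copies, config.wildtype_copies, config.contamination
    denom = (m + w) * (1.0 - c) + 2.0 * c
    if denom == 0.0:  # degenerate: no DNA at all; unreachable with m>=1 unless c=1,m+w=0
        return 0.0
    return m * (1.0 - c) / denom
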