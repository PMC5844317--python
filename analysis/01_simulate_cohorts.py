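"""Simulate the two balanced-lethal screen designs at study scale.

Two cohorts are generated: a duplication-balanced screen (49 strains, mean
depth 25x, 43 target genes of which 6 carry two sequenced alleles) and a
translocation-balanced screen (86 strains, mean depth 31x, 46 target genes of
which 40 carry two alleles). All files a real analysis would start from
(FASTA, GFF3, zone table, MMP-style database, per-strain VCFs, truth sidecar)
are written under scratch/cohorts/; small summary tables go to results/.

Run from the repository root:  python analysis/01_simulate_cohorts.py
"""

from pathlib import Path

import pandas as pd

from balancerscan import BalancerConfig, io
from balancerscan import simulate as sim

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "cohorts"
RESULTS = ROOT / "results"

DESIGNS = {
    # name: (config, strains, pair_fraction, n_zones, seed)
    "sdp3_like": (BalancerConfig.duplication(), 49, 6 / 43, 14, 101),
    "et1_like": (BalancerConfig.translocation(), 86, 40 / 46, 23, 202),
}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for name, (config, n_strains, pair_frac, n_zones, seed) in DESIGNS.items():
        genome, genes = sim.simulate_reference(
            seed, n_chromosomes=2, chrom_length=220_000, n_genes=100
        )
        zones = sim.make_zones(genome, genes, n_zones=n_zones)
        cohort, truths, mmp = sim.simulate_cohort(
            genome, genes, zones, config, n_strains,
            n_background=20, seed=seed + 1, pair_fraction=pair_frac,
        )
        out = SCRATCH / name
        out.mkdir(parents=True, exist_ok=True)
        io.write_fasta(out / "genome.fa", genome)
        io.write_gff3(out / "genes.gff3", genes)
        io.write_zones(out / "zones.tsv", zones)
        mmp.to_tsv(out / "mmp.tsv")
        io.write_cohort(out / "calls", cohort, genome)
        io.write_truth(out / "truth.tsv", sim.truth_frame(truths))

        frame = sim.truth_frame(truths)
        n_genes_hit = frame.target_gene.nunique()
        n_paired = (frame.target_gene.value_counts() >= 2).sum()
        rows.append(
            dict(cohort=name, balancer=config.kind, strains=n_strains,
                 mean_depth=sim.DEFAULT_DEPTH[config.kind],
                 target_genes=n_genes_hit, two_allele_genes=int(n_paired),
                 zones=len(zones), calls=len(cohort))
        )
        print(f"{name}: {n_strains} strains, {n_genes_hit} target genes "
              f"({n_paired} with two alleles), {len(cohort)} calls -> {out}")
    pd.DataFrame(rows).to_csv(RESULTS / "01_cohorts.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
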