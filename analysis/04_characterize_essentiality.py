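"""Characterize essential-gene traits.

Four analyses:
 1. conservation tally of the curated 60-gene table (clades N/I/M/F);
 2. duplicability, connectivity and expression of synthetic essential-like
    (G1, G2) vs nonessential-like (G3, G4) gene groups, compared by Fisher's
    exact test;
 3. conservation of the 100-residue window around a missense site in a
    synthetic ortholog alignment;
 4. the N-terminal position bias of nonsense vs missense lethal alleles in
    the simulated cohorts.

Run from the repository root:  python analysis/04_characterize_essentiality.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from balancerscan import io, simulate as sim, traits
from balancerscan.effects import VariantEffect

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "cohorts"
RESULTS = ROOT / "results"

GROUP_SIZES = {"G1": 143, "G2": 1208, "G3": 796, "G4": 2000}
# G4 stands in for the genome-wide no-phenotype class, scaled down from
# ~12,800 genes to keep the tables small; proportions, not counts, are
# what the comparisons use.


def conservation() -> None:
    counts = traits.conservation_tally(io.load_conservation_table())
    pct = traits.conservation_percentages(counts)
    frame = pd.DataFrame(
        dict(category=list(counts), genes=list(counts.values()),
             percent=[round(pct[k], 1) for k in counts])
    )
    frame.to_csv(RESULTS / "04_conservation_tally.tsv", sep="\t", index=False)
    print("conservation tally:", counts)


def group_traits() -> None:
    groups = sim.simulate_gene_groups(GROUP_SIZES, seed=40)

    paralogs = sim.simulate_paralog_table(
        groups,
        {"G1": 0.08, "G2": 0.09, "G3": 0.25, "G4": 0.30},
        seed=41,
    )
    dup = traits.classify_duplicability(paralogs, genes=list(groups.gene_id))
    singleton = {g: cls == "singleton" for g, cls in dup.items()}
    dup_cmp = traits.group_proportion_compare(singleton, groups)
    dup_cmp.to_csv(RESULTS / "04_duplicability.tsv", sep="\t", index=False)
    print("singleton proportions:\n", dup_cmp.to_string(index=False))

    inter = sim.simulate_interaction_table(
        groups, {"G1": 12.0, "G2": 11.0, "G3": 5.0, "G4": 3.0}, seed=42
    )
    conn = traits.connectivity_summary(inter, groups)
    conn.to_csv(RESULTS / "04_connectivity.tsv", sep="\t", index=False)
    print("hub (>10 interactors) fractions:\n",
          conn[["group", "frac_>10", "hub_p_vs_G1"]].to_string(index=False))

    expr = sim.simulate_expression_matrix(
        groups, n_stages=23,
        multiplier_by_group={"G1": 4.0, "G2": 4.0}, seed=43,
    )
    summary, slopes = traits.expression_summary(expr, groups)
    summary.to_csv(RESULTS / "04_expression_stages.tsv", sep="\t", index=False)
    print("expression trend slopes (log2 RPKM per stage):",
          {k: round(v, 4) for k, v in slopes.items()})


def window_demo() -> None:
    """Synthetic ortholog alignment: conserved core, divergent flanks."""
    rng = np.random.default_rng(44)
    core = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 140))
    rows = []
    for _ in range(26):
        row = list(core)
        for i in range(len(row)):
            # flanks diverge freely; the 100-residue core window is conserved
            p_mut = 0.05 if 20 <= i < 120 else 0.6
            if rng.random() < p_mut:
                row[i] = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"))
        rows.append("".join(row))
    out = traits.window_conservation([core, *rows], mutated_position=70)
    pd.DataFrame(
        dict(column=out.columns, identity=np.round(out.identities, 3))
    ).to_csv(RESULTS / "04_window_conservation.tsv", sep="\t", index=False)
    print(f"window mean identity {out.window_mean:.3f} "
          f"(conserved: {out.conserved})")


def nonsense_positions() -> None:
    effects = []
    for name in ("sdp3_like", "et1_like"):
        truth = io.read_truth(SCRATCH / name / "truth.tsv")
        genome = io.read_fasta(SCRATCH / name / "genome.fa")
        genes = {g.gene_id: g for g in io.read_gff3(SCRATCH / name / "genes.gff3")}
        for r in truth.itertuples():
            gene = genes[r.target_gene]
            cds_pos = gene.cds_position(int(r.pos))
            if cds_pos is None or r.consequence not in ("missense", "nonsense"):
                continue
            effects.append(
                VariantEffect(r.target_gene, gene.transcript_id, r.consequence,
                              relative_position=cds_pos / gene.cds_length)
            )
    out = traits.nonsense_position_stat(effects, 10_000, seed=45)
    pd.DataFrame(
        [dict(consequence=k, mean_relative_position=round(v, 3),
              n=out.n.get(k, 0)) for k, v in out.class_means.items()]
    ).to_csv(RESULTS / "04_nonsense_position.tsv", sep="\t", index=False)
    print("mean relative CDS positions:",
          {k: round(v, 3) for k, v in out.class_means.items()},
          f"permutation p = {out.p_value:.4g}"
          if out.p_value is not None else "(comparison skipped)")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    conservation()
    group_traits()
    window_demo()
    nonsense_positions()


if __name__ == "__main__":
    main()
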