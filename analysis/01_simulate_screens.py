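"""Generate the synthetic isogenic screen campaign.

Writes the guide library (chip CSV), screen design, count matrix and
reference gene lists under scratch/screens/ in the formats the rest of the
pipeline reads.
"""

from common import SCRATCH, SEED, build_scenario

from oncodep import screen_io, synthetic_data as sd


def main() -> None:
    scenario = build_scenario(SEED)
    library = sd.simulate_library(scenario)
    design = sd.standard_design(n_replicates=2, control_replicates=3)
    counts = sd.simulate_screen(library, design, scenario)

    outdir = SCRATCH / "screens"
    outdir.mkdir(parents=True, exist_ok=True)
    screen_io.write_chip(library, outdir / "chip.csv")
    screen_io.write_design(design, outdir / "design.tsv")
    screen_io.write_count_matrix(counts, outdir / "counts.tsv")
    gdir = outdir / "genesets"
    gdir.mkdir(exist_ok=True)
    for name, genes in scenario.registry().sets.items():
        screen_io.write_gene_list(genes, gdir / f"{name}.txt")

    print(f"library: {len(library.table)} guides "
          f"({library.n_controls} non-targeting)")
    print(f"screen: {counts.counts.shape[0]} guides x "
          f"{counts.counts.shape[1]} samples -> {outdir}")


if __name__ == "__main__":
    main()
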