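"""Gene-level one-sided permutation tests per screen arm.

For each (line, condition) arm: guide-level CS averaged over replicates,
alpha-RRA rank aggregation in both directions, permutation p-values, and a
merged per-arm score table written to scratch/rra/<line>_<condition>.tsv.
A summary of significant-gene counts goes to results/test_summary.tsv.
"""

import importlib

import pandas as pd
from common import RESULTS, SCRATCH, SEED

from oncodep import screen_io
from oncodep.counts_qc import exclude_cross_targeting
from oncodep.pipeline import arm_guide_cs
from oncodep.significance import run_both_directions

load_screen = importlib.import_module("02_screen_qc").load_screen

N_PERMUTATIONS = 1000


def main() -> None:
    _, library, _ = load_screen()
    guide_table = screen_io.read_scores(SCRATCH / "scores" / "guide_scores.tsv")
    gene_table = screen_io.read_scores(SCRATCH / "scores" / "gene_scores.tsv")

    outdir = SCRATCH / "rra"
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    arms = guide_table[["cell_line", "condition"]].drop_duplicates()
    for i, (line, cond) in enumerate(arms.itertuples(index=False)):
        lib_arm = exclude_cross_targeting(library, line)
        stats = arm_guide_cs(guide_table, line, cond)
        stats = stats.loc[stats.index.intersection(lib_arm.guide_ids)]
        tested = run_both_directions(stats, lib_arm.guide_to_gene(),
                                     n_permutations=N_PERMUTATIONS,
                                     seed=SEED * 1000 + 2 * i)
        cs = gene_table[(gene_table["cell_line"] == line)
                        & (gene_table["condition"] == cond)]
        merged = tested.merge(cs[["gene", "cs"]], on="gene")
        screen_io.write_scores(merged, outdir / f"{line}_{cond}.tsv")
        rows.append({
            "cell_line": line, "condition": cond,
            "n_sig_depleted": int(((merged["p_depletion"] < 0.05)
                                   & (merged["cs"] < -0.5)).sum()),
            "n_sig_enriched": int(((merged["p_enrichment"] < 0.05)
                                   & (merged["cs"] > 0.5)).sum())})
    summary = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    screen_io.write_scores(summary, RESULTS / "test_summary.tsv")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
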