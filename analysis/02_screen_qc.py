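"""Replicate quality control for the simulated campaign.

Reads the screen from scratch/screens/, applies the low-abundance filter,
and reports per-replicate SSMD (pass at < -0.5) and pairwise replicate
correlations; writes results/qc_report.tsv and results/qc_correlations.tsv.
"""

import pandas as pd
from common import RESULTS, SCRATCH

from oncodep import screen_io
from oncodep.counts_qc import qc_screen


def load_screen():
    base = SCRATCH / "screens"
    library = screen_io.read_chip(base / "chip.csv")
    design = screen_io.read_design(base / "design.tsv")
    counts = screen_io.read_count_matrix(base / "counts.tsv", library, design)
    qc_essential = screen_io.read_gene_list(base / "genesets" / "qc_essential.txt")
    return counts, library, qc_essential


def main() -> None:
    counts, library, qc_essential = load_screen()
    _, _, report = qc_screen(counts, library, qc_essential)

    RESULTS.mkdir(exist_ok=True)
    frame = report.as_frame()
    screen_io.write_scores(frame, RESULTS / "qc_report.tsv")
    screen_io.write_scores(report.replicate_correlation,
                           RESULTS / "qc_correlations.tsv")

    print(f"low-abundance guides removed: {report.n_low_abundance_removed}")
    print(f"median SSMD: {frame['ssmd'].median():.2f}; "
          f"{int(frame['pass'].sum())}/{len(frame)} replicates pass (< -0.5)")
    r2 = report.replicate_correlation["r2"]
    print(f"replicate r^2 range: {r2.min():.2f}-{r2.max():.2f}")


if __name__ == "__main__":
    main()
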