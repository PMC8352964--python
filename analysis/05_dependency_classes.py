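"""Dependency classification and comparison against the planted truth.

Reads the per-arm score tables, applies the |CS| > 0.5 & p < 0.05 rule,
partitions erlotinib-essential genes across the three lines (Venn), assigns
the dependency classes, and scores them against the genes the generator
planted.  Writes results/dependency_calls.tsv, results/venn.tsv and
results/recovery.tsv.
"""

import pandas as pd
from common import LINES, RESULTS, SCRATCH, planted_truth

from oncodep import screen_io
from oncodep.dependency_map import call_arm, classify_dependencies


def main() -> None:
    arm_calls = {}
    for path in sorted((SCRATCH / "rra").glob("*.tsv")):
        line, cond = path.stem.rsplit("_", 1)
        arm_calls[(line, cond)] = call_arm(screen_io.read_scores(path))
    calls = classify_dependencies(arm_calls)

    RESULTS.mkdir(exist_ok=True)
    screen_io.write_scores(calls.labels, RESULTS / "dependency_calls.tsv")
    pd.Series(calls.venn).rename("count").rename_axis("region") \
        .reset_index().to_csv(RESULTS / "venn.tsv", sep="\t", index=False)

    truth = planted_truth()
    rows = []
    for label, by_line in truth.items():
        for line, genes in by_line.items():
            called = calls.genes_with_label(label, line)
            rows.append({
                "label": label, "cell_line": line, "n_planted": len(genes),
                "n_recovered": len(genes & called),
                "recovery": len(genes & called) / len(genes),
                "n_extra_calls": len(called - genes)})
    recovery = pd.DataFrame(rows)
    screen_io.write_scores(recovery, RESULTS / "recovery.tsv")

    print("venn (erlotinib-essential):", calls.venn)
    print(recovery.to_string(index=False))
    pan = calls.genes_with_label("pan_essential")
    print(f"pan-essential genes: {len(pan)} "
          "(the planted essential reference block)")


if __name__ == "__main__":
    main()
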