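"""Dependency classification across isogenic lines.

A gene is "essential" in an arm when CS < -cs_cut with depletion p < p_cut,
and "positively selected" when CS > +cs_cut with enrichment p < p_cut
(defaults 0.5 and 0.05).  Cross-line classes:

- pan_essential: essential in every oncogene line's erlotinib arm;
- oncogene_dependency(line): essential in that line's erlotinib arm but not
  in the control line's vehicle (DMSO) arm;
- baseline_synthetic_lethal(line): essential in that line's DMSO arm but
  not in the control line's DMSO arm;
- cooperating_knockout(line): positively selected in that line's erlotinib
  arm.

A gene may carry several line-scoped labels; each is recorded separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_CS_CUT = 0.5
DEFAULT_P_CUT = 0.05


def call_gene(
    cs: float,
    p_depletion: float,
    p_enrichment: float,
    cs_cut: float = DEFAULT_CS_CUT,
    p_cut: float = DEFAULT_P_CUT,
) -> tuple[bool, bool]:
    """(essential, positively_selected) flags for one gene in one arm."""
    essential = (cs < -cs_cut) and (p_depletion < p_cut)
    selected = (cs > cs_cut) and (p_enrichment < p_cut)
    return essential, selected


def call_arm(
    scores: pd.DataFrame,
    cs_cut: float = DEFAULT_CS_CUT,
    p_cut: float = DEFAULT_P_CUT,
) -> pd.DataFrame:
    """Vectorized calls over a per-gene table with columns (gene, cs,
    p_depletion, p_enrichment)."""
    out = scores[["gene"]].copy()
    out["essential"] = (scores["cs"] < -cs_cut) & (scores["p_depletion"] < p_cut)
    out["positively_selected"] = (
        (scores["cs"] > cs_cut) & (scores["p_enrichment"] < p_cut))
    return out


def venn_partition(sets: Mapping[str, set]) -> dict[str, int]:
    """Exhaustive disjoint region counts for three named sets.

    Keys: "all" (shared by the three), "<name>_only" for each set, and
    "<a>&<b>" for each pair (members of exactly that pair).  Counts sum to
    the size of the union.
    """
    names = list(sets)
    if len(names) != 3:
        raise ValueError("venn_partition expects exactly three sets")
    a, b, c = (set(sets[n]) for n in names)
    out = {"all": len(a & b & c)}
    universe = {names[0]: a, names[1]: b, names[2]: c}
    for n in names:
        others = [universe[m] for m in names if m != n]
        out[f"{n}_only"] = len(universe[n] - others[0] - others[1])
    for n1, n2 in combinations(names, 2):
        rest = next(m for m in names if m not in (n1, n2))
        out[f"{n1}&{n2}"] = len(
            (universe[n1] & universe[n2]) - universe[rest])
    return out


@dataclass
class DependencyCallSet:
    """Per-gene flags per arm plus line-scoped class labels."""

    flags: pd.DataFrame  # columns: gene, cell_line, condition, essential, positively_selected
    labels: pd.DataFrame  # columns: gene, label, cell_line (empty for pan_essential)
    venn: dict[str, int] = field(default_factory=dict)
    cs_cut: float = DEFAULT_CS_CUT
    p_cut: float = DEFAULT_P_CUT

    def genes_with_label(self, label: str, cell_line: str | None = None) -> set[str]:
        m = self.labels["label"] == label
        if cell_line is not None:
            m &= self.labels["cell_line"] == cell_line
        return set(self.labels.loc[m, "gene"])


def classify_dependencies(
    arm_calls: Mapping[tuple[str, str], pd.DataFrame],
    oncogene_lines: Sequence[str] = ("EGFR", "KRAS", "RIT1"),
    control_line: str = "control",
    cs_cut: float = DEFAULT_CS_CUT,
    p_cut: float = DEFAULT_P_CUT,
) -> DependencyCallSet:
    """Assign dependency classes from per-arm call tables.

    ``arm_calls`` maps (cell_line, condition) to a table from
    :func:`call_arm`.  Requires the control line's DMSO arm and, for each
    oncogene line, both DMSO and erlotinib arms.  Genes filtered out of some
    arms are classified on the arms where they are present; coverage is
    recorded in the flags table.
    """
    needed = [(control_line, "DMSO")]
    for line in oncogene_lines:
        needed += [(line, "DMSO"), (line, "erlotinib")]
    for arm in needed:
        if arm not in arm_calls:
            raise ValueError(f"missing arm {arm}")

    flag_rows = []
    for (line, cond), table in arm_calls.items():
        t = table.copy()
        t["cell_line"], t["condition"] = line, cond
        flag_rows.append(t)
    flags = pd.concat(flag_rows, ignore_index=True)

    def ess(line: str, cond: str) -> set[str]:
        t = arm_calls[(line, cond)]
        return set(t.loc[t["essential"], "gene"])

    def sel(line: str, cond: str) -> set[str]:
        t = arm_calls[(line, cond)]
        return set(t.loc[t["positively_selected"], "gene"])

    control_ess = ess(control_line, "DMSO")
    label_rows: list[dict] = []

    pan = set.intersection(*(ess(line, "erlotinib") for line in oncogene_lines))
    label_rows += [{"gene": g, "label": "pan_essential", "cell_line": ""}
                   for g in sorted(pan)]
    for line in oncogene_lines:
        for g in sorted(ess(line, "erlotinib") - control_ess):
            label_rows.append({"gene": g, "label": "oncogene_dependency",
                               "cell_line": line})
        for g in sorted(ess(line, "DMSO") - control_ess):
            label_rows.append({"gene": g, "label": "baseline_synthetic_lethal",
                               "cell_line": line})
        for g in sorted(sel(line, "erlotinib")):
            label_rows.append({"gene": g, "label": "cooperating_knockout",
                               "cell_line": line})

    labels = pd.DataFrame(label_rows,
                          columns=["gene", "label", "cell_line"])
    venn = venn_partition({line: ess(line, "erlotinib")
                           for line in oncogene_lines})
    return DependencyCallSet(flags, labels, venn, cs_cut, p_cut)


def differential_cs(gene_cs_a: pd.Series, gene_cs_b: pd.Series) -> pd.DataFrame:
    """Per-gene delta CS = cs_A - cs_B over the common gene universe, ranked
    ascending; antisymmetric under swapping the two lines."""
    common = gene_cs_a.index.intersection(gene_cs_b.index)
    d = (gene_cs_a.loc[common] - gene_cs_b.loc[common]).astype(float)
    out = pd.DataFrame({"gene": common, "delta_cs": d.to_numpy()})
    out = out.sort_values("delta_cs", kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
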