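"""End-to-end screen analysis: QC -> CRISPR scores -> per-arm alpha-RRA
permutation tests -> dependency classification.

This is the orchestration layer the drivers, the command line and the
acceptance checks share; each stage lives in its own module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .counts_qc import QCReport, exclude_cross_targeting, qc_screen
from .crispr_score import score_screen
from .dependency_map import (DEFAULT_CS_CUT, DEFAULT_P_CUT, DependencyCallSet,
                             call_arm, classify_dependencies)
from .screen_io import CountMatrix, GeneSetRegistry, GuideLibrary
from .significance import run_both_directions


@dataclass
class ScreenAnalysis:
    """Everything one screen analysis produces."""

    qc: QCReport
    guide_table: pd.DataFrame
    gene_table: pd.DataFrame
    arm_scores: dict[tuple[str, str], pd.DataFrame]
    calls: DependencyCallSet


def arm_guide_cs(guide_table: pd.DataFrame, cell_line: str,
                 condition: str) -> pd.Series:
    """Guide-level CS for one arm, averaged over that arm's replicates."""
    sub = guide_table[(guide_table["cell_line"] == cell_line)
                      & (guide_table["condition"] == condition)]
    if sub.empty:
        raise ValueError(f"no samples for arm {(cell_line, condition)}")
    return sub.groupby("guide_id")["cs"].mean()


def analyze_screen(
    counts: CountMatrix,
    library: GuideLibrary,
    registry: GeneSetRegistry,
    oncogene_lines: Sequence[str] = ("EGFR", "KRAS", "RIT1"),
    control_line: str = "control",
    rpm_threshold: float = 1.0,
    pseudocount: float = 1.0,
    baseline: str = "plasmid",
    alpha: float = 0.25,
    n_permutations: int = 1000,
    seed: int = 0,
    cs_cut: float = DEFAULT_CS_CUT,
    p_cut: float = DEFAULT_P_CUT,
) -> ScreenAnalysis:
    """Run the full chain on one pooled screen with shared plasmid baseline."""
    counts, library, qc = qc_screen(
        counts, library, registry["qc_essential"], rpm_threshold)
    guide_table, gene_table = score_screen(
        counts, library, registry, pseudocount, baseline)

    arms = sorted({(s.cell_line, s.condition)
                   for s in counts.endpoint_samples()})
    arm_scores: dict[tuple[str, str], pd.DataFrame] = {}
    arm_calls: dict[tuple[str, str], pd.DataFrame] = {}
    for i, (line, cond) in enumerate(arms):
        lib_arm = exclude_cross_targeting(library, line) if line in oncogene_lines else library
        stats = arm_guide_cs(guide_table, line, cond)
        stats = stats.loc[stats.index.intersection(lib_arm.guide_ids)]
        tested = run_both_directions(
            stats, lib_arm.guide_to_gene(), alpha=alpha,
            n_permutations=n_permutations, seed=seed * 1000 + i * 2)
        gene_cs = gene_table[(gene_table["cell_line"] == line)
                             & (gene_table["condition"] == cond)]
        merged = tested.merge(gene_cs[["gene", "cs"]], on="gene")
        arm_scores[(line, cond)] = merged
        arm_calls[(line, cond)] = call_arm(merged, cs_cut, p_cut)

    calls = classify_dependencies(arm_calls, oncogene_lines, control_line,
                                  cs_cut, p_cut)
    return ScreenAnalysis(qc, guide_table, gene_table, arm_scores, calls)
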