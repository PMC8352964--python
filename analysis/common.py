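"""Shared study design for the analysis drivers.

One synthetic isogenic screen campaign: three oncogene-expressing lines
(EGFR, KRAS, RIT1) plus a vector control, each screened against the same
library, with line-specific oncogene dependencies, baseline synthetic
lethals, and RIT1-specific cooperating (positively selected) knockouts
planted at known positions so every downstream claim can be checked against
ground truth.
"""

from pathlib import Path

from oncodep import synthetic_data as sd

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"

LINES = ("EGFR", "KRAS", "RIT1")
N_GENES = 800
PER_CLASS = 20
SEED = 1

GENES = [f"GENE{i:05d}" for i in range(N_GENES)]


def planted_truth() -> dict[str, dict[str, set[str]]]:
    """Ground-truth gene sets per class and line."""
    start = 160  # past the essential/nonessential anchor blocks
    truth: dict[str, dict[str, set[str]]] = {
        "oncogene_dependency": {}, "baseline_synthetic_lethal": {},
        "cooperating_knockout": {}}
    cursor = start
    for line in LINES:
        truth["oncogene_dependency"][line] = set(GENES[cursor:cursor + PER_CLASS])
        cursor += PER_CLASS
    for line in LINES:
        truth["baseline_synthetic_lethal"][line] = set(GENES[cursor:cursor + PER_CLASS])
        cursor += PER_CLASS
    truth["cooperating_knockout"]["RIT1"] = set(GENES[cursor:cursor + PER_CLASS])
    return truth


def build_scenario(seed: int = SEED) -> sd.ScreenScenario:
    truth = planted_truth()
    effects: dict = {}
    for line, genes in truth["oncogene_dependency"].items():
        for g in genes:
            effects[(g, line, "erlotinib")] = -0.25
    for line, genes in truth["baseline_synthetic_lethal"].items():
        for g in genes:
            effects[(g, line, "DMSO")] = -0.25
            effects[(g, line, "erlotinib")] = -0.25
    for line, genes in truth["cooperating_knockout"].items():
        for g in genes:
            effects[(g, line, "erlotinib")] = +0.15
    return sd.ScreenScenario(n_genes=N_GENES, n_control_guides=200,
                             effects=effects, seed=seed)
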