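"""Generators for screens, drug plates and tumor cohorts with the
statistical structure the analysis assumes.

The screen generator plants per-gene, per-arm fitness effects expressed in
log2 units per population doubling, so an effect e over D doublings maps to
an expected guide log2 fold-change of e*D against the plasmid library.
Plasmid representation is log-normal; sequencing counts are negative
binomial around expected proportions renormalized per sample (sequencing
measures relative, not absolute, abundance).  Reference essential genes
carry a strong negative effect in every endpoint arm; reference
nonessential genes and non-targeting controls are neutral, which is what
anchored CRISPR-score scaling and SSMD quality control assume.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import NON_TARGETING
from .cooccurrence import HIPPO_GENES, CohortTable
from .drug_screen import logistic
from .screen_io import CountMatrix, GeneSetRegistry, GuideLibrary, SampleMeta

# fixed sub-stream keys so each generator is independently reproducible
_KEY_LIBRARY, _KEY_SCREEN, _KEY_PLATE, _KEY_COHORT = 11, 13, 17, 19


@dataclass
class ScreenScenario:
    """Study conditions for one synthetic screen.

    ``effects`` maps (gene, cell_line, condition) to a fitness effect in
    log2 units per population doubling; unlisted combinations default to 0.
    The first ``essential_frac`` of genes form the essential reference set
    and carry ``essential_effect`` in every endpoint arm; the next
    ``nonessential_frac`` form the neutral nonessential reference set.
    """

    n_genes: int = 1000
    guides_per_gene: int = 4
    n_control_guides: int = 100
    doublings: float = 12.0
    depth: float = 500.0
    dispersion: float = 10.0
    plasmid_spread: float = 0.5
    effects: dict = field(default_factory=dict)
    essential_frac: float = 0.10
    nonessential_frac: float = 0.10
    essential_effect: float = -0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.guides_per_gene, self.n_control_guides) <= 0:
            raise ValueError("all counts must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.depth <= 0 or self.plasmid_spread < 0:
            raise ValueError("invalid depth or plasmid_spread")

    @property
    def gene_names(self) -> list[str]:
        return [f"GENE{i:05d}" for i in range(self.n_genes)]

    @property
    def essential_genes(self) -> list[str]:
        k = int(round(self.essential_frac * self.n_genes))
        return self.gene_names[:k]

    @property
    def nonessential_genes(self) -> list[str]:
        k = int(round(self.essential_frac * self.n_genes))
        m = int(round(self.nonessential_frac * self.n_genes))
        return self.gene_names[k:k + m]

    def registry(self) -> GeneSetRegistry:
        reg = GeneSetRegistry()
        reg.add("essential_ref", self.essential_genes)
        reg.add("nonessential_ref", self.nonessential_genes)
        # the QC essential set plays the role of the constitutive
        # spliceosome/ribosome/proteasome panel: genes lethal everywhere
        reg.add("qc_essential", self.essential_genes)
        return reg

    def effect(self, gene: str, cell_line: str, condition: str) -> float:
        if (gene, cell_line, condition) in self.effects:
            return float(self.effects[(gene, cell_line, condition)])
        if gene in set(self.essential_genes):
            return self.essential_effect
        return 0.0


@dataclass
class CohortScenario:
    """Study conditions for one synthetic tumor cohort."""

    n_tumors: int = 230
    alteration_rate: float = 37 / 230
    hippo_genes: Sequence[str] = HIPPO_GENES
    low_rate_altered: float = 0.757
    low_rate_nonaltered: float = 0.456
    expression_sd: float = 1.0
    mutation_fraction: float = 5 / 37  # of altered tumors (the rest amplified)
    mean_expression: float = 8.0  # log2-TPM-like location
    amp_expression_shift: float = 1.0  # index-gene bump in amplified tumors
    index_gene: str = "RIT1"
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.alteration_rate, self.low_rate_altered,
                  self.low_rate_nonaltered, self.mutation_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.n_tumors < 2 or self.expression_sd <= 0:
            raise ValueError("invalid n_tumors or expression_sd")


def _rng(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def simulate_library(scenario: ScreenScenario) -> GuideLibrary:
    """Brunello-like library: guides_per_gene targeting guides per gene plus
    non-targeting controls, with random distinct 20-nt sequences."""
    rng = _rng(scenario.seed, _KEY_LIBRARY)
    n = scenario.n_genes * scenario.guides_per_gene + scenario.n_control_guides
    bases = np.array(list("ACGT"))
    seqs = ["".join(row) for row in bases[rng.integers(0, 4, size=(n, 20))]]
    rows = []
    i = 0
    for gene in scenario.gene_names:
        for j in range(scenario.guides_per_gene):
            rows.append((f"{gene}_sg{j + 1}", seqs[i], gene, False))
            i += 1
    for j in range(scenario.n_control_guides):
        rows.append((f"NTC{j + 1:04d}", seqs[i], NON_TARGETING, True))
        i += 1
    return GuideLibrary(pd.DataFrame(
        rows, columns=["guide_id", "sequence", "gene", "is_control"]))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.clip(mean, 1e-12, None)
    if np.isinf(dispersion):
        return rng.poisson(mean)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_screen(
    library: GuideLibrary,
    design: Sequence[SampleMeta],
    scenario: ScreenScenario,
) -> CountMatrix:
    """Draw a guide x sample count matrix with planted fitness effects.

    Plasmid guide proportions are log-normal(0, plasmid_spread), normalized.
    An endpoint sample's expected proportions are the plasmid proportions
    times 2^(doublings * effect(gene, line, condition)), renormalized;
    counts are negative binomial with mean proportional to those proportions
    at an average of ``depth`` reads per guide.  ETP samples have zero
    doublings.  Non-targeting guides always have effect 0.
    """
    if not any(s.condition == "plasmid" for s in design):
        raise ValueError("design must contain a plasmid sample")
    rng = _rng(scenario.seed, _KEY_SCREEN)
    g2g = library.guide_to_gene()
    guides = library.guide_ids
    n_guides = len(guides)
    total_reads = scenario.depth * n_guides

    base = rng.lognormal(mean=0.0, sigma=scenario.plasmid_spread, size=n_guides)
    plasmid_prop = base / base.sum()

    effect_cache: dict[tuple[str, str], np.ndarray] = {}

    def arm_effects(line: str, condition: str) -> np.ndarray:
        key = (line, condition)
        if key not in effect_cache:
            eff = np.array([
                0.0 if g2g[g] == NON_TARGETING
                else scenario.effect(g2g[g], line, condition)
                for g in guides
            ])
            effect_cache[key] = eff
        return effect_cache[key]

    cols = {}
    for s in design:
        if s.condition == "plasmid":
            mean = plasmid_prop * total_reads
        else:
            doublings = 0.0 if s.condition == "ETP" else scenario.doublings
            eff = arm_effects(s.cell_line, s.condition)
            prop = plasmid_prop * np.exp2(doublings * eff)
            prop = prop / prop.sum()
            mean = prop * total_reads
        cols[s.sample_id] = _nb_draw(rng, mean, scenario.dispersion)
    counts = pd.DataFrame(cols, index=guides)
    counts.index.name = "guide_id"
    return CountMatrix(counts, list(design))


def standard_design(
    lines: Sequence[str] = ("EGFR", "KRAS", "RIT1"),
    n_replicates: int = 2,
    control_replicates: int = 3,
    include_etp: bool = False,
) -> list[SampleMeta]:
    """The isogenic screen layout: one plasmid sample, a vehicle-only control
    line, and DMSO + erlotinib arms for each oncogene line."""
    design = [SampleMeta("plasmid", "other", "plasmid", 1)]
    if include_etp:
        design += [SampleMeta(f"ETP_{r}", "other", "ETP", r)
                   for r in range(1, n_replicates + 1)]
    design += [SampleMeta(f"control_DMSO_{r}", "control", "DMSO", r)
               for r in range(1, control_replicates + 1)]
    for line in lines:
        for cond in ("DMSO", "erlotinib"):
            design += [SampleMeta(f"{line}_{cond}_{r}", line, cond, r)
                       for r in range(1, n_replicates + 1)]
    return design


def simulate_dose_response(
    true_params: tuple[float, float, float, float],
    doses: Sequence[float],
    noise_sd: float,
    seed: int,
    n_replicates: int = 1,
    compound: str = "compound",
) -> pd.DataFrame:
    """Long-format plate table (compound, dose, replicate, viability) from a
    logistic curve plus Gaussian noise, truncated at 0."""
    doses = np.asarray(doses, dtype=float)
    if (doses <= 0).any():
        raise ValueError("doses must be positive")
    top, bottom, log10_ec50, hill = true_params
    rng = _rng(seed, _KEY_PLATE)
    clean = logistic(doses, top, bottom, log10_ec50, hill)
    rows = []
    for r in range(1, n_replicates + 1):
        v = clean + rng.normal(0.0, noise_sd, size=doses.size) if noise_sd > 0 else clean
        v = np.clip(v, 0.0, None)
        for d, vi in zip(doses, v):
            rows.append({"compound": compound, "dose": d, "replicate": r,
                         "viability": vi})
    return pd.DataFrame(rows)


# offsets (in units of expression_sd below the mean) for the two expression
# components; the empirical mean-1sd threshold must land between them, which
# holds whenever each pathway gene carries lows in >= ~3% of tumors
_SAFE_TRUNCATION = -1.0
_LOW_OFFSET = -5.0


def simulate_cohort(scenario: CohortScenario) -> CohortTable:
    """Draw a tumor cohort whose derived low-expression indicator reproduces
    the planted class-conditional any-low rates.

    Alteration is Bernoulli(alteration_rate), split into mutation and
    amplification; the any-pathway-gene-low indicator is Bernoulli with the
    class-conditional rate; expression is drawn from a two-component model
    (safe values truncated at mean - 1 sd, planted lows at mean - 5 sd) so
    the empirical low-expression rule recovers the planted indicator
    exactly.  Self-consistency is verified after drawing.
    """
    rng = _rng(scenario.seed, _KEY_COHORT)
    n = scenario.n_tumors
    s = scenario.expression_sd
    mu = scenario.mean_expression

    altered = rng.random(n) < scenario.alteration_rate
    mutation = altered & (rng.random(n) < scenario.mutation_fraction)
    amplification = altered & ~mutation
    diploid = ~amplification

    rate = np.where(altered, scenario.low_rate_altered, scenario.low_rate_nonaltered)
    low_indicator = rng.random(n) < rate
    # each low tumor gets exactly one low pathway gene, chosen uniformly
    genes = list(scenario.hippo_genes)
    which_gene = rng.integers(0, len(genes), size=n)

    data = {"tumor_id": [f"T{i + 1:04d}" for i in range(n)],
            "mutation": mutation, "amplification": amplification,
            "diploid": diploid}
    for gi, gene in enumerate(genes):
        # safe component: normal truncated to >= mu + _SAFE_TRUNCATION * s
        z = rng.normal(size=n)
        # reflect the lower tail instead of rejection sampling: keeps the
        # draw vectorized and deterministic; the shape change is irrelevant
        z = np.where(z < _SAFE_TRUNCATION, 2 * _SAFE_TRUNCATION - z, z)
        x = mu + s * z
        is_low_here = low_indicator & (which_gene == gi)
        x[is_low_here] = mu + s * (_LOW_OFFSET + 0.2 * rng.normal(size=int(is_low_here.sum())))
        data[f"expr_{gene}"] = x

    # index-gene expression tracks amplification, referenced to diploids
    data[f"expr_{scenario.index_gene}"] = (
        mu + scenario.amp_expression_shift * s * amplification
        + s * rng.normal(size=n))

    cohort = CohortTable(pd.DataFrame(data), index_gene=scenario.index_gene)

    from .cooccurrence import any_low  # local import avoids cycle at module load

    derived = any_low(cohort, genes).to_numpy()
    if not np.array_equal(derived, low_indicator):
        raise RuntimeError(
            "scenario outside the generator's validity region: the empirical "
            "low-expression rule does not reproduce the planted indicator "
            "(each pathway gene needs planted lows in >= ~3% of tumors)")
    return cohort
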