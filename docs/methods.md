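# Methods

## The screening model

The package targets isogenic pooled CRISPR knockout screens: a genome-scale
guide library (≈4 guides per gene plus non-targeting controls, mirroring
Brunello-style designs) infected into cell lines that differ only in an
introduced oncogene, grown for ~12 population doublings under vehicle
(DMSO) or drug (erlotinib), with guide abundance read out by sequencing and
compared to the starting plasmid library. A guide knocking out a gene with
fitness effect e (log2 units per doubling) is expected to change abundance
by e·D log2 units over D doublings; everything downstream is a way of
estimating and testing that quantity robustly.

The plasmid library, not the early time point (ETP), is the baseline for
all fold-changes; ETP comparison is available behind the `baseline`
argument of `score_screen`. The rationale is that ETP samples track the
plasmid closely, and a single common baseline keeps arms comparable.

## Quality control

- **Low-abundance filter.** Guides with < 1 read-per-million in the plasmid
  sample are removed from all samples before scoring. The filter runs
  before normalization and scoring; it is idempotent.
- **Cross-targeting exclusions.** Screens of an oncogene-expressing line
  must drop guides that cannot cut the introduced cDNA, since in that line
  they fail to report the oncogene's own essentiality. The default table
  carries the four published guide sequences (one for KRAS, two for RIT1,
  one for EGFR); it is an ordinary mapping and can be replaced.
- **SSMD.** Replicate quality contrasts LFCs of guides targeting a
  constitutively essential panel (spliceosome/ribosome/proteasome-style;
  in synthetic screens the essential reference set stands in for it)
  against non-targeting controls:
  SSMD = (median(ess) − median(ntc)) / √(MADs(ess)² + MADs(ntc)²). The
  phrase "median average deviation" in screen write-ups is read as the
  median absolute deviation with the 1.4826 normal-consistency constant —
  the standard robust scale estimator. The sign convention makes passing
  replicates negative (essential dropout), with the pass bar at
  SSMD < −0.5. Degenerate inputs: both MADs zero with equal medians gives
  0; with unequal medians, a signed infinity plus a warning.

## CRISPR scores

Per replicate: LFC = log2((RPM + c)/(RPM_plasmid + c)) with pseudocount
c = 1 RPM (bounds the LFC of zero-count guides; the value is conventional,
not fitted); robust normalization (x − median)/MADs; then an affine anchor
map cs = (x − m_non)/(m_non − m_ess) where m_non and m_ess are the
per-replicate medians over reference nonessential and essential genes. By
construction the anchor medians land exactly on (0, −1) every run, and the
chain is invariant to rescaling any sample's raw counts.

Two genuinely open choices, resolved as follows:

- **Gene-first anchoring.** Anchor medians are taken over per-gene means of
  guide-level values rather than over raw guides, so anchor sets with
  unequal guide counts are not dominated by large genes.
- **Mean collapse.** Gene CS is the plain mean over guides within
  replicate, then over replicates — not a rank-based collapse. Guide
  filtering runs before normalization.

## Significance: α-RRA with a permutation null

Guide statistics (guide-level CS averaged over an arm's replicates) are
converted to percentiles rank/(N + 1) with average-rank ties — ascending
for depletion, descending for enrichment. For a gene with sorted
percentiles p(1) ≤ … ≤ p(m),
ρ = min over i ≤ k of BetaCDF(p(i); i, m − i + 1) with
k = #{i : p(i) ≤ α}, and ρ = 1 when k = 0. α defaults to 0.25 (only the
top quarter of the ranking can drive a call) and is configurable.

The null reassigns percentiles to pseudo-genes matched on guide count:
for each observed guide count m, N permutations of m draws from the pooled
percentile distribution. This preserves the marginal rank distribution and
is adequate at desk scale; it does not reproduce any particular published
tool's internal variance modeling, and numeric agreement with published
per-gene p-values is not expected. p uses the add-one estimator with floor
1/(N + 1); no mid-p correction. Benjamini–Hochberg FDR is reported
alongside but calls use raw p, matching the |CS| > 0.5 & p < 0.05
convention.

A consequence worth knowing: when a sizeable block of genes is strongly
depleted (e.g. the essential reference block), the pooled null contains
their extreme percentiles and the depletion test becomes conservative for
ordinary genes. Calibration is therefore assessed on screens with no
planted effects, where the empirical fraction of p < 0.05 sits in
[0.03, 0.07] at 2,000 genes × 4 guides × 1,000 permutations.

## Dependency classes

Essential: CS < −0.5 and depletion p < 0.05 (strict inequalities);
positively selected: CS > 0.5 and enrichment p < 0.05. The "< 0.5" form
seen in some figure legends is read as CS < −0.5, consistent with the
|CS| > 0.5 wording. Classes:

- pan_essential — essential in all oncogene lines' drug arms;
- oncogene_dependency(line) — essential in that line's drug arm and not in
  the control line's vehicle arm (the control cannot grow under drug, so
  its vehicle arm is the reference);
- baseline_synthetic_lethal(line) — essential in that line's vehicle arm
  and not in the control's;
- cooperating_knockout(line) — positively selected in that line's drug arm.

Labels are line-scoped and non-exclusive: a gene planted lethal in a line's
vehicle and drug arms is correctly both a baseline synthetic lethal and an
oncogene dependency, and pan-essential genes also appear as per-line
dependencies when absent from the control. The Venn partition of
drug-arm-essential genes is computed on the genes present in all three
lines after filtering; genes filtered from some arms are classified on the
arms they retain.

## Drug screens

Viability is test luminescence over the mean reference signal. The
inhibitor-response logistic is fit by bounded least squares (top ∈ [0,1.5],
bottom = top·f with f ∈ [0,1] so bottom ≤ top is structural, log10 EC50
within two decades of the tested range); three-parameter mode fixes
hill = 1, a four-parameter mode frees it. AUC is the closed-form mean of
the fitted curve over the log10-dose range (trapezoid fallback on
non-convergence), normalized by range width so constant viability v gives
AUC = v; this makes AUCs comparable across compounds but is not guaranteed
to match any specific plotting software's unnormalized convention. ΔAUC
between lines is median-centered across compounds before ranking.

## Cohort co-occurrence

Altered = mutated OR amplified for the index gene. Low expression is
strict: x < mean − 1·sd, with the sample (n−1) standard deviation, on the
log2 expression scale. The pathway indicator is an OR over the listed
genes' low flags. The Fisher test is one-sided in the fixed direction
"altered tumors have the greater low proportion". The default Hippo panel
has 7 genes (AMOTL1, NF2, STK4, STK38L, MAP4K5, TAOK3, SAV1); a 6-gene
variant without NF2 is provided (`HIPPO_GENES_6`) because published
figure and methods listings differ on its inclusion. The H-score is
Σ_i percent_i · i over intensity bins 1–3, range 0–300.

## Synthetic data: what it emulates and what it does not

**Screens.** Plasmid guide representation is log-normal(0, σ = 0.5);
counts are negative binomial (size 10) around expected proportions that
are renormalized per sample — sequencing measures relative abundance, so a
large planted block shifts everyone else slightly, exactly as in real
screens. Effects are per-doubling so the 12-doubling design maps linearly
to expected LFC. Defaults: 4 guides/gene, mean depth 500 reads/guide
(500-fold-coverage-style), 10% essential reference genes at −0.25/doubling
and 10% neutral nonessential reference genes, non-targeting controls
neutral. Not modelled: infection MOI, selection kinetics, guide-efficiency
heterogeneity, copy-number artifacts, off-target cutting. Passing tests
therefore show the analysis recovers planted truth under idealized
sequencing noise, not that it corrects real-screen artifacts.

**Plates.** Logistic curves plus Gaussian noise on the viability scale,
truncated at 0 (truncation, not resampling — simpler and the bias is
negligible at the default noise sd 0.02).

**Cohorts.** Alteration is Bernoulli; the any-pathway-low indicator is
Bernoulli with class-conditional rates; expression is then constructed so
the empirical mean − 1 sd rule reproduces the planted indicator exactly:
non-low values are drawn from a normal folded at mean − 1 sd, planted lows
sit near mean − 5 sd, and each low tumor lowers one pathway gene chosen
uniformly. Because the threshold is estimated from the column itself, this
construction is valid only when each pathway gene carries planted lows in
roughly 3–45% of tumors; the generator verifies self-consistency after
drawing and refuses scenarios outside that region. This is a deliberate
trade: real cohorts have correlated expression and chance lows (~16% per
gene for Gaussian columns), which the generator sacrifices to make the
planted contingency exact. The default scenario mirrors the published
cohort shape: 230 tumors, 37 altered (5 mutated, 32 amplified), any-low
rates 0.757 / 0.456.

## Problem sizes and numerics

The test suite and acceptance script run the calibration screen at 2,000
genes × 4 guides × 1,000 permutations, the full pipeline at 800 genes with
2 replicates per arm, the drug screen at 40 compounds × 8 doses × 2
replicates, and cohorts at 230 tumors — sizes chosen so every check runs in
seconds while keeping ≥ 200 events per estimated rate. Dose-response fits
use tight optimizer tolerances (1e-14) so noiseless recovery holds to
1e-6. Permutation seeds are derived deterministically per arm and
direction; all generators are reproducible from a single integer seed.

## Known limitations

- Permutation p-values are floored at 1/(N + 1); ranking among the
  strongest hits needs larger N.
- The depletion test is conservative in screens dominated by a large
  essential block (see above).
- No copy-number or guide-efficacy correction; CS values for amplified
  regions in real data would be biased.
- The cohort generator's validity region excludes very rare or very
  common planted-low scenarios.
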