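"""Per-guide log2 fold-changes and anchored, normalized CRISPR scores.

The chain is: reads-per-million -> LFC against the plasmid library (with a
pseudocount) -> per-replicate robust normalization (subtract the median,
divide by the scaled median absolute deviation) -> affine anchoring so that
per-replicate per-gene medians of the reference nonessential genes sit at 0
and of the reference essential genes at -1.  Gene-level CRISPR scores (CS)
are the mean over a gene's guides within each replicate, then the mean over
replicates.  The whole chain is invariant to rescaling any sample's raw
counts by a positive constant.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .counts_qc import mads, to_rpm
from .screen_io import CountMatrix, GeneSetRegistry, GuideLibrary

log = logging.getLogger(__name__)

MIN_ANCHOR_GUIDES = 10


def compute_lfc(
    rpm: pd.DataFrame,
    plasmid_sample: str,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """log2((rpm + pseudocount) / (rpm_plasmid + pseudocount)) per sample."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    base = rpm[plasmid_sample] + pseudocount
    return np.log2(rpm.add(pseudocount).div(base, axis=0))


def normalize_replicate(lfc_column: pd.Series) -> pd.Series:
    """Center at the median and scale by the 1.4826-scaled MAD."""
    x = lfc_column.astype(float)
    if x.notna().sum() < 3:
        raise ValueError("need >= 3 finite values to normalize")
    scale = mads(x.to_numpy())
    if scale == 0:
        raise ValueError("degenerate replicate: MAD is zero")
    return (x - x.median()) / scale


def gene_medians(
    values: pd.Series,
    guide_to_gene: pd.Series,
    genes: Sequence[str],
) -> tuple[float, int]:
    """Median over per-gene means of guide-level values for the given gene
    set; returns (median, number of contributing guides)."""
    members = guide_to_gene[guide_to_gene.isin(set(genes))]
    vals = values.loc[values.index.intersection(members.index)]
    per_gene = vals.groupby(members.loc[vals.index]).mean()
    return float(per_gene.median()), int(len(vals))


def scale_to_anchors(
    norm_lfc: pd.Series,
    guide_to_gene: pd.Series,
    essential_ref: Sequence[str],
    nonessential_ref: Sequence[str],
) -> pd.Series:
    """Affine map sending the nonessential anchor median to 0 and the
    essential anchor median to -1:  cs = (x - m_non) / (m_non - m_ess)."""
    m_non, n_non = gene_medians(norm_lfc, guide_to_gene, nonessential_ref)
    m_ess, n_ess = gene_medians(norm_lfc, guide_to_gene, essential_ref)
    if min(n_non, n_ess) < MIN_ANCHOR_GUIDES:
        raise ValueError(
            f"anchor sets need >= {MIN_ANCHOR_GUIDES} guides "
            f"(got nonessential {n_non}, essential {n_ess})")
    if m_non == m_ess:
        raise ValueError("anchor medians coincide: no dynamic range")
    return (norm_lfc - m_non) / (m_non - m_ess)


def collapse_to_genes(
    cs: pd.DataFrame,
    library: GuideLibrary,
) -> pd.Series:
    """Gene CS: mean over a gene's guides within each replicate column, then
    mean across replicate columns.  Non-targeting guides are excluded; genes
    with no surviving guides are absent (logged)."""
    g2g = library.guide_to_gene()
    targeting = g2g[g2g != "NON_TARGETING"]
    present = cs.index.intersection(targeting.index)
    per_gene = cs.loc[present].groupby(targeting.loc[present]).mean()
    missing = set(library.genes) - set(per_gene.index)
    if missing:
        log.info("%d gene(s) had no surviving guides", len(missing))
    return per_gene.mean(axis=1)


def score_screen(
    counts: CountMatrix,
    library: GuideLibrary,
    registry: GeneSetRegistry,
    pseudocount: float = 1.0,
    baseline: str = "plasmid",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full scoring chain for one screen.

    Returns (guide_table, gene_table).  ``guide_table`` is long-format with
    columns (guide_id, gene, sample_id, cell_line, condition, replicate,
    rpm, lfc, norm_lfc, cs) over endpoint samples; ``gene_table`` has one
    row per (gene, cell_line, condition) with the replicate-averaged CS and
    per-replicate values retained as cs_rep<k> columns.

    ``baseline`` selects the comparison sample: the plasmid library
    (default) or the early time point ("ETP").
    """
    if baseline == "plasmid":
        base_sample = counts.plasmid_sample
    elif baseline == "ETP":
        etp = [s.sample_id for s in counts.samples if s.condition == "ETP"]
        if not etp:
            raise ValueError("no ETP sample to use as baseline")
        base_sample = etp[0]
    else:
        raise ValueError(f"unknown baseline {baseline!r}")

    rpm = to_rpm(counts)
    lfc = compute_lfc(rpm, base_sample, pseudocount)
    g2g = library.guide_to_gene()
    endpoints = counts.endpoint_samples()

    guide_rows = []
    cs_cols: dict[str, pd.Series] = {}
    for s in endpoints:
        norm = normalize_replicate(lfc[s.sample_id])
        cs = scale_to_anchors(norm, g2g, registry["essential_ref"],
                              registry["nonessential_ref"])
        cs_cols[s.sample_id] = cs
        guide_rows.append(pd.DataFrame({
            "guide_id": cs.index, "gene": g2g.loc[cs.index].to_numpy(),
            "sample_id": s.sample_id, "cell_line": s.cell_line,
            "condition": s.condition, "replicate": s.replicate,
            "rpm": rpm.loc[cs.index, s.sample_id].to_numpy(),
            "lfc": lfc.loc[cs.index, s.sample_id].to_numpy(),
            "norm_lfc": norm.loc[cs.index].to_numpy(),
            "cs": cs.to_numpy(),
        }))
    guide_table = pd.concat(guide_rows, ignore_index=True)

    gene_rows = []
    arms = sorted({s.arm for s in endpoints})
    for line, cond in arms:
        reps = [s for s in endpoints if s.arm == (line, cond)]
        cs_mat = pd.DataFrame({s.sample_id: cs_cols[s.sample_id] for s in reps})
        gene_cs = collapse_to_genes(cs_mat, library)
        row = pd.DataFrame({"gene": gene_cs.index, "cell_line": line,
                            "condition": cond, "cs": gene_cs.to_numpy()})
        targeting = g2g[g2g != "NON_TARGETING"]
        n_guides = targeting.groupby(targeting).size()
        row["n_guides"] = n_guides.reindex(row["gene"]).to_numpy()
        for k, s in enumerate(reps, start=1):
            rep_gene = collapse_to_genes(cs_mat[[s.sample_id]], library)
            row[f"cs_rep{k}"] = rep_gene.reindex(row["gene"]).to_numpy()
        gene_rows.append(row)
    gene_table = pd.concat(gene_rows, ignore_index=True)
    return guide_table, gene_table
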