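"""Count normalization, guide exclusion rules and replicate-level quality
statistics for pooled screens.

Guides under-represented in the plasmid library (< 1 read-per-million by
default) are removed before scoring; guides that cannot target the
introduced oncogene cDNA are removed from that oncogene line's screens.
Replicate quality is summarized by the robust strictly standardized mean
difference (SSMD) between the log2 fold-changes of guides targeting a
constitutively essential panel and of non-targeting controls; a replicate
passes at SSMD < -0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .screen_io import CountMatrix, GuideLibrary

SSMD_PASS_THRESHOLD = -0.5
MAD_CONSISTENCY = 1.4826  # scales the MAD to the sd of a normal

#: Guides that do not target the introduced cDNA of the named oncogene and
#: are therefore removed from that line's screens.
CROSS_TARGETING_EXCLUSIONS: dict[str, tuple[str, ...]] = {
    "KRAS": ("AGATATTCACCATTATAGGT",),
    "RIT1": ("CATGCGGGACCAGTATATGA", "GTGATGATCTGGCTTACCAA"),
    "EGFR": ("TGTCACCACATAATTACCTG",),
}


@dataclass
class QCReport:
    """Replicate-level quality summary for one screen."""

    ssmd: dict[str, float] = field(default_factory=dict)  # sample_id -> SSMD
    ssmd_pass: dict[str, bool] = field(default_factory=dict)
    replicate_correlation: pd.DataFrame | None = None
    n_low_abundance_removed: int = 0
    cross_targeting_removed: list[str] = field(default_factory=list)

    def record_ssmd(self, sample_id: str, value: float) -> None:
        self.ssmd[sample_id] = value
        self.ssmd_pass[sample_id] = bool(value < SSMD_PASS_THRESHOLD)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": list(self.ssmd),
            "ssmd": list(self.ssmd.values()),
            "pass": [self.ssmd_pass[s] for s in self.ssmd],
        })


def mads(x: np.ndarray) -> float:
    """Median absolute deviation scaled by 1.4826."""
    x = np.asarray(x, dtype=float)
    return MAD_CONSISTENCY * float(np.median(np.abs(x - np.median(x))))


def to_rpm(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Scale every sample column to sum to one million reads."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    sums = df.sum(axis=0)
    zero = sums.index[sums == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero)}")
    return df.astype(float) * (1e6 / sums)


def filter_low_abundance(
    counts: CountMatrix,
    threshold: float = 1.0,
    report: QCReport | None = None,
) -> CountMatrix:
    """Drop guides whose plasmid-sample abundance is below ``threshold`` RPM."""
    rpm = to_rpm(counts)[counts.plasmid_sample]
    keep = rpm >= threshold
    if report is not None:
        report.n_low_abundance_removed = int((~keep).sum())
    if keep.all():
        return counts
    return counts.subset_guides(counts.guide_ids[keep])


def exclude_cross_targeting(
    library: GuideLibrary,
    expressed_oncogene: str,
    exclusion_table: Mapping[str, Sequence[str]] = CROSS_TARGETING_EXCLUSIONS,
    report: QCReport | None = None,
) -> GuideLibrary:
    """For a screen of the named oncogene line, drop guides whose sequence is
    in that oncogene's exclusion list.  Other lines pass through unchanged."""
    seqs = set(exclusion_table.get(expressed_oncogene, ()))
    if not seqs:
        return library
    drop = library.table["sequence"].isin(seqs)
    if report is not None:
        report.cross_targeting_removed = library.table.loc[drop, "guide_id"].tolist()
    if not drop.any():
        return library
    return GuideLibrary(library.table.loc[~drop].reset_index(drop=True))


def replicate_correlation(lfc_by_replicate: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r (and r^2) between replicate columns of per-guide
    LFC; empty with a warning when fewer than two replicates exist."""
    cols = list(lfc_by_replicate.columns)
    if len(cols) < 2:
        warnings.warn("fewer than 2 replicates: no correlations computed")
        return pd.DataFrame(columns=["sample_a", "sample_b", "r", "r2"])
    rows = []
    for a, b in combinations(cols, 2):
        r = float(np.corrcoef(lfc_by_replicate[a], lfc_by_replicate[b])[0, 1])
        rows.append({"sample_a": a, "sample_b": b, "r": r, "r2": r * r})
    return pd.DataFrame(rows)


def ssmd(
    lfc: pd.Series,
    qc_essential_guides: Sequence[str],
    control_guides: Sequence[str],
) -> float:
    """Robust SSMD between essential-targeting and control guide LFCs.

    SSMD = (median(ess) - median(ctrl)) / sqrt(MADs(ess)^2 + MADs(ctrl)^2),
    negative when essential guides drop out.  Degenerate inputs (both MADs
    zero) give 0 for equal medians and a signed infinity with a warning
    otherwise.
    """
    ess = lfc.loc[lfc.index.intersection(qc_essential_guides)].to_numpy(float)
    ctrl = lfc.loc[lfc.index.intersection(control_guides)].to_numpy(float)
    ess, ctrl = ess[np.isfinite(ess)], ctrl[np.isfinite(ctrl)]
    if len(ess) < 2 or len(ctrl) < 2:
        raise ValueError("both guide sets need >= 2 finite LFC values")
    num = float(np.median(ess) - np.median(ctrl))
    denom = float(np.hypot(mads(ess), mads(ctrl)))
    if denom == 0.0:
        if num == 0.0:
            return 0.0
        warnings.warn("zero MADs with unequal medians: SSMD is infinite")
        return float(np.sign(num) * np.inf)
    return num / denom


def qc_screen(
    counts: CountMatrix,
    library: GuideLibrary,
    qc_essential_genes: Sequence[str],
    rpm_threshold: float = 1.0,
    expressed_oncogene: str | None = None,
) -> tuple[CountMatrix, GuideLibrary, QCReport]:
    """Full guide-level QC: cross-targeting exclusion, low-abundance filter,
    and per-endpoint-replicate SSMD on LFC vs plasmid."""
    from .crispr_score import compute_lfc  # deferred: scoring imports qc

    report = QCReport()
    if expressed_oncogene is not None:
        library = exclude_cross_targeting(library, expressed_oncogene,
                                          report=report)
        counts = counts.subset_guides(library.guide_ids)
    counts = filter_low_abundance(counts, rpm_threshold, report=report)
    library = library.subset(counts.guide_ids)

    rpm = to_rpm(counts)
    lfc = compute_lfc(rpm, counts.plasmid_sample)
    g2g = library.guide_to_gene()
    ess_guides = g2g.index[g2g.isin(set(qc_essential_genes))]
    ctrl_guides = library.table.loc[library.table["is_control"], "guide_id"]
    endpoints = [s.sample_id for s in counts.endpoint_samples()]
    for sid in endpoints:
        report.record_ssmd(sid, ssmd(lfc[sid], ess_guides, ctrl_guides))
    report.replicate_correlation = replicate_correlation(lfc[endpoints])
    return counts, library, report
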