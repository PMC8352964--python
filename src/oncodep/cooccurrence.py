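"""Tumor-cohort co-occurrence analysis between alteration of an index gene
and low expression of a pathway gene set, plus the IHC H-score formula.

A tumor is "altered" when the index gene is mutated or amplified.  A gene is
"low" in a tumor when its log2 expression is more than one sample standard
deviation below the cohort mean (strict inequality at the boundary).  The
association between alteration and having at least one low pathway gene is
tested with a one-sided Fisher exact test, directed at the altered group
having the greater low proportion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

#: Hippo-pathway gene panel used for the low-expression indicator (7 genes).
HIPPO_GENES = ("AMOTL1", "NF2", "STK4", "STK38L", "MAP4K5", "TAOK3", "SAV1")
#: 6-gene alternative panel (drops NF2).
HIPPO_GENES_6 = tuple(g for g in HIPPO_GENES if g != "NF2")


@dataclass
class CohortTable:
    """Per-tumor alteration flags and per-gene log2 expression.

    ``data`` columns: tumor_id, mutation, amplification, diploid (booleans
    for the index gene) and one ``expr_<GENE>`` column per gene.  The
    "altered" flag is always derived (mutation OR amplification), never
    stored.
    """

    data: pd.DataFrame
    index_gene: str = "RIT1"

    def __post_init__(self) -> None:
        required = ["tumor_id", "mutation", "amplification", "diploid"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        if "altered" in self.data.columns:
            raise ValueError("'altered' must be derived, not stored")
        expr = self.data[self.expression_columns()].to_numpy(dtype=float)
        if not np.isfinite(expr).all():
            raise ValueError("non-finite expression values")

    def expression_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("expr_")]

    @property
    def genes(self) -> list[str]:
        return [c[len("expr_"):] for c in self.expression_columns()]

    def expression(self, gene: str) -> pd.Series:
        col = f"expr_{gene}"
        if col not in self.data.columns:
            raise KeyError(f"gene {gene!r} absent from expression table")
        return self.data[col].astype(float)

    @property
    def altered(self) -> pd.Series:
        return self.data["mutation"].astype(bool) | self.data["amplification"].astype(bool)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for (rows: altered / non-altered) x (columns: low / not low)."""

    a: int  # altered, low
    b: int  # altered, not low
    c: int  # non-altered, low
    d: int  # non-altered, not low

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative count in contingency table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def call_altered(mutation, amplification) -> pd.Series:
    """Altered = mutated OR amplified, elementwise."""
    return pd.Series(np.asarray(mutation, bool) | np.asarray(amplification, bool))


def alteration_summary(mutation, amplification) -> dict:
    """Cohort summary: altered count, total, exact and rounded percentage."""
    altered = call_altered(mutation, amplification)
    n_total = int(altered.size)
    n_altered = int(altered.sum())
    pct = 100.0 * n_altered / n_total
    return {
        "n_altered": n_altered, "n_total": n_total,
        "percent": pct, "percent_rounded": int(round(pct)),
    }


def zscore_vs_reference(expression, diploid) -> np.ndarray:
    """z-score of each tumor's expression against the diploid-sample
    distribution (mean and sample sd of the diploid subset)."""
    x = np.asarray(expression, dtype=float)
    dip = np.asarray(diploid, dtype=bool)
    ref = x[dip]
    if ref.size < 2:
        raise ValueError("need >=2 diploid reference samples")
    sd = ref.std(ddof=1)
    if sd == 0:
        raise ValueError("zero spread in diploid reference")
    return (x - ref.mean()) / sd


def call_low_expression(expression) -> np.ndarray:
    """Low expression: strictly more than 1 sample sd below the cohort mean."""
    x = np.asarray(expression, dtype=float)
    if x.size < 2:
        raise ValueError("need >=2 tumors")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("zero spread: no tumor called low")
        return np.zeros(x.size, dtype=bool)
    return x < x.mean() - sd


def any_low(cohort: CohortTable, genes) -> pd.Series:
    """Per-tumor indicator: at least one listed gene is low in that tumor."""
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene list")
    flags = np.zeros(len(cohort.data), dtype=bool)
    for g in genes:
        flags |= call_low_expression(cohort.expression(g))
    return pd.Series(flags, name="any_low")


def build_contingency(cohort: CohortTable, genes=HIPPO_GENES) -> ContingencyTable2x2:
    """Cross-tabulate alteration of the index gene against the any-low flag."""
    low = any_low(cohort, genes).to_numpy()
    alt = cohort.altered.to_numpy()
    return ContingencyTable2x2(
        a=int((alt & low).sum()), b=int((alt & ~low).sum()),
        c=int((~alt & low).sum()), d=int((~alt & ~low).sum()),
    )


def fisher_one_sided(table: ContingencyTable2x2) -> float:
    """One-sided Fisher exact p: probability, under fixed margins, of a low
    proportion in the altered row at least as large as observed."""
    arr = table.as_array()
    if arr.sum(axis=1).min() == 0 or arr.sum(axis=0).min() == 0:
        warnings.warn("degenerate margin: p = 1")
        return 1.0
    _, p = stats.fisher_exact(arr, alternative="greater")
    return float(p)


def cooccurrence_report(cohort: CohortTable, genes=HIPPO_GENES) -> dict:
    """Full co-occurrence analysis: contingency counts, proportions, p."""
    t = build_contingency(cohort, genes)
    return {
        "table": t,
        "prop_low_altered": t.a / (t.a + t.b) if t.a + t.b else np.nan,
        "prop_low_nonaltered": t.c / (t.c + t.d) if t.c + t.d else np.nan,
        "p_one_sided": fisher_one_sided(t),
        "genes": list(genes),
    }


def h_score(percent_by_intensity: dict[int, float]) -> float:
    """IHC H-score: sum over intensity bins {1,2,3} of percent positive x
    intensity, range 0-300."""
    pct = {i: float(percent_by_intensity.get(i, 0.0)) for i in (1, 2, 3)}
    if any(v < 0 for v in pct.values()):
        raise ValueError("negative percentage")
    if sum(pct.values()) > 100.0 + 1e-9:
        raise ValueError("bin percentages sum to more than 100")
    return float(sum(pct[i] * i for i in (1, 2, 3)))


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.data.to_csv(path, index=False, float_format="%.6g")


def read_cohort(path: str | Path, index_gene: str = "RIT1") -> CohortTable:
    df = pd.read_csv(path)
    for c in ("mutation", "amplification", "diploid"):
        df[c] = df[c].astype(bool)
    return CohortTable(df, index_gene=index_gene)
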