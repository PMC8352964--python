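"""Readers, writers and validated containers for every tabular screen artifact.

Formats are deliberately plain: wide tab-separated count matrices with guide
ids in the first column (PoolQ-style output), a separate design TSV mapping
sample id to (cell_line, condition, replicate), a "chip" CSV annotating each
guide with its 20-nt sequence and target gene, one-symbol-per-line gene
lists, and tab-separated score/call tables.  Gene symbols are opaque
case-sensitive strings; no alias resolution is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import NON_TARGETING

CELL_LINES = ("control", "EGFR", "KRAS", "RIT1", "other")
CONDITIONS = ("plasmid", "ETP", "DMSO", "erlotinib", "other")

_DNA = set("ACGT")


class ScreenIOError(ValueError):
    """Raised on any malformed or inconsistent screen artifact."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GuideLibrary:
    """Guide-to-gene annotation, including non-targeting controls.

    ``table`` has columns (guide_id, sequence, gene, is_control) with one row
    per guide.  ``is_control`` is true exactly when ``gene`` is the
    ``NON_TARGETING`` sentinel.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = ["guide_id", "sequence", "gene", "is_control"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ScreenIOError(f"guide library missing columns: {missing}")
        if t["guide_id"].duplicated().any():
            dups = t.loc[t["guide_id"].duplicated(), "guide_id"].tolist()
            raise ScreenIOError(f"duplicate guide ids: {dups[:5]}")
        bad = [s for s in t["sequence"] if len(s) != 20 or not set(s) <= _DNA]
        if bad:
            raise ScreenIOError(
                f"{len(bad)} sequences are not 20-nt ACGT strings, e.g. {bad[0]!r}"
            )
        mism = t["is_control"] != (t["gene"] == NON_TARGETING)
        if mism.any():
            raise ScreenIOError(
                "is_control flag inconsistent with NON_TARGETING gene for "
                f"guides {t.loc[mism, 'guide_id'].tolist()[:5]}"
            )

    @property
    def guide_ids(self) -> pd.Index:
        return pd.Index(self.table["guide_id"])

    @property
    def genes(self) -> pd.Index:
        """Targeted genes (controls excluded), in order of first appearance."""
        return pd.Index(self.table.loc[~self.table["is_control"], "gene"].unique())

    @property
    def n_controls(self) -> int:
        return int(self.table["is_control"].sum())

    def guide_to_gene(self) -> pd.Series:
        return self.table.set_index("guide_id")["gene"]

    def subset(self, guide_ids: Iterable[str]) -> "GuideLibrary":
        keep = self.table["guide_id"].isin(set(guide_ids))
        return GuideLibrary(self.table.loc[keep].reset_index(drop=True))


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample screen design: which arm of which line, which replicate."""

    sample_id: str
    cell_line: str
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        if self.cell_line not in CELL_LINES:
            raise ScreenIOError(
                f"sample {self.sample_id}: cell_line {self.cell_line!r} "
                f"not one of {CELL_LINES}"
            )
        if self.condition not in CONDITIONS:
            raise ScreenIOError(
                f"sample {self.sample_id}: condition {self.condition!r} "
                f"not one of {CONDITIONS}"
            )
        if self.replicate < 1:
            raise ScreenIOError(f"sample {self.sample_id}: replicate must be >= 1")

    @property
    def arm(self) -> tuple[str, str]:
        return (self.cell_line, self.condition)


@dataclass
class CountMatrix:
    """Guide x sample read counts plus per-sample design metadata."""

    counts: pd.DataFrame  # index: guide_id, columns: sample_id
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if list(self.counts.columns) != ids:
            raise ScreenIOError("count columns do not match sample metadata order")
        keys = [(s.cell_line, s.condition, s.replicate) for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ScreenIOError("(cell_line, condition, replicate) not unique")
        n_plasmid = sum(s.condition == "plasmid" for s in self.samples)
        if n_plasmid != 1:
            raise ScreenIOError(
                f"expected exactly one plasmid sample, found {n_plasmid}"
            )
        if (self.counts.to_numpy() < 0).any():
            raise ScreenIOError("negative counts")
        zero = self.counts.columns[(self.counts.sum(axis=0) == 0)]
        if len(zero):
            raise ScreenIOError(f"all-zero count column(s): {list(zero)}")

    @property
    def plasmid_sample(self) -> str:
        return next(s.sample_id for s in self.samples if s.condition == "plasmid")

    @property
    def guide_ids(self) -> pd.Index:
        return self.counts.index

    def meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def endpoint_samples(self) -> list[SampleMeta]:
        return [s for s in self.samples if s.condition not in ("plasmid", "ETP")]

    def subset_guides(self, guide_ids: Iterable[str]) -> "CountMatrix":
        keep = self.counts.index.isin(set(guide_ids))
        return CountMatrix(self.counts.loc[keep], list(self.samples))


@dataclass
class GeneSetRegistry:
    """Named, non-empty sets of gene symbols used throughout the pipeline."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def add(self, name: str, genes: Iterable[str]) -> None:
        genes = frozenset(genes)
        if name in self.sets:
            raise ScreenIOError(f"gene set {name!r} already registered")
        if not genes:
            raise ScreenIOError(f"gene set {name!r} is empty")
        self.sets[name] = genes
        ess, non = self.sets.get("essential_ref"), self.sets.get("nonessential_ref")
        if ess and non and ess & non:
            raise ScreenIOError(
                f"essential_ref and nonessential_ref overlap: {sorted(ess & non)[:5]}"
            )

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_design(path: str | Path) -> dict[str, SampleMeta]:
    """Read a design TSV (sample_id, cell_line, condition, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "cell_line", "condition", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ScreenIOError(f"design file missing columns: {missing}")
    out: dict[str, SampleMeta] = {}
    for _, row in df.iterrows():
        sid = row["sample_id"].strip()
        if sid in out:
            raise ScreenIOError(f"duplicate sample id in design: {sid}")
        out[sid] = SampleMeta(
            sid, row["cell_line"].strip(), row["condition"].strip(),
            int(row["replicate"]),
        )
    return out


def read_count_matrix(
    path: str | Path,
    library: GuideLibrary,
    design: Mapping[str, SampleMeta],
) -> CountMatrix:
    """Read a wide PoolQ-style counts TSV and validate it against library/design.

    First column holds guide ids; the header row holds sample ids, each of
    which must appear in ``design``.  Counts are coerced to non-negative
    integers; any non-numeric cell is a hard error naming its coordinates.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    unknown_cols = [c for c in df.columns if c not in design]
    if unknown_cols:
        raise ScreenIOError(
            f"count columns missing from design: {unknown_cols}"
        )
    unknown_guides = df.index.difference(library.guide_ids)
    if len(unknown_guides):
        raise ScreenIOError(
            f"{len(unknown_guides)} guide id(s) absent from library, "
            f"e.g. {list(unknown_guides[:5])}"
        )
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ScreenIOError(
                f"non-numeric count at guide {row!r}, sample {col!r}: "
                f"{df.loc[row, col]!r}"
            )
        df[col] = numeric.fillna(0).round().astype(np.int64)
    samples = [design[c] for c in df.columns]
    return CountMatrix(df, samples)


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    df = cm.counts.copy()
    df.index.name = "guide_id"
    df.to_csv(path, sep="\t")


def write_design(samples: Iterable[SampleMeta], path: str | Path) -> None:
    rows = [
        {"sample_id": s.sample_id, "cell_line": s.cell_line,
         "condition": s.condition, "replicate": s.replicate}
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line; whitespace-trimmed, duplicates dropped."""
    text = Path(path).read_text().splitlines()
    symbols = [line.strip() for line in text if line.strip()]
    if not symbols:
        raise ScreenIOError(f"empty gene list: {path}")
    n_dup = len(symbols) - len(set(symbols))
    if n_dup:
        warnings.warn(f"{path}: dropped {n_dup} duplicate symbol(s)")
    return set(symbols)


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def read_chip(path: str | Path) -> GuideLibrary:
    """Read a chip CSV with fixed leading columns (guide_id, sequence, gene)."""
    df = pd.read_csv(path, dtype=str)
    required = ["guide_id", "sequence", "gene"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ScreenIOError(f"chip file missing columns: {missing}")
    if df.empty:
        raise ScreenIOError(f"empty chip file: {path}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"chip file: ignoring extra column(s) {extra}")
    out = df[required].copy()
    for c in required:
        out[c] = out[c].str.strip()
    out["is_control"] = out["gene"] == NON_TARGETING
    return GuideLibrary(out.reset_index(drop=True))


def write_chip(library: GuideLibrary, path: str | Path) -> None:
    library.table[["guide_id", "sequence", "gene"]].to_csv(path, index=False)


def write_scores(table: pd.DataFrame, path: str | Path) -> None:
    """Write any score/call table as TSV with floats at 6 significant digits."""
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
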