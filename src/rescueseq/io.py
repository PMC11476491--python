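"""Tab-separated and GMT readers/writers for the pipeline's on-disk formats.

All tables are TSV with a header row; gene and sample identifiers are opaque
strings.  Floats are written with a fixed format so that repeated runs with
the same inputs produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

FLOAT_FORMAT = "%.10g"


@dataclass
class CountMatrix:
    """Gene x sample integer count table with arm assignments.

    ``counts`` is indexed by gene_id with one column per sample; ``arms``
    maps sample_id -> arm label.  ``gene_lengths`` (bp) is only required for
    FPKM.  ``depth_factors`` holds the simulator's true per-sample depth
    factors when the matrix is synthetic, so size-factor recovery is testable.
    """

    counts: pd.DataFrame
    arms: pd.Series
    gene_lengths: pd.Series | None = None
    depth_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integral")
            self.counts = counts.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in counts.columns if s not in self.arms.index]
        if missing:
            raise ValueError(f"samples without arm assignment: {missing}")
        self.arms = self.arms.loc[counts.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_of(self, arm: str) -> list[str]:
        sel = self.arms[self.arms == arm]
        return list(sel.index)


@dataclass
class GeneSet:
    term_id: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate members in term {self.term_id}")


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)
    enriched_terms: tuple[str, ...] = ()

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene_id":
        raise ValueError(f"{path}: first column must be 'gene_id', got {df.columns[0]!r}")
    return df.set_index("gene_id")


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "arm"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: sample sheet needs columns {sorted(required)}")
    return df


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def arms_from_sheet(sheet: pd.DataFrame) -> pd.Series:
    return sheet.set_index("sample_id")["arm"]


def read_gene_lengths(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns or "length" not in df.columns:
        raise ValueError(f"{path}: gene metadata needs 'gene_id' and 'length' columns")
    return df.set_index("gene_id")["length"]


def write_gene_lengths(lengths: pd.Series, path: str | Path) -> None:
    lengths.rename("length").to_csv(path, sep="\t", index_label="gene_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: GMT rows need term, description, members")
            sets.append(GeneSet(fields[0], fields[1], tuple(fields[2:])))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.term_id, gs.description, *gs.genes]) + "\n")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "sample_id": str, "arm": str})
    required = {"gene_id", "sample_id", "arm", "ct"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: Ct table needs columns {sorted(required)}")
    return df


def write_ct_table(ct: pd.DataFrame, path: str | Path) -> None:
    ct.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_table(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    """Write any result table deterministically (fixed float format)."""
    df.to_csv(
        path,
        sep="\t",
        index=index_label is not None,
        index_label=index_label,
        float_format=FLOAT_FORMAT,
    )


def load_count_matrix(
    counts_path: str | Path,
    samples_path: str | Path,
    lengths_path: str | Path | None = None,
) -> CountMatrix:
    counts = read_counts_tsv(counts_path)
    sheet = read_sample_sheet(samples_path)
    arms = arms_from_sheet(sheet)
    lengths = read_gene_lengths(lengths_path) if lengths_path else None
    return CountMatrix(counts=counts, arms=arms, gene_lengths=lengths)
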