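"""Aptamer count and frequency matrices.

The central container is :class:`CountMatrix`: integer read counts for
each aptamer variable-region sequence in each sample, together with the
per-sample total of processed reads.  The totals are carried separately
from the retained rows because pool-fraction normalization divides by
*all* dereplicated reads of a sample, including reads belonging to
sequences that were later dropped by the minimum-count filter.

Frequencies ("percent of pool") and relative levels are plain pandas
DataFrames; helper writers keep the on-disk TSV layout uniform.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

_SEQ_RE = re.compile(r"^[ACGT]+$")

TOTALS_MARKER = "#total:"


class CountTableError(ValueError):
    """Invalid count table content."""


@dataclass
class CountMatrix:
    """Integer counts (sequences x samples) plus per-sample totals.

    ``counts``: DataFrame indexed by uppercase A/C/G/T variable-region
    sequence, one integer column per sample.  ``totals``: Series of
    per-sample processed-read totals; always >= the column sums.
    """

    counts: pd.DataFrame
    totals: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise CountTableError(f"duplicate sequence rows: {dupes[:3]}")
        for seq in self.counts.index:
            if not _SEQ_RE.match(str(seq)):
                raise CountTableError(f"invalid sequence: {seq!r}")
        if not np.issubdtype(self.counts.to_numpy().dtype, np.integer):
            raise CountTableError("counts must be integers")
        if (self.counts.to_numpy() < 0).any():
            raise CountTableError("counts must be non-negative")
        self.totals = self.totals.loc[self.counts.columns].astype(np.int64)
        colsums = self.counts.sum(axis=0)
        bad = self.totals[self.totals < colsums]
        if len(bad):
            raise CountTableError(
                f"totals below retained column sums for samples: {bad.index.tolist()}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sequences(self) -> list[str]:
        return list(self.counts.index)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.counts.equals(other.counts) and self.totals.equals(other.totals)

    @classmethod
    def from_dict(
        cls,
        per_sample: dict[str, dict[str, int]],
        totals: dict[str, int] | None = None,
    ) -> "CountMatrix":
        """Build from ``{sample_id: {sequence: count}}`` maps.

        When ``totals`` is omitted each sample's total defaults to the
        sum of its counts.
        """
        df = pd.DataFrame(per_sample).fillna(0).astype(np.int64)
        df = df.sort_index()
        df.index.name = "sequence"
        if totals is None:
            tot = df.sum(axis=0)
        else:
            tot = pd.Series(totals)
        return cls(df, tot.astype(np.int64))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        """Read a sequence-keyed TSV count table.

        Layout: first column ``sequence``, one column per sample.  An
        optional row whose sequence field is ``#total:`` carries the
        per-sample processed-read totals; without it, totals default to
        column sums.
        """
        df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
        if df.columns[0] != "sequence":
            raise CountTableError(
                f"first column must be 'sequence', got {df.columns[0]!r}"
            )
        df = df.set_index("sequence")
        totals = None
        if TOTALS_MARKER in df.index:
            totals_row = df.loc[TOTALS_MARKER]
            df = df.drop(index=TOTALS_MARKER)
            totals = _to_int(totals_row, context="totals row")
        counts = df.apply(lambda col: _to_int(col, context=f"column {col.name!r}"))
        if counts.index.has_duplicates:
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise CountTableError(f"duplicate sequence rows: {dupes[:3]}")
        if totals is None:
            totals = counts.sum(axis=0)
        return cls(counts, totals)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.loc[TOTALS_MARKER] = self.totals
        # totals row first so readers see the denominator before the data
        out = out.loc[[TOTALS_MARKER] + self.sequences]
        out.index.name = "sequence"
        out.to_csv(path, sep="\t")


def _to_int(col: pd.Series, context: str) -> pd.Series:
    try:
        as_float = col.astype(float)
        as_int = col.astype(float).astype(np.int64)
    except (TypeError, ValueError) as exc:
        raise CountTableError(f"non-numeric count in {context}") from exc
    if not np.all(as_float == as_int):
        raise CountTableError(f"non-integer count in {context}")
    return as_int


def write_frequency_tsv(freqs: pd.DataFrame, path: str | Path) -> None:
    out = freqs.copy()
    out.index.name = "sequence"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_frequency_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sequence")


def write_fasta(sequences: list[str], path: str | Path, prefix: str = "apt") -> None:
    """Export aptamer variable regions as FASTA, named by abundance rank."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [
        SeqRecord(Seq(s), id=f"{prefix}{i + 1:05d}", description="")
        for i, s in enumerate(sequences)
    ]
    SeqIO.write(records, str(path), "fasta")
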