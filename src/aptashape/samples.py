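"""Sample metadata: barcodes, group labels and cohort assignment.

Every sample in a branched selection is one patient plasma specimen,
identified during sequencing by the barcode carried on its PCR primers.
Group labels follow the clinical staging used throughout the package:

* ``C``    -- control individuals without bladder cancer,
* ``Ta``   -- non-muscle-invasive (early stage) tumors,
* ``T2T4`` -- muscle-invasive (late stage, T2-T4) cancer.

Samples belong either to the ``training`` cohort (used for model fitting
and aptamer discovery) or the ``validation`` cohort (classified only).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

GROUP_C = "C"
GROUP_TA = "Ta"
GROUP_T2T4 = "T2T4"
GROUPS = (GROUP_C, GROUP_TA, GROUP_T2T4)
CANCER_GROUPS = (GROUP_TA, GROUP_T2T4)

COHORT_TRAINING = "training"
COHORT_VALIDATION = "validation"
COHORTS = (COHORT_TRAINING, COHORT_VALIDATION)

_DNA_RE = re.compile(r"^[ACGT]+$")


class SampleSheetError(ValueError):
    """Invalid sample sheet content."""


def normalize_group(label: str) -> str:
    """Map a free-form group label case-insensitively onto {C, Ta, T2T4}.

    Accepts common spellings such as ``ta``, ``T2-T4`` or ``t2t4``.
    """
    folded = label.strip().lower().replace("-", "").replace("–", "")
    if folded == "c":
        return GROUP_C
    if folded == "ta":
        return GROUP_TA
    if folded == "t2t4":
        return GROUP_T2T4
    raise SampleSheetError(f"unknown group label: {label!r}")


def normalize_cohort(label: str) -> str:
    folded = label.strip().lower()
    if folded in COHORTS:
        return folded
    raise SampleSheetError(f"unknown cohort label: {label!r}")


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    barcode: str
    group: str
    cohort: str


class SampleSheet:
    """Validated collection of :class:`SampleRecord`.

    Invariants enforced at construction: unique sample ids, unique
    equal-length DNA barcodes, and group/cohort labels drawn from the
    controlled vocabularies.
    """

    def __init__(self, records: Iterable[SampleRecord]):
        self.records: tuple[SampleRecord, ...] = tuple(records)
        if not self.records:
            raise SampleSheetError("sample sheet is empty")
        seen_ids: set[str] = set()
        seen_barcodes: set[str] = set()
        lengths = set()
        for rec in self.records:
            if rec.sample_id in seen_ids:
                raise SampleSheetError(f"duplicate sample_id: {rec.sample_id!r}")
            seen_ids.add(rec.sample_id)
            if not _DNA_RE.match(rec.barcode):
                raise SampleSheetError(
                    f"barcode for {rec.sample_id!r} is not a DNA string: {rec.barcode!r}"
                )
            if rec.barcode in seen_barcodes:
                raise SampleSheetError(f"duplicate barcode: {rec.barcode!r}")
            seen_barcodes.add(rec.barcode)
            lengths.add(len(rec.barcode))
            if rec.group not in GROUPS:
                raise SampleSheetError(f"unknown group: {rec.group!r}")
            if rec.cohort not in COHORTS:
                raise SampleSheetError(f"unknown cohort: {rec.cohort!r}")
        if len(lengths) > 1:
            raise SampleSheetError(f"barcodes have unequal lengths: {sorted(lengths)}")
        self.barcode_length: int = lengths.pop()

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    @property
    def barcode_to_sample(self) -> dict[str, str]:
        return {r.barcode: r.sample_id for r in self.records}

    def group_of(self, sample_id: str) -> str:
        return self._by_id()[sample_id].group

    def _by_id(self) -> dict[str, SampleRecord]:
        return {r.sample_id: r for r in self.records}

    def groups(self, sample_ids: Sequence[str] | None = None) -> pd.Series:
        """Group label per sample id, as a pandas Series."""
        by_id = self._by_id()
        ids = list(sample_ids) if sample_ids is not None else self.sample_ids
        return pd.Series({s: by_id[s].group for s in ids}, name="group").loc[ids]

    def subset(self, cohort: str | None = None, groups: Sequence[str] | None = None) -> "SampleSheet":
        recs = [
            r
            for r in self.records
            if (cohort is None or r.cohort == cohort)
            and (groups is None or r.group in groups)
        ]
        if not recs:
            raise SampleSheetError(
                f"no samples match cohort={cohort!r}, groups={groups!r}"
            )
        return SampleSheet(recs)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"sample_id", "barcode", "group", "cohort"}
        missing = required - set(df.columns)
        if missing:
            raise SampleSheetError(f"sample sheet missing columns: {sorted(missing)}")
        records = [
            SampleRecord(
                sample_id=row.sample_id.strip(),
                barcode=row.barcode.strip().upper(),
                group=normalize_group(row.group),
                cohort=normalize_cohort(row.cohort),
            )
            for row in df.itertuples()
        ]
        return cls(records)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.records],
                "barcode": [r.barcode for r in self.records],
                "group": [r.group for r in self.records],
                "cohort": [r.cohort for r in self.records],
            }
        )
        df.to_csv(path, sep="\t", index=False)
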