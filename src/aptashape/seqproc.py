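"""Raw paired reads to a clustered, filtered, normalized frequency matrix.

Processing stages, mirroring a standard amplicon workflow:

1. demultiplex read pairs by the barcode prefix of read 1;
2. join pair mates by overlap alignment of read 1 with the reverse
   complement of read 2;
3. extract the aptamer variable region between the two constant flanks;
4. dereplicate identical regions into (sequence, count) records;
5. drop sequences seen fewer than ``min_count`` times in a sample
   (the per-sample read total is retained as normalization denominator);
6. merge near-identical sequences by greedy centroid clustering under
   the restricted Damerau-Levenshtein distance;
7. convert counts to percent-of-pool frequencies and keep the
   ``top_n`` most abundant aptamers.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .countmatrix import CountMatrix
from .distance import (
    bounded_edit_distance,
    composition_lower_bounds,
    composition_matrix,
)
from .samples import SampleSheet

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SeqProcError(ValueError):
    """Unrecoverable read-processing configuration or input error."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# FASTQ streaming
# ---------------------------------------------------------------------------

def iter_fastq_pairs(
    r1_path: str | Path, r2_path: str | Path
) -> Iterator[tuple[str, str, str, str]]:
    """Yield (read1, read2, qual1, qual2) from a FASTQ file pair.

    Files may be gzip-compressed (detected by ``.gz`` suffix).
    """
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with _open_text(r1_path) as f1, _open_text(r2_path) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        for (t1, s1, q1), (t2, s2, q2) in zip(it1, it2, strict=True):
            yield s1.upper(), s2.upper(), q1, q2


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------

def validate_barcodes(sheet: SampleSheet, max_barcode_mismatch: int) -> None:
    """Reject barcode sets whose pairwise distance makes assignment ambiguous.

    Two barcodes within ``2 * max_barcode_mismatch`` of each other can
    both match a read prefix, so assignment would be ambiguous by
    construction.
    """
    barcodes = list(sheet.barcode_to_sample)
    for i, a in enumerate(barcodes):
        for b in barcodes[i + 1 :]:
            if hamming(a, b) <= 2 * max_barcode_mismatch:
                raise SeqProcError(
                    f"barcodes {a!r} and {b!r} are within "
                    f"{2 * max_barcode_mismatch} mismatches of each other; "
                    "demultiplexing would be ambiguous"
                )


def assign_barcode(
    read1: str, barcode_to_sample: dict[str, str], max_mismatch: int, barcode_length: int
) -> str | None:
    """Sample id for a read, or None if unmatched or ambiguous."""
    prefix = read1[:barcode_length]
    if len(prefix) < barcode_length:
        return None
    if max_mismatch == 0:
        return barcode_to_sample.get(prefix)
    hits = [
        sample
        for barcode, sample in barcode_to_sample.items()
        if hamming(prefix, barcode) <= max_mismatch
    ]
    if len(hits) == 1:
        return hits[0]
    return None


def demultiplex(
    read_pairs: Iterable[tuple[str, str, str, str]],
    sheet: SampleSheet,
    max_barcode_mismatch: int = 0,
) -> tuple[dict[str, list[tuple[str, str, str, str]]], int]:
    """Partition read pairs by barcode; returns (per-sample pairs, n unassigned)."""
    validate_barcodes(sheet, max_barcode_mismatch)
    table = sheet.barcode_to_sample
    out: dict[str, list[tuple[str, str, str, str]]] = {s: [] for s in sheet.sample_ids}
    unassigned = 0
    for pair in read_pairs:
        sample = assign_barcode(pair[0], table, max_barcode_mismatch, sheet.barcode_length)
        if sample is None:
            unassigned += 1
        else:
            out[sample].append(pair)
    return out, unassigned


# ---------------------------------------------------------------------------
# Pair-mate joining
# ---------------------------------------------------------------------------

_SEED_LENGTH = 12


def join_pairs(
    read1: str,
    read2: str,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
    qual1: str | None = None,
    qual2: str | None = None,
) -> str | None:
    """Merge a read pair into the amplicon sequence, or None on rejection.

    Read 2 is reverse-complemented and slid along read 1; the offset with
    at least ``min_overlap`` overlapping bases and the fewest mismatches
    wins (ties go to the longer overlap, i.e. the smaller offset).  The
    merge is accepted when the mismatch fraction in the overlap is at
    most ``max_mismatch_frac``.  Disagreeing bases are resolved toward
    the higher base quality; ties keep the read-1 base.

    Offsets are first proposed by exact seed matches of read-2 12-mers
    in read 1 and fall back to exhaustive scanning when no seeded offset
    is acceptable, so short or error-rich pairs still find the
    minimizing offset.
    """
    if not read1 or not read2:
        raise SeqProcError("cannot join empty reads")
    rc2 = reverse_complement(read2)
    if rc2 == read1 and len(read1) >= min_overlap:
        return read1  # mates span the identical amplicon
    arr1 = np.frombuffer(read1.encode(), dtype=np.uint8)
    arr2 = np.frombuffer(rc2.encode(), dtype=np.uint8)

    def evaluate(offsets) -> tuple[int, int] | None:
        best: tuple[int, int] | None = None
        for offset in offsets:
            overlap = min(len(read1) - offset, len(rc2))
            if overlap < min_overlap:
                continue
            mism = int(
                np.count_nonzero(arr1[offset : offset + overlap] != arr2[:overlap])
            )
            cand = (mism, offset)
            if best is None or cand < best:
                best = cand
        return best

    def acceptable(best: tuple[int, int] | None) -> bool:
        if best is None:
            return False
        mism, offset = best
        overlap = min(len(read1) - offset, len(rc2))
        return mism / overlap <= max_mismatch_frac

    best = evaluate(_seed_offsets(read1, rc2))
    if not acceptable(best):
        best = evaluate(range(0, len(read1) - min_overlap + 1))
    if not acceptable(best):
        return None
    mism, offset = best
    overlap = min(len(read1) - offset, len(rc2))
    if mism == 0:
        return read1[: offset + overlap] + rc2[overlap:]
    rq2 = qual2[::-1] if qual2 is not None else None
    merged = list(read1[: offset + overlap])
    for k in np.flatnonzero(arr1[offset : offset + overlap] != arr2[:overlap]):
        i1 = offset + int(k)
        q1 = ord(qual1[i1]) if qual1 is not None else 0
        q2 = ord(rq2[int(k)]) if rq2 is not None else 0
        if q2 > q1:
            merged[i1] = rc2[int(k)]
    return "".join(merged) + rc2[overlap:]


def _seed_offsets(read1: str, rc2: str) -> list[int]:
    """Candidate alignment offsets from exact 12-mer matches of rc2 in read1."""
    offsets: set[int] = set()
    for seed_start in range(0, len(rc2) - _SEED_LENGTH + 1, _SEED_LENGTH):
        seed = rc2[seed_start : seed_start + _SEED_LENGTH]
        pos = read1.find(seed)
        while pos != -1:
            if pos - seed_start >= 0:
                offsets.add(pos - seed_start)
            pos = read1.find(seed, pos + 1)
    return sorted(offsets)


# ---------------------------------------------------------------------------
# Variable-region extraction
# ---------------------------------------------------------------------------

def _find_approximate(
    haystack: str, needle: str, max_mismatch: int, start: int = 0
) -> int | None:
    """Leftmost occurrence of ``needle`` with the fewest substitutions.

    Returns None when no window matches within ``max_mismatch``.  An
    exact hit short-circuits via ``str.find``; otherwise all windows are
    compared at once.
    """
    ln = len(needle)
    if len(haystack) - start < ln:
        return None
    exact = haystack.find(needle, start)
    if exact != -1:
        return exact
    if max_mismatch == 0:
        return None
    hay = np.frombuffer(haystack.encode(), dtype=np.uint8)[start:]
    ndl = np.frombuffer(needle.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(hay, ln)
    mism = np.count_nonzero(windows != ndl[None, :], axis=1)
    pos = int(np.argmin(mism))
    if mism[pos] > max_mismatch:
        return None
    return start + pos


def extract_variable_region(
    merged: str,
    flank5: str,
    flank3: str,
    max_flank_mismatch: int = 1,
    length_range: tuple[int, int] = (30, 42),
) -> str | None:
    """Variable region between the constant flanks, or None on rejection.

    Both flanks must match with at most ``max_flank_mismatch``
    substitutions each, and the enclosed region length must fall inside
    ``length_range`` (default centered on the designed 36 nt).
    """
    if not flank5 or not flank3:
        raise SeqProcError("flank sequences must be non-empty")
    pos5 = _find_approximate(merged, flank5, max_flank_mismatch)
    if pos5 is None:
        return None
    region_start = pos5 + len(flank5)
    pos3 = _find_approximate(merged, flank3, max_flank_mismatch, start=region_start)
    if pos3 is None:
        return None
    region = merged[region_start:pos3]
    lo, hi = length_range
    if not (lo <= len(region) <= hi):
        return None
    return region


# ---------------------------------------------------------------------------
# Dereplication and filtering
# ---------------------------------------------------------------------------

def dereplicate(regions: Iterable[str]) -> dict[str, int]:
    """Collapse identical sequences into a sequence -> count map."""
    return dict(Counter(regions))


def filter_min_count(counts: CountMatrix, min_count: int) -> CountMatrix:
    """Zero out per-sample counts below ``min_count``; totals unchanged.

    The filter is per sample: a sequence kept in one sample may be
    zeroed in another.  Rows that become all-zero are dropped.  Totals
    keep the dropped reads, preserving the normalization denominator.
    """
    if min_count < 1:
        raise SeqProcError("min_count must be >= 1")
    filtered = counts.counts.where(counts.counts >= min_count, 0)
    filtered = filtered[filtered.sum(axis=1) > 0]
    return CountMatrix(filtered.astype(np.int64), counts.totals.copy())


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterTable:
    """Result of greedy centroid clustering.

    ``members`` maps each centroid sequence to its member sequences
    (centroid first); ``counts`` holds the per-sample counts with
    members merged into their centroid.
    """

    counts: CountMatrix
    members: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.members)


def cluster_by_edit_distance(
    counts: CountMatrix, max_dist: int = 3, variant: str = "osa"
) -> ClusterTable:
    """Greedy abundance-ordered centroid clustering.

    Sequences are visited in descending total count (ties broken
    lexicographically); each joins the first existing centroid within
    ``max_dist`` edits, else founds a new centroid.  Member counts are
    summed into the centroid per sample.  ``max_dist = 3`` encodes the
    "distance < 4" merge rule.
    """
    if max_dist < 0:
        raise SeqProcError("max_dist must be >= 0")
    totals_per_seq = counts.counts.sum(axis=1)
    order = sorted(counts.sequences, key=lambda s: (-totals_per_seq[s], s))
    centroids: list[str] = []
    centroid_comp_rows: list[np.ndarray] = []
    centroid_lens: list[int] = []
    members: dict[str, list[str]] = {}
    assignment: dict[str, str] = {}
    comp_all = composition_matrix(order)
    for idx, seq in enumerate(order):
        assigned = None
        if centroids and max_dist > 0:
            comps = np.vstack(centroid_comp_rows)
            bounds = composition_lower_bounds(comp_all[idx], comps)
            lens = np.asarray(centroid_lens)
            cand = np.flatnonzero(
                (bounds <= max_dist) & (np.abs(lens - len(seq)) <= max_dist)
            )
            for ci in cand:
                if bounded_edit_distance(seq, centroids[ci], max_dist, variant) <= max_dist:
                    assigned = centroids[ci]
                    break
        elif centroids and max_dist == 0:
            assigned = None  # distinct sequences never merge at distance 0
        if assigned is None:
            centroids.append(seq)
            centroid_comp_rows.append(comp_all[idx])
            centroid_lens.append(len(seq))
            members[seq] = [seq]
            assignment[seq] = seq
        else:
            members[assigned].append(seq)
            assignment[seq] = assigned
    merged = counts.counts.groupby(
        counts.counts.index.map(assignment)
    ).sum()
    merged.index.name = "sequence"
    merged = merged.sort_index()
    table = CountMatrix(merged.astype(np.int64), counts.totals.copy())
    return ClusterTable(counts=table, members=members)


# ---------------------------------------------------------------------------
# Normalization and abundance ranking
# ---------------------------------------------------------------------------

def normalize_frequencies(counts: CountMatrix) -> pd.DataFrame:
    """Percent-of-pool frequencies: count / per-sample total * 100."""
    zero = counts.totals[counts.totals == 0]
    if len(zero):
        raise SeqProcError(
            f"zero processed-read total for samples: {zero.index.tolist()}"
        )
    freqs = counts.counts.div(counts.totals, axis=1) * 100.0
    return freqs


def select_top_abundant(freqs: pd.DataFrame, n: int) -> pd.DataFrame:
    """Keep the ``n`` aptamers with the largest mean frequency across samples.

    Ties on the mean are broken lexicographically by sequence so the
    selection is deterministic.
    """
    if n < 1:
        raise SeqProcError("top_n must be >= 1")
    if len(freqs) <= n:
        if len(freqs) < n:
            logger.warning(
                "requested top %d aptamers but only %d available; keeping all",
                n,
                len(freqs),
            )
        return freqs.copy()
    means = freqs.mean(axis=1)
    ranking = sorted(freqs.index, key=lambda s: (-means[s], s))
    keep = ranking[:n]
    return freqs.loc[keep]


# ---------------------------------------------------------------------------
# Per-sample read processing driver
# ---------------------------------------------------------------------------

@dataclass
class ReadProcessingStats:
    total_pairs: int = 0
    unassigned: int = 0
    join_rejected: int = 0
    extract_rejected: int = 0


def process_read_pairs(
    read_pairs: Iterable[tuple[str, str, str, str]],
    sheet: SampleSheet,
    flank5: str,
    flank3: str,
    max_barcode_mismatch: int = 0,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
    max_flank_mismatch: int = 1,
    length_range: tuple[int, int] = (30, 42),
) -> tuple[CountMatrix, ReadProcessingStats]:
    """Stream read pairs through demultiplex, join, extract, dereplicate.

    Returns the dereplicated (unfiltered) count matrix whose totals are
    the per-sample numbers of successfully extracted reads, plus
    processing statistics.
    """
    validate_barcodes(sheet, max_barcode_mismatch)
    table = sheet.barcode_to_sample
    per_sample: dict[str, Counter] = {s: Counter() for s in sheet.sample_ids}
    stats = ReadProcessingStats()
    for r1, r2, q1, q2 in read_pairs:
        stats.total_pairs += 1
        sample = assign_barcode(r1, table, max_barcode_mismatch, sheet.barcode_length)
        if sample is None:
            stats.unassigned += 1
            continue
        merged = join_pairs(
            r1, r2, min_overlap=min_overlap, max_mismatch_frac=max_mismatch_frac,
            qual1=q1, qual2=q2,
        )
        if merged is None:
            stats.join_rejected += 1
            continue
        region = extract_variable_region(
            merged, flank5, flank3,
            max_flank_mismatch=max_flank_mismatch, length_range=length_range,
        )
        if region is None:
            stats.extract_rejected += 1
            continue
        per_sample[sample][region] += 1
    totals = {s: sum(c.values()) for s, c in per_sample.items()}
    matrix = CountMatrix.from_dict(
        {s: dict(c) for s, c in per_sample.items()}, totals=totals
    )
    # preserve sheet sample order
    matrix = CountMatrix(
        matrix.counts[sheet.sample_ids], matrix.totals[sheet.sample_ids]
    )
    return matrix, stats
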