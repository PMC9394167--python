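"""Synthetic branched-selection sequencing data with ground truth.

The generator emulates the statistical structure of a late-round
selection pool read out by per-sample branched selections:

* a pool of ~36-nt variable regions, partly organized into families of
  point-mutated descendants of common ancestors;
* a heavy-tailed log-normal abundance spectrum in which the most
  abundant aptamer holds roughly 10% of the pool and the long tail of
  aptamers each hold far less than 1%;
* group-specific enrichment or depletion multipliers planted on a known
  subset of aptamers (the signal the analysis should recover);
* multiplicative log-normal patient-to-patient noise; and
* multinomial sequencing at a configurable read depth.

Counts can be emitted as barcoded paired-end FASTQ so the read
processing stages are exercised end to end; ground truth is returned as
a :class:`TruthTable` for sensitivity / false-positive accounting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigError, PlantedEffect, SimulationConfig
from .countmatrix import CountMatrix
from .samples import (
    COHORT_TRAINING,
    GROUP_C,
    GROUP_TA,
    GROUP_T2T4,
    SampleRecord,
    SampleSheet,
)
from .seqproc import reverse_complement

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class TruthTable:
    """Ground truth of a simulated pool.

    One row per aptamer: sequence, baseline pool fraction (summing to
    one), per-group expected multiplier, family id (empty string for
    singletons), and whether an effect was planted on it.
    """

    table: pd.DataFrame  # columns: sequence, baseline_fraction, mult_C, mult_Ta, mult_T2T4, family_id, planted

    def __post_init__(self) -> None:
        if not np.isclose(self.table["baseline_fraction"].sum(), 1.0):
            raise ConfigError("baseline fractions must sum to 1")
        if self.table["sequence"].duplicated().any():
            raise ConfigError("duplicate sequences in truth table")

    @property
    def sequences(self) -> list[str]:
        return self.table["sequence"].tolist()

    def multipliers(self, group: str) -> np.ndarray:
        return self.table[f"mult_{group}"].to_numpy()

    def planted_sequences(self) -> list[str]:
        return self.table.loc[self.table["planted"], "sequence"].tolist()

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        df["planted"] = df["planted"].astype(bool)
        df["family_id"] = df["family_id"].astype(str)
        return cls(df)


def _random_sequences(rng: np.random.Generator, n: int, length: int) -> list[str]:
    draws = rng.integers(0, 4, size=(n, length))
    return ["".join(_BASES[row]) for row in draws]


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0.0:
        return seq
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for pos in hits:
        current = out[pos]
        choices = [b for b in "ACGT" if b != current]
        out[pos] = choices[rng.integers(0, 3)]
    return "".join(out)


def generate_pool(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> TruthTable:
    """Draw a pool of distinct sequences with log-normal baseline fractions.

    Family ancestors and singletons are uniform over {A,C,G,T}^L; family
    members carry i.i.d. point substitutions at the within-family
    mutation rate.  Baseline fractions are log-normal(mu, sigma),
    normalized to sum to one; only sigma shapes the spectrum after
    normalization.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_total = cfg.n_aptamers
    if n_total < 1:
        raise ConfigError("pool must contain at least one aptamer")
    length = cfg.variable_region_length
    if n_total > 4 ** length:
        raise ConfigError(
            f"cannot draw {n_total} distinct sequences of length {length}"
        )
    sequences: list[str] = []
    families: list[str] = []
    foreign: set[str] = set()  # sequences owned by other families / singletons

    for fam_idx in range(cfg.n_families):
        fam_id = f"F{fam_idx + 1:03d}"
        for _attempt in range(1000):
            ancestor = _random_sequences(rng, 1, length)[0]
            if ancestor not in foreign:
                break
        else:
            raise ConfigError("could not draw distinct family ancestors")
        fam_members = [ancestor]
        for _ in range(cfg.members_per_family - 1):
            # members may coincide with the ancestor or a sibling (e.g. at
            # mutation rate 0); coinciding rows are collapsed below
            for _attempt in range(1000):
                member = _mutate(rng, ancestor, cfg.mutation_rate_within_family)
                if member not in foreign:
                    break
            else:
                raise ConfigError("could not keep family members out of other families")
            fam_members.append(member)
        foreign.update(fam_members)
        sequences.extend(fam_members)
        families.extend([fam_id] * len(fam_members))
    n_singles = 0
    attempts = 0
    while n_singles < cfg.n_singletons:
        attempts += 1
        if attempts > 1000 * max(cfg.n_singletons, 1):
            raise ConfigError(
                f"could not draw {cfg.n_singletons} distinct singleton "
                f"sequences of length {length}"
            )
        cand = _random_sequences(rng, 1, length)[0]
        if cand not in foreign:
            foreign.add(cand)
            sequences.append(cand)
            families.append("")
            n_singles += 1

    weights = rng.lognormal(cfg.abundance_mu, cfg.abundance_sigma, size=n_total)
    table = pd.DataFrame(
        {
            "sequence": sequences,
            "baseline_fraction": weights,
            "mult_C": 1.0,
            "mult_Ta": 1.0,
            "mult_T2T4": 1.0,
            "family_id": families,
            "planted": False,
        }
    )
    # rows with identical sequence (possible within a family) collapse
    # into one pool member carrying the summed abundance weight
    table = (
        table.groupby("sequence", as_index=False, sort=False)
        .agg(
            baseline_fraction=("baseline_fraction", "sum"),
            mult_C=("mult_C", "first"),
            mult_Ta=("mult_Ta", "first"),
            mult_T2T4=("mult_T2T4", "first"),
            family_id=("family_id", "first"),
            planted=("planted", "first"),
        )
        .reset_index(drop=True)
    )
    table["baseline_fraction"] /= table["baseline_fraction"].sum()
    truth = TruthTable(table)
    return apply_planted_effects(truth, cfg.planted_effects)


_EFFECT_GROUPS = {
    "vsC_cancer": (GROUP_TA, GROUP_T2T4),
    "Ta_vs_T2T4": (GROUP_T2T4,),
    "Ta_only": (GROUP_TA,),
    "T2T4_only": (GROUP_T2T4,),
}


def apply_planted_effects(truth: TruthTable, effects: list[PlantedEffect]) -> TruthTable:
    """Multiply group abundances of the indexed aptamers by their effect."""
    table = truth.table.copy()
    for effect in effects:
        if not (0 <= effect.index < len(table)):
            raise ConfigError(f"planted index {effect.index} out of range")
        for group in _EFFECT_GROUPS[effect.comparison]:
            table.loc[effect.index, f"mult_{group}"] *= effect.multiplier
        table.loc[effect.index, "planted"] = True
    return TruthTable(table)


def choose_plantable_indices(
    truth: TruthTable,
    n: int,
    rng: np.random.Generator,
    min_fraction: float = 1e-4,
    max_fraction: float = 1e-2,
    singletons_only: bool = True,
) -> list[int]:
    """Indices of aptamers suitable for planting an effect.

    Candidates must be abundant enough to be observed reliably at the
    simulated depth (baseline fraction >= ``min_fraction``) but not so
    dominant that changing them visibly shifts every other aptamer's
    pool fraction through renormalization (<= ``max_fraction``).  By
    default only singleton aptamers qualify, so clustering cannot merge
    a planted sequence with unplanted family members.
    """
    t = truth.table
    mask = (t["baseline_fraction"] >= min_fraction) & (
        t["baseline_fraction"] <= max_fraction
    )
    if singletons_only:
        mask &= t["family_id"] == ""
    candidates = np.flatnonzero(mask.to_numpy())
    if len(candidates) < n:
        raise ConfigError(
            f"only {len(candidates)} aptamers in the plantable abundance band; "
            f"{n} requested"
        )
    return sorted(rng.choice(candidates, size=n, replace=False).tolist())


def make_sample_sheet(
    cfg: SimulationConfig,
    cohort: str = COHORT_TRAINING,
    prefix: str | None = None,
    rng: np.random.Generator | None = None,
    min_barcode_dist: int = 3,
    avoid: tuple[str, ...] = (),
) -> SampleSheet:
    """Barcoded sample sheet for one simulated cohort.

    Barcodes are drawn greedily so every pair differs at
    ``min_barcode_dist`` or more positions, keeping mismatch-tolerant
    demultiplexing unambiguous.  ``avoid`` lists barcodes already in
    use elsewhere (e.g. another cohort) that new draws must also keep
    their distance from.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    n_samples = cfg.n_control + cfg.n_ta + cfg.n_t2t4
    barcodes: list[str] = []
    attempts = 0
    while len(barcodes) < n_samples:
        attempts += 1
        if attempts > 100_000:
            raise ConfigError("could not draw enough well-separated barcodes")
        cand = "".join(_BASES[rng.integers(0, 4, size=cfg.barcode_length)])
        if all(
            sum(a != b for a, b in zip(cand, bc)) >= min_barcode_dist
            for bc in list(avoid) + barcodes
        ):
            barcodes.append(cand)
    prefix = prefix if prefix is not None else cohort[:1].upper()
    records = []
    idx = 0
    for group, count in (
        (GROUP_C, cfg.n_control),
        (GROUP_TA, cfg.n_ta),
        (GROUP_T2T4, cfg.n_t2t4),
    ):
        for k in range(count):
            records.append(
                SampleRecord(
                    sample_id=f"{prefix}_{group}_{k + 1:02d}",
                    barcode=barcodes[idx],
                    group=group,
                    cohort=cohort,
                )
            )
            idx += 1
    return SampleSheet(records)


def simulate_branched_counts(
    truth: TruthTable,
    sheet: SampleSheet,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Multinomial per-sample counts under planted effects and noise.

    For sample s in group g, sampling probabilities are proportional to
    baseline_a * multiplier_{a,g} * eps_{a,s} with eps log-normal(0,
    sample_noise_sigma^2); counts are Multinomial(read_depth, p).  The
    second return value holds the realized per-sample probability
    vectors (the expected frequencies of the multinomial draw).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    baseline = truth.table["baseline_fraction"].to_numpy()
    sequences = truth.sequences
    count_cols: dict[str, np.ndarray] = {}
    prob_cols: dict[str, np.ndarray] = {}
    for rec in sheet:
        mult = truth.multipliers(rec.group)
        if cfg.sample_noise_sigma > 0:
            eps = rng.lognormal(0.0, cfg.sample_noise_sigma, size=len(baseline))
        else:
            eps = 1.0
        weights = baseline * mult * eps
        p = weights / weights.sum()
        count_cols[rec.sample_id] = rng.multinomial(cfg.read_depth, p)
        prob_cols[rec.sample_id] = p
    counts = pd.DataFrame(count_cols, index=pd.Index(sequences, name="sequence"))
    totals = pd.Series(cfg.read_depth, index=counts.columns, dtype=np.int64)
    probs = pd.DataFrame(prob_cols, index=counts.index)
    # drop never-observed aptamers from the count matrix (they would not
    # appear in real sequencing output); totals stay at read_depth
    observed = counts.sum(axis=1) > 0
    counts = counts[observed]
    matrix = CountMatrix(counts.astype(np.int64), totals)
    return matrix, probs


def write_fastq_pairs(
    counts: CountMatrix,
    sheet: SampleSheet,
    cfg: SimulationConfig,
    out_dir: str | Path,
    rng: np.random.Generator | None = None,
    basename: str = "reads",
) -> tuple[Path, Path]:
    """Emit every counted molecule once as a barcoded paired-end read.

    The amplicon is barcode + 5' flank + variable region + 3' flank;
    read 1 is its first ``read_length`` bases and read 2 the first
    ``read_length`` bases of its reverse complement, so the mates
    overlap across the variable region.  Reads from all samples are
    pooled and shuffled, as on a multiplexed lane.  An optional uniform
    substitution ``error_rate`` exercises the mismatch tolerances.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 3)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    min_len = sheet.barcode_length + len(cfg.flank5)
    if cfg.read_length < min_len:
        raise ConfigError(
            f"read_length {cfg.read_length} shorter than barcode + 5' flank ({min_len})"
        )
    barcode_of = {rec.sample_id: rec.barcode for rec in sheet}
    pairs: list[tuple[str, str]] = []
    for sample_id in counts.sample_ids:
        barcode = barcode_of[sample_id]
        col = counts.counts[sample_id]
        for seq, n in col[col > 0].items():
            amplicon = barcode + cfg.flank5 + seq + cfg.flank3
            r1 = amplicon[: cfg.read_length]
            r2 = reverse_complement(amplicon)[: cfg.read_length]
            pairs.extend([(r1, r2)] * int(n))
    order = rng.permutation(len(pairs))
    qual1 = chr(cfg.phred_quality + 33)
    r1_path = out_dir / f"{basename}_R1.fastq"
    r2_path = out_dir / f"{basename}_R2.fastq"
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for out_idx, pair_idx in enumerate(order):
            r1, r2 = pairs[pair_idx]
            if cfg.error_rate > 0:
                r1 = _sequencing_errors(rng, r1, cfg.error_rate)
                r2 = _sequencing_errors(rng, r2, cfg.error_rate)
            name = f"sim.{out_idx + 1}"
            f1.write(f"@{name}/1\n{r1}\n+\n{qual1 * len(r1)}\n")
            f2.write(f"@{name}/2\n{r2}\n+\n{qual1 * len(r2)}\n")
    return r1_path, r2_path


def _sequencing_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for pos in hits:
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[rng.integers(0, 3)]
    return "".join(out)
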