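"""Named simulation scenarios: the study conditions used for evaluation.

Three reusable setups, all at a read depth of 100,000 (scaled down from
the study's millions of reads; pool fractions, not raw counts, carry the
signal) and patient-noise sigma 0.3:

* :func:`recovery_scenario` -- a 500-singleton pool with 10 planted
  effects (5 aptamers depleted to 0.5x in both cancer groups, 5
  enriched 2x in T2-T4), 32 samples per group.  Used to measure
  sensitivity and false positives of the discovery stage.
* :func:`study_scenario` -- a structured pool (20 families of 5 plus
  400 singletons) with a planted effect pattern shaped like the
  published finding: 15 aptamers depleted in cancer, 15 enriched in
  late-stage and 3 in early-stage samples; a 96-sample training cohort
  and a 22-sample validation cohort (10 C / 8 Ta / 4 T2-T4).
* :func:`null_scenario` -- the recovery pool with no planted effects,
  for false-selection rates under the null.

Planted aptamers are drawn from a mid-abundance band (baseline pool
fraction between 1e-4 and 1e-2): abundant enough to be observed
reliably at the simulated depth, yet small enough that perturbing them
does not shift every other aptamer's pool fraction through
renormalization.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .config import PlantedEffect, SimulationConfig
from .countmatrix import CountMatrix
from .samples import COHORT_VALIDATION, SampleSheet
from .simulate import (
    TruthTable,
    choose_plantable_indices,
    generate_pool,
    make_sample_sheet,
    simulate_branched_counts,
)

DEPTH = 100_000
NOISE_SIGMA = 0.3


def _planted(indices: list[int], comparison: str, multiplier: float) -> list[PlantedEffect]:
    return [PlantedEffect(i, comparison, multiplier) for i in indices]


def recovery_scenario(seed: int) -> tuple[TruthTable, SampleSheet, CountMatrix, SimulationConfig]:
    """Pool of 500 singletons, 10 planted effects, 32 samples per group."""
    cfg = SimulationConfig(
        n_families=0,
        members_per_family=0,
        n_singletons=500,
        sample_noise_sigma=NOISE_SIGMA,
        read_depth=DEPTH,
        n_control=32,
        n_ta=32,
        n_t2t4=32,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    truth = generate_pool(cfg, rng=rng)
    idx = choose_plantable_indices(truth, 10, rng)
    effects = _planted(idx[:5], "vsC_cancer", 0.5) + _planted(idx[5:], "Ta_vs_T2T4", 2.0)
    cfg = replace(cfg, planted_effects=effects)
    truth = generate_pool(cfg, rng=np.random.default_rng(seed))
    sheet = make_sample_sheet(cfg, rng=np.random.default_rng(seed + 1))
    counts, _ = simulate_branched_counts(truth, sheet, cfg, rng=np.random.default_rng(seed + 2))
    return truth, sheet, counts, cfg


def null_scenario(seed: int) -> tuple[TruthTable, SampleSheet, CountMatrix, SimulationConfig]:
    """Recovery pool and cohort sizes with no planted effects."""
    cfg = SimulationConfig(
        n_families=0,
        members_per_family=0,
        n_singletons=500,
        sample_noise_sigma=NOISE_SIGMA,
        read_depth=DEPTH,
        n_control=32,
        n_ta=32,
        n_t2t4=32,
        seed=seed,
    )
    truth = generate_pool(cfg, rng=np.random.default_rng(seed))
    sheet = make_sample_sheet(cfg, rng=np.random.default_rng(seed + 1))
    counts, _ = simulate_branched_counts(truth, sheet, cfg, rng=np.random.default_rng(seed + 2))
    return truth, sheet, counts, cfg


def study_scenario(
    seed: int,
) -> tuple[TruthTable, SampleSheet, CountMatrix, SimulationConfig]:
    """Structured pool, published-like effect pattern, both cohorts.

    The planted pattern mirrors the discovered aptamer classes: 15
    aptamers depleted to 0.5x in both cancer groups (triggering the
    against-control comparisons at expected |coef| 0.75), 15 aptamers
    shifted 1.25x in T2-T4 and 0.8x in Ta (a stage contrast of expected
    |coef| ~0.45 that stays below the 0.5 against-control gate), and 3
    with the opposite stage shift.  The returned sheet and count matrix
    cover the 96-sample training cohort and the 22-sample validation
    cohort together.
    """
    base_cfg = SimulationConfig(
        sample_noise_sigma=NOISE_SIGMA,
        read_depth=DEPTH,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    truth = generate_pool(base_cfg, rng=rng)
    idx = choose_plantable_indices(truth, 33, rng)
    effects = (
        _planted(idx[:15], "vsC_cancer", 0.5)
        + _planted(idx[15:30], "T2T4_only", 1.25)
        + _planted(idx[15:30], "Ta_only", 0.8)
        + _planted(idx[30:33], "Ta_only", 1.25)
        + _planted(idx[30:33], "T2T4_only", 0.8)
    )
    cfg = replace(base_cfg, planted_effects=effects)
    truth = generate_pool(cfg, rng=np.random.default_rng(seed))
    train_sheet = make_sample_sheet(cfg, rng=np.random.default_rng(seed + 1), prefix="TR")
    val_cfg = replace(cfg, n_control=10, n_ta=8, n_t2t4=4)
    val_sheet = make_sample_sheet(
        val_cfg,
        cohort=COHORT_VALIDATION,
        prefix="VA",
        rng=np.random.default_rng(seed + 4),
        avoid=tuple(r.barcode for r in train_sheet),
    )
    sheet = SampleSheet(list(train_sheet) + list(val_sheet))
    train_counts, _ = simulate_branched_counts(
        truth, train_sheet, cfg, rng=np.random.default_rng(seed + 2)
    )
    val_counts, _ = simulate_branched_counts(
        truth, val_sheet, val_cfg, rng=np.random.default_rng(seed + 5)
    )
    merged = train_counts.counts.join(val_counts.counts, how="outer").fillna(0)
    merged = merged.astype("int64").sort_index()
    totals = pd.concat([train_counts.totals, val_counts.totals])
    counts = CountMatrix(merged[sheet.sample_ids], totals[sheet.sample_ids].astype("int64"))
    return truth, sheet, counts, cfg
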