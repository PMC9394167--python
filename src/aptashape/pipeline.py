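"""End-to-end orchestration: reads or counts -> discriminatory set -> labels.

``run_pipeline`` executes the three analysis stages in order:

1. **seqproc** -- process FASTQ pairs (or accept a pre-made count
   table), filter by minimum count, cluster near-identical sequences,
   normalize to percent-of-pool, and keep the most abundant aptamers
   (ranked on training samples);
2. **diffenrich** -- relative levels on the training cohort, per-aptamer
   group OLS for the three comparisons, BH adjustment, selection of
   discriminatory aptamers and family labeling;
3. **classify** -- relative levels of the discriminatory aptamers on the
   validation cohort (the training cohort when no validation samples
   exist), heatmap column clustering, PCA, component orientation, and
   sign-rule classification.

All outputs are plain TSV / Newick / text; a run log records the
configuration and stage statistics (no timestamps), so reruns with the
same inputs and seed are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import classify as _classify
from . import diffenrich as _diffenrich
from . import seqproc as _seqproc
from .config import PipelineConfig
from .countmatrix import CountMatrix, write_fasta, write_frequency_tsv
from .diffenrich import DiscriminatorySet
from .samples import COHORT_TRAINING, COHORT_VALIDATION, SampleSheet

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage failure, labeled with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    counts: CountMatrix                      # clustered, filtered counts
    frequencies: pd.DataFrame                # top-N percent-of-pool
    ols_results: pd.DataFrame
    discriminatory: DiscriminatorySet
    # classification products are None when no aptamer passed selection
    pca: _classify.PCAResult | None
    classification: _classify.ClassificationResult | None
    column_clustering: _classify.ColumnClustering | None
    log_lines: list[str]


def _check_samples_known(counts: CountMatrix, sheet: SampleSheet) -> None:
    known = set(sheet.sample_ids)
    unknown = [s for s in counts.sample_ids if s not in known]
    if unknown:
        raise PipelineError(
            "seqproc", f"samples absent from the sample sheet: {unknown}"
        )


def process_counts(
    counts: CountMatrix, sheet: SampleSheet, cfg: PipelineConfig, log: list[str]
) -> tuple[CountMatrix, pd.DataFrame]:
    """Filter, cluster, normalize and rank an input count matrix."""
    _check_samples_known(counts, sheet)
    log.append(f"seqproc: input {len(counts.sequences)} sequences, "
               f"{len(counts.sample_ids)} samples")
    filtered = _seqproc.filter_min_count(counts, cfg.min_count)
    log.append(f"seqproc: {len(filtered.sequences)} sequences after "
               f"min_count>={cfg.min_count} filter")
    clustered = _seqproc.cluster_by_edit_distance(
        filtered, max_dist=cfg.cluster_max_dist, variant=cfg.distance_variant
    )
    log.append(f"seqproc: {clustered.n_clusters} clusters at "
               f"distance<={cfg.cluster_max_dist} ({cfg.distance_variant})")
    freqs = _seqproc.normalize_frequencies(clustered.counts)
    training_ids = [
        r.sample_id for r in sheet if r.cohort == COHORT_TRAINING
        and r.sample_id in freqs.columns
    ]
    ranking_cols = training_ids if training_ids else list(freqs.columns)
    top = _seqproc.select_top_abundant(freqs[ranking_cols], cfg.top_n)
    top_all = freqs.loc[top.index]
    log.append(f"seqproc: kept top {len(top_all)} aptamers by mean frequency "
               f"over {len(ranking_cols)} ranking samples")
    return clustered.counts, top_all


def process_fastq(
    r1_path: str | Path,
    r2_path: str | Path,
    sheet: SampleSheet,
    cfg: PipelineConfig,
    log: list[str],
) -> tuple[CountMatrix, pd.DataFrame]:
    """Full read processing from a pooled FASTQ pair."""
    pairs = _seqproc.iter_fastq_pairs(r1_path, r2_path)
    raw, stats = _seqproc.process_read_pairs(
        pairs,
        sheet,
        flank5=cfg.flank5,
        flank3=cfg.flank3,
        max_barcode_mismatch=cfg.max_barcode_mismatch,
        min_overlap=cfg.min_overlap,
        max_mismatch_frac=cfg.max_mismatch_frac,
        max_flank_mismatch=cfg.max_flank_mismatch,
        length_range=cfg.length_range,
    )
    log.append(
        "seqproc: "
        f"{stats.total_pairs} read pairs, {stats.unassigned} unassigned, "
        f"{stats.join_rejected} join-rejected, "
        f"{stats.extract_rejected} extract-rejected"
    )
    return process_counts(raw, sheet, cfg, log)


def run_pipeline(
    cfg: PipelineConfig,
    sheet: SampleSheet,
    counts: CountMatrix | None = None,
    fastq_pair: tuple[str | Path, str | Path] | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute seqproc -> diffenrich -> classify and optionally write outputs.

    Exactly one of ``counts`` or ``fastq_pair`` must be given.  The
    pipeline is a pure function of (inputs, config): identical inputs
    and ``cfg.rng_seed`` yield byte-identical output files.
    """
    if (counts is None) == (fastq_pair is None):
        raise PipelineError("seqproc", "provide exactly one of counts or fastq_pair")
    log: list[str] = [f"config: {asdict(cfg)}"]

    # --- stage 1: seqproc ---------------------------------------------------
    try:
        if fastq_pair is not None:
            clustered, freqs = process_fastq(fastq_pair[0], fastq_pair[1], sheet, cfg, log)
        else:
            clustered, freqs = process_counts(counts, sheet, cfg, log)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("seqproc", str(exc)) from exc

    # --- stage 2: diffenrich ------------------------------------------------
    try:
        training = sheet.subset(cohort=COHORT_TRAINING)
        train_ids = [s for s in training.sample_ids if s in freqs.columns]
        missing = [s for s in training.sample_ids if s not in freqs.columns]
        if missing:
            raise _diffenrich.DiffEnrichError(
                f"training samples missing from frequency matrix: {missing}"
            )
        levels = _diffenrich.relative_to_mean(freqs[train_ids])
        ols = _diffenrich.run_differential_tests(levels, training, mode=cfg.ols_mode)
        selected = _diffenrich.select_discriminatory(ols, cfg)
        log.append(
            f"diffenrich: {len(selected.sequences)} discriminatory aptamers "
            f"({', '.join(f'{c}={len(selected.sequences_for(c))}' for c in _diffenrich.COMPARISONS)})"
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("diffenrich", str(exc)) from exc

    # --- stage 3: classify --------------------------------------------------
    pca = classification = columns = None
    disc_seqs = [s for s in selected.sequences if s in freqs.index]
    if not disc_seqs:
        log.append("classify: skipped (no discriminatory aptamers selected)")
    else:
        try:
            pca, classification, columns = _classify_stage(
                cfg, sheet, training, freqs, selected, disc_seqs, log
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("classify", str(exc)) from exc

    result = PipelineResult(
        counts=clustered,
        frequencies=freqs,
        ols_results=ols,
        discriminatory=selected,
        pca=pca,
        classification=classification,
        column_clustering=columns,
        log_lines=log,
    )
    if out_dir is not None:
        write_outputs(result, Path(out_dir))
    return result


def _classify_stage(
    cfg: PipelineConfig,
    sheet: SampleSheet,
    training: SampleSheet,
    freqs: pd.DataFrame,
    selected: DiscriminatorySet,
    disc_seqs: list[str],
    log: list[str],
) -> tuple[_classify.PCAResult, _classify.ClassificationResult, _classify.ColumnClustering]:
    """Heatmap ordering, PCA, orientation and sign-rule classification."""
    try:
        evaluation = sheet.subset(cohort=COHORT_VALIDATION)
        cohort_used = COHORT_VALIDATION
    except Exception:
        evaluation = training
        cohort_used = COHORT_TRAINING
        log.append("classify: no validation samples; classifying the "
                   "training cohort (resubstitution)")
    eval_ids = [s for s in evaluation.sample_ids if s in freqs.columns]
    if not eval_ids:
        raise _classify.ClassifyError("no evaluation samples in frequency matrix")
    eval_levels = _diffenrich.relative_to_mean(freqs.loc[disc_seqs, eval_ids])
    # heatmap rows in family order (labeled families first, then singletons)
    fam_of = dict(zip(selected.table["sequence"], selected.table["family"]))
    row_order = sorted(
        eval_levels.index, key=lambda s: (fam_of.get(s) == "", fam_of.get(s, ""), s)
    )
    eval_levels = eval_levels.loc[row_order]
    columns = _classify.hierarchical_cluster_columns(
        eval_levels, metric=cfg.heatmap_metric
    )
    pca = _classify.pca_fit(eval_levels.T, center=cfg.pca_center, scale=cfg.pca_scale)
    pca = _classify.orient_components(pca, evaluation)
    mode = (
        _classify.MODE_COMBINED
        if pca.scores.shape[1] >= 2
        else _classify.MODE_CANCER_VS_CONTROL
    )
    classification = _classify.classify_by_sign(pca, evaluation, mode=mode)
    log.append(
        f"classify: cohort={cohort_used}, "
        f"PC1 variance fraction={pca.variance_fraction[0]:.4f}, "
        + ", ".join(
            f"{task} accuracy={acc:.4f}"
            for task, acc in classification.accuracies.items()
        )
    )
    return pca, classification, columns


def write_outputs(result: PipelineResult, out_dir: Path) -> None:
    """Write every pipeline product as a text file under ``out_dir``."""
    out_dir.mkdir(parents=True, exist_ok=True)
    result.counts.to_tsv(out_dir / "counts.tsv")
    write_frequency_tsv(result.frequencies, out_dir / "frequencies.tsv")
    result.ols_results.to_csv(
        out_dir / "ols_results.tsv", sep="\t", index=False, float_format="%.10g"
    )
    result.discriminatory.to_tsv(out_dir / "discriminatory.tsv")
    write_fasta(result.discriminatory.sequences, out_dir / "discriminatory.fasta")
    for comparison in _diffenrich.COMPARISONS:
        coords = _diffenrich.volcano_coordinates(result.ols_results, comparison)
        coords.to_csv(
            out_dir / f"volcano_{comparison}.tsv",
            sep="\t",
            index=False,
            float_format="%.10g",
        )
    if result.pca is not None:
        scores = result.pca.scores.copy()
        scores.index.name = "sample_id"
        scores.to_csv(out_dir / "pca_scores.tsv", sep="\t", float_format="%.10g")
        loadings = result.pca.loadings.copy()
        loadings.index.name = "sequence"
        loadings.to_csv(out_dir / "pca_loadings.tsv", sep="\t", float_format="%.10g")
        pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(len(result.pca.variance_fraction))],
                "variance_fraction": result.pca.variance_fraction,
            }
        ).to_csv(out_dir / "pca_variance.tsv", sep="\t", index=False, float_format="%.10g")
    if result.classification is not None:
        result.classification.to_tsv(out_dir / "predictions.tsv")
        pd.DataFrame(
            sorted(result.classification.accuracies.items()),
            columns=["task", "accuracy"],
        ).to_csv(out_dir / "accuracy.tsv", sep="\t", index=False, float_format="%.10g")
    if result.column_clustering is not None:
        (out_dir / "dendrogram.nwk").write_text(result.column_clustering.newick + "\n")
    (out_dir / "run_log.txt").write_text("\n".join(result.log_lines) + "\n")
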