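"""Pipeline and simulation configuration objects with YAML round trip."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

# Constant regions flanking the 36-nt variable region on the sense strand
# of the amplicon (5' leader after the T7 start, and 3' trailer).
DEFAULT_FLANK5 = "GGGGCCACCAACGACATT"
DEFAULT_FLANK3 = "GTTGATATAAATAGTGCCCATGGATC"


class ConfigError(ValueError):
    """Invalid configuration value."""


@dataclass
class PipelineConfig:
    """Tunable parameters of the analysis pipeline.

    Defaults encode the published analysis settings: sequences kept when
    observed at least 4 times per sample, homologous sequences merged at
    optimal-string-alignment distance < 4, the 1000 most abundant
    aptamers tested, and selection thresholds |coef| > 0.5 (cancer vs
    control) or > 0.25 (Ta vs T2-T4) at Benjamini-Hochberg adjusted
    p < 0.01.
    """

    min_count: int = 4
    cluster_max_dist: int = 3          # "distance < 4" == max inclusive distance 3
    top_n: int = 1000
    coef_threshold_vs_C: float = 0.5
    coef_threshold_Ta_vs_T2T4: float = 0.25
    adj_p_threshold: float = 0.01
    flank5: str = DEFAULT_FLANK5
    flank3: str = DEFAULT_FLANK3
    rng_seed: int = 0
    # read processing
    max_barcode_mismatch: int = 0
    min_overlap: int = 10
    max_mismatch_frac: float = 0.1
    max_flank_mismatch: int = 1
    min_region_length: int = 30
    max_region_length: int = 42
    # algorithm variants
    distance_variant: str = "osa"      # "osa" (with transpositions) or "levenshtein"
    ols_mode: str = "pooled"           # "pooled" three-group model or "pairwise"
    family_max_dist: int = 8
    pca_center: bool = True
    pca_scale: bool = False
    heatmap_metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.min_count < 1:
            raise ConfigError("min_count must be >= 1")
        if self.top_n < 1:
            raise ConfigError("top_n must be >= 1")
        if self.cluster_max_dist < 0:
            raise ConfigError("cluster_max_dist must be >= 0")
        for name in ("coef_threshold_vs_C", "coef_threshold_Ta_vs_T2T4", "adj_p_threshold"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.distance_variant not in ("osa", "levenshtein"):
            raise ConfigError(f"unknown distance_variant: {self.distance_variant!r}")
        if self.ols_mode not in ("pooled", "pairwise"):
            raise ConfigError(f"unknown ols_mode: {self.ols_mode!r}")
        if self.min_region_length > self.max_region_length:
            raise ConfigError("min_region_length > max_region_length")

    @property
    def length_range(self) -> tuple[int, int]:
        return (self.min_region_length, self.max_region_length)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass(frozen=True)
class PlantedEffect:
    """A group-specific abundance multiplier planted on one pool member.

    ``comparison`` selects which groups receive the multiplier:

    * ``vsC_cancer``  -- both cancer groups (Ta and T2-T4) are multiplied,
      emulating an aptamer whose target protein differs between cancer
      patients and controls;
    * ``Ta_vs_T2T4``  -- only the T2-T4 group is multiplied, emulating a
      stage-discriminatory aptamer;
    * ``Ta_only`` / ``T2T4_only`` -- a single group is multiplied
      (used to build stage contrasts symmetric around the control level).
    """

    index: int
    comparison: str
    multiplier: float

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ConfigError("planted multiplier must be > 0")
        if self.comparison not in ("vsC_cancer", "Ta_vs_T2T4", "Ta_only", "T2T4_only"):
            raise ConfigError(f"unknown planted comparison: {self.comparison!r}")


@dataclass
class SimulationConfig:
    """Conditions for the synthetic branched-selection generator.

    The pool emulates a round-4 selection pool: a log-normal abundance
    spectrum in which the single most abundant aptamer holds roughly 10%
    of the pool while the vast majority of aptamers individually hold
    <1%, with sequence families descending from point-mutated ancestors.
    Read depth is scaled down from the study's millions of reads per
    sample to keep simulations fast; per-aptamer frequencies, not raw
    counts, carry the signal.
    """

    n_families: int = 20
    members_per_family: int = 5
    n_singletons: int = 400
    variable_region_length: int = 36
    mutation_rate_within_family: float = 0.03   # per nt, substitutions only
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.8   # calibrated so the top aptamer holds ~10% of the pool
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    sample_noise_sigma: float = 0.3             # lognormal sigma per aptamer per sample
    read_depth: int = 100_000
    n_control: int = 32
    n_ta: int = 32
    n_t2t4: int = 32
    seed: int = 0
    # read emission
    barcode_length: int = 8
    read_length: int = 100
    error_rate: float = 0.0
    phred_quality: int = 37
    flank5: str = DEFAULT_FLANK5
    flank3: str = DEFAULT_FLANK3

    def __post_init__(self) -> None:
        if self.read_depth < 1:
            raise ConfigError("read_depth must be >= 1")
        if not (0.0 <= self.mutation_rate_within_family < 1.0):
            raise ConfigError("mutation_rate_within_family must be in [0, 1)")
        if self.abundance_sigma < 0:
            raise ConfigError("abundance_sigma must be >= 0")
        if self.sample_noise_sigma < 0:
            raise ConfigError("sample_noise_sigma must be >= 0")
        if not (0.0 <= self.error_rate < 1.0):
            raise ConfigError("error_rate must be in [0, 1)")
        if min(self.n_families, self.members_per_family, self.n_singletons) < 0:
            raise ConfigError("pool composition counts must be >= 0")
        if self.n_families > 0 and self.members_per_family < 1:
            raise ConfigError("members_per_family must be >= 1 when families requested")

    @property
    def n_aptamers(self) -> int:
        return self.n_families * self.members_per_family + self.n_singletons

    def to_yaml(self, path: str | Path) -> None:
        # asdict recurses into PlantedEffect entries
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        effects = [PlantedEffect(**e) for e in data.pop("planted_effects", [])]
        return cls(planted_effects=effects, **data)
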