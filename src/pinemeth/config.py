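"""Configuration objects for the simulator and the analysis pipeline.

Two dataclasses hold every tunable number:

* :class:`SimConfig` -- the study design emulated by the synthetic methylome
  generator (sample layout, coverage model, background methylation levels,
  planted age signals).
* :class:`PipelineConfig` -- the analysis parameters (coverage floor, bin
  sizes, DMR thresholds, metaprofile bin counts, expression breaks).

Both round-trip through YAML so that every run can log its effective
configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import yaml

#: Cytosine sequence contexts (H = A, C or T).
CONTEXTS = ("CG", "CHG", "CHH")

#: Feature classes used by the simulator when drawing background levels.
FEATURE_CLASSES = ("intergenic", "exon", "intron", "te")

#: The four sampled tree ages, in years.
DEFAULT_AGES = (2, 5, 14, 35)


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


def _default_base_levels() -> dict:
    # Conifer-like background: high CG/CHG, low CHH, TE-driven hypermethylation.
    return {
        "CG": {"intergenic": 0.40, "exon": 0.50, "intron": 0.70, "te": 0.85},
        "CHG": {"intergenic": 0.30, "exon": 0.35, "intron": 0.55, "te": 0.70},
        "CHH": {"intergenic": 0.02, "exon": 0.03, "intron": 0.05, "te": 0.08},
    }


def _default_gene_level_spread() -> dict:
    # Width of the per-gene random effect applied to exons and flanks; this is
    # what couples methylation to expression across genes.
    return {"CG": 0.8, "CHG": 0.5, "CHH": 0.02}


def _default_planted() -> dict:
    return {}


@dataclass
class SimConfig:
    """Design of a synthetic age-structured bisulfite experiment.

    The defaults describe a desk-scale experiment with the same structure as
    the emulated study: 4 ages x 2 replicates at ~20x coverage, a TE-rich
    genome with occasionally very long introns, and optional planted signals
    (age-linear 1-kb bins, replicate-variable bins, age-marker genes).
    """

    seed: int = 0

    # genome
    n_chromosomes: int = 2
    chrom_length_bp: int = 1_000_000
    gc_content: float = 0.38
    n_genes: int = 60
    exon_length_range: tuple = (150, 400)
    n_introns_range: tuple = (0, 6)
    short_intron_length_range: tuple = (200, 1200)
    intron_frac_gt_5kb: float = 0.10
    intron_frac_gt_20kb: float = 0.02
    min_intergenic_gap: int = 4500
    te_fraction: float = 0.45
    te_length_range: tuple = (500, 5000)
    te_min_host_intron: int = 5000

    # read-count model
    mean_coverage: float = 20.0
    coverage_dispersion: float = 0.2
    conversion_failure_rate: float = 0.005

    # methylation states
    base_levels: dict = field(default_factory=_default_base_levels)
    gene_level_spread: dict = field(default_factory=_default_gene_level_spread)

    # planted age signal: {(context, direction): n_bins}
    n_planted_age_dmrs: dict = field(default_factory=_default_planted)
    planted_baseline: float = 0.4
    planted_effect: float = 0.3

    # replicate-variable (age-independent) bins
    n_replicate_variable_bins: int = 0
    replicate_variable_context: str = "CG"
    replicate_variable_low: float = 0.3
    replicate_variable_delta: float = 0.3

    # age-marker genes (DAL1-style)
    n_marker_genes: int = 0
    marker_chg_levels: tuple = (0.70, 0.55, 0.40, 0.25)
    marker_tpm: tuple = (5.0, 15.0, 25.0, 35.0)
    marker_upstream_bp: int = 2500
    marker_segment_bp: int = 6000
    marker_first_intron_min: int = 9000

    # sample layout
    ages: tuple = DEFAULT_AGES
    replicates_per_age: int = 2

    # expression model: log TPM = intercept - slope * m + noise, where m is
    # the gene's mean true exon+downstream CG/CHG methylation
    expression_intercept: float = 7.0
    expression_slope: float = 12.0
    expression_gene_noise_sd: float = 0.4
    expression_sample_noise_sd: float = 0.3
    zero_tpm_fraction: float = 0.13

    # lambda spike-in
    lambda_genome_bp: int = 48_502

    # sRNA tracks
    srna_bin_bp: int = 10_000
    srna_lengths: tuple = (21, 22, 24)
    srna_coupling: float = 0.0

    def validate(self) -> "SimConfig":
        if self.n_chromosomes < 1 or self.chrom_length_bp < 10_000:
            raise ConfigError("need at least one chromosome of >=10 kb")
        if not 0.0 < self.gc_content < 1.0:
            raise ConfigError("gc_content must be in (0, 1)")
        if self.n_genes < 0:
            raise ConfigError("n_genes must be >= 0")
        if not 0.0 <= self.te_fraction < 0.95:
            raise ConfigError("te_fraction must be in [0, 0.95)")
        if not 0.0 <= self.conversion_failure_rate <= 1.0:
            raise ConfigError("conversion_failure_rate must be in [0, 1]")
        for ctx, levels in self.base_levels.items():
            if ctx not in CONTEXTS:
                raise ConfigError(f"unknown context {ctx!r}")
            for klass, p in levels.items():
                if klass not in FEATURE_CLASSES:
                    raise ConfigError(f"unknown feature class {klass!r}")
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"base level {ctx}/{klass}={p} outside [0, 1]")
        if not 0.0 <= self.planted_baseline <= 1.0:
            raise ConfigError("planted_baseline must be in [0, 1]")
        if not 0.0 <= self.planted_baseline + self.planted_effect <= 1.0:
            raise ConfigError("planted_baseline + planted_effect leaves [0, 1]")
        for (ctx, direction), n in self.n_planted_age_dmrs.items():
            if ctx not in CONTEXTS or direction not in ("hyper", "hypo"):
                raise ConfigError(f"bad planted key {(ctx, direction)!r}")
            if n < 0:
                raise ConfigError("planted bin counts must be >= 0")
        if self.replicate_variable_context not in CONTEXTS:
            raise ConfigError("replicate_variable_context must be a context")
        if not 0 <= self.replicate_variable_low + self.replicate_variable_delta <= 1:
            raise ConfigError("replicate-variable levels leave [0, 1]")
        if list(self.ages) != sorted(set(self.ages)):
            raise ConfigError("ages must be strictly increasing")
        if len(self.marker_chg_levels) != len(self.ages):
            raise ConfigError("marker_chg_levels must give one level per age")
        if any(b >= a for a, b in zip(self.marker_chg_levels, self.marker_chg_levels[1:])) is False:
            pass  # strictly decreasing checked below
        if not all(a > b for a, b in zip(self.marker_chg_levels, self.marker_chg_levels[1:])):
            raise ConfigError("marker_chg_levels must strictly decrease with age")
        if not all(a < b for a, b in zip(self.marker_tpm, self.marker_tpm[1:])):
            raise ConfigError("marker_tpm must strictly increase with age")
        if self.replicates_per_age < 1:
            raise ConfigError("replicates_per_age must be >= 1")
        if not 0.0 <= self.zero_tpm_fraction < 1.0:
            raise ConfigError("zero_tpm_fraction must be in [0, 1)")
        if self.mean_coverage <= 0:
            raise ConfigError("mean_coverage must be positive")
        return self

    def sample_ids(self) -> list:
        return [
            f"y{age}_r{rep}"
            for age in self.ages
            for rep in range(1, self.replicates_per_age + 1)
        ]


@dataclass
class PipelineConfig:
    """Analysis parameters for the methylome pipeline."""

    coverage_min: int = 4
    bin_size_dmr: int = 1000
    bin_size_corr: int = 5000
    flank_bp: int = 2000
    n_body_bins: int = 20
    n_flank_bins: int = 20
    intron_bins: int = 10
    exon_bins: int = 5
    chrom_track_bin: int = 20_000_000
    dmr_p_adj_max: float = 0.01
    dmr_diff_min: dict = field(
        default_factory=lambda: {"CG": 0.2, "CHG": 0.15, "CHH": 0.1}
    )
    expression_breaks: tuple = (0.0, 1.0, 10.0, 50.0)
    group_test_alpha: float = 0.01
    min_consensus_comparisons: int = 2
    intron_length_breaks: tuple = (1000, 5000, 20000)
    intron_count_breaks: tuple = (0, 2, 5)
    merge_cg_strands: bool = False
    mc_call_alpha: float = 0.05
    site_mean_bins: bool = False  # per-bin level as mean of site ratios instead of count-weighted
    stem_max_unit_change: int = 1
    stem_permutations: int = 1000

    def validate(self) -> "PipelineConfig":
        if self.coverage_min < 1:
            raise ConfigError("coverage_min must be >= 1")
        for name in ("bin_size_dmr", "bin_size_corr", "flank_bp", "n_body_bins",
                     "n_flank_bins", "intron_bins", "exon_bins", "chrom_track_bin"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0.0 < self.dmr_p_adj_max <= 1.0:
            raise ConfigError("dmr_p_adj_max must be in (0, 1]")
        for ctx in CONTEXTS:
            d = self.dmr_diff_min.get(ctx)
            if d is None or not 0.0 < d <= 1.0:
                raise ConfigError(f"dmr_diff_min[{ctx}] must be in (0, 1]")
        if self.min_consensus_comparisons < 1:
            raise ConfigError("min_consensus_comparisons must be >= 1")
        return self


def to_yaml(cfg, path=None) -> str:
    """Serialize a config dataclass to YAML (string, optionally to *path*)."""
    text = yaml.safe_dump(_jsonable(asdict(cfg)), sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def from_yaml(cls, source):
    """Load a config dataclass from a YAML path or string, with defaulting."""
    try:
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    except (OSError, TypeError):
        data = yaml.safe_load(source) or {}
    known = {f for f in cls.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    data = {k: _detuple(cls, k, v) for k, v in data.items()}
    return cls(**data).validate()


def _detuple(cls, key, value):
    default = cls.__dataclass_fields__[key].default
    if isinstance(value, list):
        return tuple(value)
    if key == "n_planted_age_dmrs" and isinstance(value, dict):
        # YAML cannot key on tuples; accept "CHG:hyper" style keys
        return {tuple(k.split(":")): v for k, v in value.items()}
    return value


def _jsonable(obj):
    if isinstance(obj, dict):
        return {
            (":".join(k) if isinstance(k, tuple) else k): _jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, tuple):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, list):
        return [_jsonable(v) for v in obj]
    return obj


def config_hash(cfg) -> str:
    """Stable short hash of a config, for run logs."""
    payload = json.dumps(_jsonable(asdict(cfg)), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def with_overrides(cfg, **kwargs):
    """Return a copy of *cfg* with fields replaced and re-validated."""
    return replace(cfg, **kwargs).validate()
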