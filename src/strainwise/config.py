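"""Pipeline configuration: every numeric threshold used by any analysis stage.

All stages read their thresholds from a :class:`PipelineConfig` instance so a
single object documents — and lets the user override — the complete parameter
surface of the pipeline.  The on-disk format is YAML (flat key: value mapping).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import yaml

__all__ = ["PipelineConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Raised for malformed config files or invariant violations."""


@dataclass
class PipelineConfig:
    """Numeric constants for the strain-pair enhancer pipeline.

    Fold-change thresholds are plain ratios (not log scaled); windows and
    distances are base pairs.
    """

    # --- responsive-element calling ---
    induce_fc: float = 2.5          # min fold change (both markers) for induced/repressed
    neutral_fc: float = 1.4         # both markers below this ratio -> neutral
    min_h3k27ac: float = 16.0       # min normalized H3K27ac tags (max over conditions)
    min_polii: float = 8.0          # min normalized RNA Pol II tags
    # --- strain-differential categorization ---
    gene_basal_fc: float = 1.5      # basal-expression ratio splitting low/equal/high
    enhancer_basal_fc: float = 2.0  # basal H3K27ac ratio splitting low/equal/high
    gene_induce_fc: float = 2.0     # gene induction threshold (with q gate)
    similar_fc: float = 1.5         # strain-similar enhancer bound
    differential_tiers: list = field(default_factory=lambda: [1.5, 2.0, 3.0, 4.0])
    # --- windows / distances ---
    variant_window_bp: int = 150    # half-width around element center for variant search
    signal_window_bp: int = 500     # half-width for histone / Pol II quantification
    tf_window_bp: int = 150         # half-width for TF quantification
    merge_dist_bp: int = 2500       # interval merge distance for interaction overlap
    tss_exclusion_bp: int = 2500    # super-enhancer TSS signal exclusion
    stitch_dist_bp: int = 12500     # super-enhancer stitching distance
    promoter_window_bp: int = 1000  # TSS distance defining promoters
    # --- sequence model ---
    seq_len_bp: int = 300           # model input length
    top_frac: float = 0.20          # functional-position quantile
    kmer_k: int = 5                 # interpretation k-mer size
    kmer_top_frac: float = 0.10     # score quantile for k-mer counting
    lr_init: float = 3e-4           # initial learning rate (from-scratch training)
    lr_factor: float = 0.9          # LR reduction factor on stagnation
    patience_epochs: int = 20       # early-stop patience (training loss)
    stagnation_epochs: int = 5      # stagnant epochs before an LR cut
    max_epochs: int = 80            # hard cap on training epochs
    batch_size: int = 64
    conv_channels: list = field(default_factory=lambda: [16, 16, 16])
    conv_widths: list = field(default_factory=lambda: [12, 4, 4])
    pool_widths: list = field(default_factory=lambda: [2, 1, 138])
    fc_units: int = 16
    gc_tol: float = 0.02            # GC-content matching tolerance for backgrounds
    bg_search_bp: int = 100_000     # background search half-range around foreground
    # --- motif mutation ---
    motif_cluster_corr: float = 0.6  # clustering threshold on score-diff correlation
    expr_filter_tpm: float = 2.0     # motif expression filter
    # --- cis / trans ---
    cis_window_log2: float = 1.0     # |log2 parental - log2 F1| window for cis
    parental_fc_min: float = 2.0     # parental fold-change gate for trans eligibility
    # --- connectivity ---
    corr_pair_fc: float = 4.0        # between-strain fold-change preselection for E-E pairs
    null_distance_bin_bp: int = 100_000  # distance-matched null binning
    # --- misc ---
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("induce_fc", "neutral_fc", "gene_basal_fc", "enhancer_basal_fc",
                     "gene_induce_fc", "similar_fc", "parental_fc_min", "corr_pair_fc"):
            if not getattr(self, name) > 1:
                raise ConfigError(f"{name} must be > 1, got {getattr(self, name)}")
        for t in self.differential_tiers:
            if not t > 1:
                raise ConfigError(f"differential_tiers entries must be > 1, got {t}")
        for name in ("top_frac", "kmer_top_frac"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        for name in ("variant_window_bp", "signal_window_bp", "tf_window_bp",
                     "merge_dist_bp", "tss_exclusion_bp", "stitch_dist_bp",
                     "promoter_window_bp", "seq_len_bp", "null_distance_bin_bp",
                     "bg_search_bp"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if not self.neutral_fc < self.induce_fc:
            raise ConfigError(
                f"neutral_fc ({self.neutral_fc}) must be < induce_fc ({self.induce_fc})")
        if not 0 < self.lr_factor < 1:
            raise ConfigError(f"lr_factor must be in (0, 1), got {self.lr_factor}")
        if self.lr_init <= 0:
            raise ConfigError(f"lr_init must be positive, got {self.lr_init}")

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def replace(self, **kwargs: Any) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def config_hash(self) -> str:
        """Stable short hash of the full parameter set, for provenance headers."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


_FIELD_NAMES = {f.name for f in dataclasses.fields(PipelineConfig)}


def load_config(path: str | Path | None = None,
                overrides: dict[str, Any] | None = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from defaults, a YAML file, and overrides.

    Precedence: overrides (e.g. CLI flags) > file values > defaults.  Unknown
    keys are rejected so typos never silently fall back to defaults.
    """
    values: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            loaded = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            line = f" at line {mark.line + 1}" if mark is not None else ""
            raise ConfigError(f"malformed config file {path}{line}: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must be a key: value mapping")
        values.update(loaded)
    if overrides:
        values.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(values) - _FIELD_NAMES
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**values)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
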