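"""Run configuration: a flat key-value file (YAML) with CLI overrides.

Every stage's tunables live in one :class:`PipelineConfig`; defaults are
the pipeline's published operating point (FastICA tolerance 1e-7, K²
cutoff 550, enrichment FDR 1e-5, correlation p 0.05).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    # --- input paths (all optional when simulating) ---
    expression_path: str | None = None
    metadata_path: str | None = None
    regulons_path: str | None = None
    pathways_path: str | None = None
    genome_fasta: str | None = None
    genome_gff: str | None = None
    promoter_scores_path: str | None = None
    output_dir: str = "modulome_out"

    # --- synthetic simulation (used when no expression_path is given) ---
    simulate: bool = True
    n_genes: int = 1000
    n_samples: int = 50
    n_modules: int = 5
    module_size_min: int = 8
    module_size_max: int = 15
    n_replicate_groups: int = 25
    replicates_per_group: int = 2
    noise_sd: float = 0.1
    activity_sd: float = 1.0
    weight_magnitude: float = 1.0
    regulon_jitter: float = 0.2

    # --- preprocessing ---
    pseudocount: float = 1.0
    reference_group: str | None = None  # None: use metadata is_reference flags

    # --- ICA ---
    dimension: int | None = None  # fixed k; None -> OptICA over candidates
    optica_candidates: tuple = (2, 5, 10, 20)
    n_restarts: int = 20
    tolerance: float = 1e-7
    max_iter: int = 1000
    cluster_eps: float = 0.2
    single_gene_dominance: float = 0.7
    base_seed: int = 0

    # --- extraction ---
    k2_cutoff: float = 550.0

    # --- annotation ---
    annotate: bool = True
    fdr_cutoff: float = 1e-5
    tf_p_cutoff: float = 0.05
    intersection_dominance: float = 0.6
    promoter_score_cutoff: float = 0.8

    # --- activity analysis ---
    network_p_cutoff: float = 0.05
    top_k_active: int = 4
    contrast: tuple | None = None  # (condition, reference condition)

    def validate(self) -> None:
        for name in ("pseudocount", "tolerance", "k2_cutoff", "fdr_cutoff",
                     "tf_p_cutoff", "network_p_cutoff", "cluster_eps"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.dimension is None and not self.optica_candidates:
            raise ConfigError("either dimension or optica_candidates must be set")
        if self.expression_path is not None:
            for name in ("expression_path", "metadata_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ConfigError(f"{name} missing or does not exist: {p}")
            if self.annotate and (
                self.regulons_path is None or not Path(self.regulons_path).exists()
            ):
                raise ConfigError(
                    "annotation enabled but regulons_path is missing or does not exist"
                )
        for name in ("pathways_path", "genome_fasta", "genome_gff", "promoter_scores_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path, overrides: dict | None = None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must be a flat key-value mapping")
        raw.update(overrides or {})
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("optica_candidates", "contrast"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("optica_candidates", "contrast"):
            if isinstance(d[key], tuple):
                d[key] = list(d[key])
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
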