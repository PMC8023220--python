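"""Run configuration shared by every pipeline stage.

A single :class:`RunConfig` carries all decision thresholds so that no stage
can drift from another: the fold-change cutoff, the significance level, the
expression floor, the codon-window width used for peak segment assignment,
and the clustering parameters.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

VALID_MULTIPLE_TESTING = ("bh_fdr", "raw_p")


@dataclasses.dataclass
class RunConfig:
    """Thresholds and tuning parameters for a full run.

    Parameters
    ----------
    fc_threshold:
        Minimum fold change (linear scale, >= 1) for a gene to be called
        differential. Applied as ``|log2fc| >= log2(fc_threshold)``.
    alpha:
        Significance level applied to adjusted (or raw) p-values.
    fpkm_min:
        Expression floor: a gene counts as expressed in a (genotype, assay)
        group when its mean replicate FPKM reaches this value.
    window_nt:
        Width (nt, even) of the windows centered on the start and stop codons
        used during peak segment assignment.
    k_clusters:
        Number of k-means clusters for the multi-layer integration.
    rng_seed:
        Seed for every stochastic step (k-means restarts, permutations).
    multiple_testing:
        ``"bh_fdr"`` adjusts p-values by Benjamini-Hochberg before applying
        ``alpha``; ``"raw_p"`` applies ``alpha`` to unadjusted p-values.
    """

    fc_threshold: float = 1.5
    alpha: float = 0.01
    fpkm_min: float = 1.0
    window_nt: int = 200
    k_clusters: int = 8
    rng_seed: int = 17
    multiple_testing: str = "bh_fdr"

    def __post_init__(self) -> None:
        if self.fc_threshold < 1:
            raise ValueError(f"fc_threshold must be >= 1, got {self.fc_threshold}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.fpkm_min < 0:
            raise ValueError(f"fpkm_min must be >= 0, got {self.fpkm_min}")
        if self.window_nt % 2 != 0 or self.window_nt < 0:
            raise ValueError(f"window_nt must be a non-negative even integer, got {self.window_nt}")
        if self.k_clusters < 1:
            raise ValueError(f"k_clusters must be >= 1, got {self.k_clusters}")
        if self.multiple_testing not in VALID_MULTIPLE_TESTING:
            raise ValueError(
                f"multiple_testing must be one of {VALID_MULTIPLE_TESTING}, "
                f"got {self.multiple_testing!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config from a YAML key/value file; kwargs override file values."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
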