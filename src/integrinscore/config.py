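"""Run configuration: every filter threshold used by the pipeline, with defaults.

The defaults encode the published screening rules: promoter-methylation pairs kept at
|rho| >= 0.15 and p < 0.05; miRNA pairs at |rho| >= 0.3 and p < 0.05 in more than five
cancer types, after dropping miRNAs not expressed above 1 in more than 500 samples;
TF-target pairs at |rho| >= 0.2 and p < 0.01; DEGs at |FC| >= 2 and BH-FDR < 0.05;
GSEA significance at FDR < 0.1; drug IC50 correlations at |rho| >= 0.1 and p < 0.05;
CMap-style compounds at |enrichment score| > 95 in at least ten cancer types; survival
significance at p < 0.05. Magnitude thresholds are inclusive (>=), p-value thresholds
strict (<), and count thresholds strict (> "more than").
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

logger = logging.getLogger("integrinscore")

__all__ = ["RunConfig", "ConfigError", "load_config", "resolve_config"]


class ConfigError(ValueError):
    """Raised for unknown keys or out-of-range thresholds in a run configuration."""


@dataclass
class RunConfig:
    """Resolved pipeline configuration.

    ``endpoint_map`` assigns OS or PFS per cancer type; cancers absent from the map
    use ``endpoint_default``.  ``minprop`` is the minimum fraction of samples allowed
    on either side of an optimal cutpoint; ``n_perm_cutpoint`` the number of label
    permutations used for the maximally-selected-rank-statistic p-value.
    """

    seed: int = 0
    endpoint_default: str = "OS"
    endpoint_map: dict[str, str] = field(default_factory=dict)
    survival_alpha: float = 0.05
    minprop: float = 0.1
    n_perm_cutpoint: int = 1000
    # methylation screen
    meth_rho: float = 0.15
    meth_p: float = 0.05
    # miRNA cascade
    mirna_rho: float = 0.3
    mirna_p: float = 0.05
    mirna_min_cancers: int = 5  # strict: significant in MORE than this many cancers
    mirna_expr_threshold: float = 1.0
    mirna_min_samples: int = 500  # strict: expressed above threshold in MORE than this
    # TF screen
    tf_rho: float = 0.2
    tf_p: float = 0.01
    tf_top_n: int = 10
    # DEG ranking
    deg_abs_log2fc: float = 1.0
    deg_fdr: float = 0.05
    deg_pseudocount: float = 1.0
    # GSEA
    gsea_fdr: float = 0.1
    gsea_weight: float = 1.0
    gsea_n_perm: int = 1000
    gsea_min_size: int = 5
    # drug / compound selection
    drug_rho: float = 0.1
    drug_p: float = 0.05
    cmap_threshold: float = 95.0
    cmap_min_cancers: int = 10

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        if self.endpoint_default not in ("OS", "PFS"):
            raise ConfigError(
                f"endpoint_default must be 'OS' or 'PFS', got {self.endpoint_default!r}"
            )
        for cancer, ep in self.endpoint_map.items():
            if ep not in ("OS", "PFS"):
                raise ConfigError(f"endpoint for {cancer!r} must be 'OS' or 'PFS', got {ep!r}")
        if not isinstance(self.seed, int) or isinstance(self.seed, bool):
            raise ConfigError("seed must be a fixed integer")
        unit = {
            "survival_alpha": self.survival_alpha,
            "meth_p": self.meth_p,
            "mirna_p": self.mirna_p,
            "tf_p": self.tf_p,
            "deg_fdr": self.deg_fdr,
            "gsea_fdr": self.gsea_fdr,
            "drug_p": self.drug_p,
            "meth_rho": self.meth_rho,
            "mirna_rho": self.mirna_rho,
            "tf_rho": self.tf_rho,
            "drug_rho": self.drug_rho,
        }
        for name, value in unit.items():
            if not 0 < value <= 1:
                raise ConfigError(f"{name} must lie in (0, 1], got {value}")
        if not 0 < self.minprop <= 0.5:
            raise ConfigError(f"minprop must lie in (0, 0.5], got {self.minprop}")
        for name in ("n_perm_cutpoint", "gsea_n_perm"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")

    def endpoint_for(self, cancer: str) -> str:
        return self.endpoint_map.get(cancer, self.endpoint_default)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        """Canonical YAML echo of the resolved config; stable byte-for-byte."""
        return yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)

    def digest(self) -> str:
        """SHA-256 hash of the canonical YAML echo, for run manifests."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()


_VALID_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


def resolve_config(overrides: dict[str, Any] | None) -> RunConfig:
    """Merge a (possibly partial) mapping of overrides onto the defaults."""
    overrides = dict(overrides or {})
    unknown = sorted(set(overrides) - _VALID_KEYS)
    if unknown:
        raise ConfigError(
            f"unknown config key(s) {unknown}; valid keys: {sorted(_VALID_KEYS)}"
        )
    cfg = RunConfig(**overrides)
    logger.info("resolved run config:\n%s", cfg.to_yaml())
    return cfg


def load_config(path: str | Path | io.TextIOBase) -> RunConfig:
    """Load a YAML config file, filling missing keys with the published defaults."""
    if isinstance(path, (str, Path)):
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = yaml.safe_load(path)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping at the top level")
    return resolve_config(raw)
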