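"""Analysis configuration shared by the CLI stages.

Every threshold the pipeline applies lives here, is validated against the
domains the individual modules define, and is serialized into the metadata
header of every output file together with a short fingerprint so that stage
outputs from different configurations cannot be silently mixed.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields

import yaml

from .diffexpr import FilterSpec

__all__ = ["AnalysisConfig"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds, modes and the seed of one analysis run."""

    gene_p_threshold: float = 0.01
    gene_use_adjusted: bool = True
    gene_fc_threshold: float = 1.0
    mirna_p_threshold: float = 0.001
    mirna_use_adjusted: bool = False
    mirna_fc_threshold: float = 1.5
    min_algorithms: int = 2
    min_hub: int = 15
    alpha_enrichment: float = 0.05
    sided: str = "greater"          # the implemented overrepresentation test
    universe_mode: str = "annotation"  # "annotation" | "measured"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.gene_filter()   # validates thresholds via FilterSpec
        self.mirna_filter()
        if self.min_algorithms < 1:
            raise ValueError("min_algorithms must be >= 1")
        if self.min_hub < 1:
            raise ValueError("min_hub must be >= 1")
        if not (0 < self.alpha_enrichment < 1):
            raise ValueError("alpha_enrichment must lie in (0, 1)")
        if self.sided != "greater":
            raise ValueError("only the one-sided (greater) test is provided")
        if self.universe_mode not in ("annotation", "measured"):
            raise ValueError("universe_mode must be 'annotation' or 'measured'")

    def gene_filter(self) -> FilterSpec:
        return FilterSpec(
            kind="gene",
            p_threshold=self.gene_p_threshold,
            use_adjusted=self.gene_use_adjusted,
            fc_threshold=self.gene_fc_threshold,
        )

    def mirna_filter(self) -> FilterSpec:
        return FilterSpec(
            kind="mirna",
            p_threshold=self.mirna_p_threshold,
            use_adjusted=self.mirna_use_adjusted,
            fc_threshold=self.mirna_fc_threshold,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def fingerprint(self) -> str:
        """Short stable hash of the configuration (seed included)."""
        text = ";".join(f"{k}={v}" for k, v in sorted(self.to_dict().items()))
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    def metadata(self) -> dict:
        meta = {"config": self.fingerprint()}
        if self.seed is not None:
            meta["seed"] = self.seed
        return meta

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown config key(s): {unknown}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
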