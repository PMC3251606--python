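"""Run configuration shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Tunable thresholds of the mining pipeline.

    tm_min/tm_max
        Accepted transmembrane-segment count, inclusive at both bounds
        (the canonical receptor has 7; partial gene models fall below 6).
    redundancy_threshold
        Within-proteome identity above which near-duplicates collapse.
    domain_evalue_cutoff
        E-value cutoff for N-terminal domain annotation.
    nutrient_evalue_cutoff
        Strict cutoff honoured for the custom nutrient-receptor profile.
    scatter_ambiguity_delta
        |log10 E_a - log10 E_b| below which a dual-model comparison is
        flagged ambiguous.
    conservation_threshold
        Column conservation fraction (inclusive >=) for the conserved
        residue report.
    report_cutoff
        E-value reporting threshold for the domain scan.
    random_seed
        Master seed for every stochastic stage.
    tm_whitelist
        Ids exempted from the TM-count filter (manual inclusions).
    """

    tm_min: int = 6
    tm_max: int = 9
    redundancy_threshold: float = 0.90
    domain_evalue_cutoff: float = 0.01
    nutrient_evalue_cutoff: float = 1e-25
    scatter_ambiguity_delta: float = 1.0
    conservation_threshold: float = 0.90
    report_cutoff: float = 10.0
    random_seed: int = 0
    tm_whitelist: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (0 < self.redundancy_threshold <= 1):
            raise ValueError("redundancy_threshold must be in (0, 1]")
        if self.tm_min > self.tm_max:
            raise ValueError("tm_min must be <= tm_max")
        for name in ("domain_evalue_cutoff", "nutrient_evalue_cutoff",
                     "scatter_ambiguity_delta", "report_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 < self.conservation_threshold <= 1):
            raise ValueError("conservation_threshold must be in (0, 1]")
        self.tm_whitelist = tuple(self.tm_whitelist)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["tm_whitelist"] = list(self.tm_whitelist)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
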