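"""Central analysis configuration.

Every numeric threshold used by the pipeline lives in one dataclass so that a
single YAML file reproduces a full run.  Defaults are the conventional values
for FastOrtho-style orthology clustering and ECM symbiosis expression studies:
50% identity / 50% coverage protein-graph edges, MCL inflation 3.0, SSPs
defined as secreted proteins shorter than 300 aa, 4.5 kb "close proximity"
to a repeat, 10,000 permutations for the reshuffled-genome null, and the
|log2FC| > 1 / FDR < 0.05 differential-expression call.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """All numeric thresholds of the pipeline in one place.

    Attributes
    ----------
    min_identity, min_coverage:
        Protein-similarity graph edge thresholds (fractions in [0, 1]).
    mcl_inflation:
        Inflation exponent of Markov clustering; larger values give
        finer-grained orthogroups.
    ssp_max_len:
        Exclusive upper bound on protein length (aa) for the SSP class:
        a secreted protein of 299 aa is an SSP, one of 300 aa is not.
    close_proximity:
        A gene whose nearest repeat lies within this many bp is in
        "close proximity" to the repeat landscape.
    n_permutations, alpha:
        Number of reshuffled genome models for the proximity null and the
        significance level.
    lfc_threshold, fdr_threshold:
        Differential-expression call thresholds (log2 units; BH-adjusted p).
    scaffold_pair_coverage, scaffold_pair_identity:
        Nucleotide-level thresholds above which two scaffolds are treated as
        an allelic pair (the longer one is the primary scaffold).
    expression_floor:
        Normalized mean count a gene must reach in at least one condition to
        be counted as "expressed".
    seed:
        Master seed for every stochastic stage.
    """

    min_identity: float = 0.50
    min_coverage: float = 0.50
    mcl_inflation: float = 3.0
    ssp_max_len: int = 300
    close_proximity: int = 4_500
    n_permutations: int = 10_000
    alpha: float = 0.05
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    scaffold_pair_coverage: float = 0.50
    scaffold_pair_identity: float = 0.90
    expression_floor: float = 5.0
    primary_scaffolds_only: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_identity",
            "min_coverage",
            "alpha",
            "fdr_threshold",
            "scaffold_pair_coverage",
            "scaffold_pair_identity",
        ):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in (
            "mcl_inflation",
            "ssp_max_len",
            "close_proximity",
            "n_permutations",
            "lfc_threshold",
            "expression_floor",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
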