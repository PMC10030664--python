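"""Run configuration shared across pipeline stages.

Defaults mirror the analysis settings of the study this pipeline
operationalises: STRING-style confidence cutoff 0.9, permutation tests of
1,000 repetitions, proximity significance at Z < -1.5 and FDR < 0.05,
differential local-entropy filter |median shift| > 0.03 nats, and MCODE
cluster-score filter >= 5.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml


@dataclasses.dataclass
class RunConfig:
    """Thresholds and sampling settings for a pipeline run.

    Attributes
    ----------
    confidence_cutoff:
        Minimum edge confidence score kept when reading a scaffold, in [0, 1].
    n_permutations:
        Number of degree-matched resamples for the proximity null.
    z_threshold:
        Proximity Z-score below which a pair is a significance candidate.
    fdr_threshold:
        Benjamini-Hochberg q-value cutoff (proximity and differential entropy).
    median_shift_threshold:
        Minimum absolute young-vs-old shift in per-node local entropy (nats)
        for a node to be called differential.
    diff_statistic:
        Location statistic for the differential-entropy shift filter:
        ``"median"`` (default) or ``"mean"``.
    mcode_score_min:
        Minimum MCODE cluster score (density x size) reported.
    rng_seed:
        Seed for every stochastic step.
    """

    confidence_cutoff: float = 0.9
    n_permutations: int = 1000
    z_threshold: float = -1.5
    fdr_threshold: float = 0.05
    median_shift_threshold: float = 0.03
    diff_statistic: str = "median"
    mcode_score_min: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence_cutoff <= 1.0:
            raise ValueError(
                f"confidence_cutoff must be in [0, 1], got {self.confidence_cutoff}"
            )
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be a positive integer")
        if not 0.0 < self.fdr_threshold <= 1.0:
            raise ValueError("fdr_threshold must be in (0, 1]")
        if self.median_shift_threshold < 0.0:
            raise ValueError("median_shift_threshold must be non-negative")
        if self.diff_statistic not in ("median", "mean"):
            raise ValueError("diff_statistic must be 'median' or 'mean'")
        if self.mcode_score_min < 0.0:
            raise ValueError("mcode_score_min must be non-negative")
        self.rng_seed = int(self.rng_seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a config from a YAML mapping; absent keys keep defaults."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a YAML mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# MCODE algorithm parameters (the published defaults the analysis invokes).
MCODE_DEGREE_CUTOFF = 2
MCODE_NODE_SCORE_CUTOFF = 0.2
MCODE_K_CORE = 2
MCODE_MAX_DEPTH = 100
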