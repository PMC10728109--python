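"""Pipeline configuration: one dataclass, YAML-loadable, validated."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Tunable parameters of the full pipeline.

    epsilon defaults to the staged convention (0.6); time-series analyses
    conventionally use 2.3.  ``mk_form`` switches the class-size factor of
    the statistic between sqrt(1/n + 1/n_k) ("as_printed", default) and the
    classical nearest-shrunken-centroid sqrt(1/n_k - 1/n).
    """

    epsilon: float = 0.6
    top_k_hubs: int = 5
    alpha: float = 0.05
    mk_form: str = "as_printed"
    test_variant: str = "welch"
    min_significant_other_stages: int = 2
    trajectory_rule: str = "strict_monotone"
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.top_k_hubs < 1:
            raise ValueError("top_k_hubs must be >= 1")
        if self.mk_form not in ("as_printed", "classical"):
            raise ValueError("mk_form must be 'as_printed' or 'classical'")
        if self.test_variant not in ("welch", "student"):
            raise ValueError("test_variant must be 'welch' or 'student'")
        if self.trajectory_rule not in ("strict_monotone", "onset_persistent"):
            raise ValueError("trajectory_rule must be 'strict_monotone' or 'onset_persistent'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__ and k != "extra"}
        extra = {k: v for k, v in data.items() if k not in cls.__dataclass_fields__}
        return cls(**known, extra=extra)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
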