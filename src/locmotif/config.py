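"""Run configuration shared by the detection pipeline and the CLI."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml


@dataclass(frozen=True)
class RunConfig:
    """Resolved settings for one motif-detection run.

    ``Q`` and ``M`` may be fixed numbers or ``"estimate"``, in which case the
    mixing parameter is calibrated on a representative network and the
    ensemble size by bootstrap frequency convergence.  Defaults follow the
    EEG application geometry: subnetwork size 3, candidate threshold 4
    occurrences within a sample, familywise level 0.05.
    """

    k: int = 3
    min_count: Optional[int] = None  # None -> 4 for k >= 3, 1 for k == 2
    alpha: float = 0.05
    Q: Union[float, str] = "estimate"
    M: Union[int, str] = "estimate"
    Q_grid: tuple[float, ...] = (1, 3, 10, 30, 100, 300)
    n_per_q: int = 1000
    mc_reps: int = 10000
    B_grid: tuple[int, ...] = (100, 250, 500)
    B_max: int = 1000
    epsilon: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must be in [0, 1)")
        if isinstance(self.Q, str) and self.Q != "estimate":
            raise ValueError("Q must be a number or 'estimate'")
        if isinstance(self.M, str) and self.M != "estimate":
            raise ValueError("M must be an integer or 'estimate'")
        if self.min_count is not None and self.min_count < 1:
            raise ValueError("min_count must be >= 1")

    @property
    def resolved_min_count(self) -> int:
        if self.min_count is not None:
            return self.min_count
        return 4 if self.k >= 3 else 1

    def to_dict(self) -> dict:
        d = asdict(self)
        d["Q_grid"] = list(self.Q_grid)
        d["B_grid"] = list(self.B_grid)
        d["resolved_min_count"] = self.resolved_min_count
        return d

    @classmethod
    def from_yaml(cls, path: Path | str, **overrides) -> "RunConfig":
        """Load a config file, then apply overrides (e.g. from CLI flags)."""
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("Q_grid", "B_grid"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)
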