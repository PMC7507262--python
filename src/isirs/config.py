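"""Run configuration with documented defaults; echoed to JSON for reruns."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .datatypes import ValidationError
from .selection import SelectionConfig


@dataclass
class RunConfig:
    """Fully resolved settings of one CLI run.

    Defaults: d=20 (or the grid {2,4,...,50} for tuning), 10 folds, 1 repeat
    (10 for d tuning), lasso penalty by internal 5-fold CV, 10 MI bins, SIRS
    screening, 50-iteration cap, constant features rejected unless
    ``drop_constant_features`` is set.
    """

    d: int = 20
    d_grid: list[int] = field(default_factory=lambda: list(range(2, 51, 2)))
    folds: int = 10
    repeats: int = 1
    seed: int = 0
    lambda_policy: dict = field(default_factory=lambda: {"cv": 5})
    mi_bins: int = 10
    screening_method: str = "sirs"
    iteration_cap: int = 50
    drop_constant_features: bool = False
    output_dir: str = "isirs_output"

    def __post_init__(self) -> None:
        if self.d < 2:
            raise ValidationError("d must be >= 2")
        if self.folds < 2:
            raise ValidationError("folds must be >= 2")
        if self.repeats < 1:
            raise ValidationError("repeats must be >= 1")
        if self.mi_bins < 2:
            raise ValidationError("mi_bins must be >= 2")

    def selection_config(self) -> SelectionConfig:
        return SelectionConfig(
            lambda_policy=dict(self.lambda_policy),
            max_iterations=self.iteration_cap,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def echo(self, output_dir: str | Path) -> Path:
        """Write the resolved config next to the results, for reproducibility."""
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "config.json"
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))
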