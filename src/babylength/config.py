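"""Run configuration: YAML round-trip and reproducibility manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .flags import WarningConfig
from .model import ModelConfig
from .synthetic import GeneratorConfig


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serialisable round-trip stable."""

    seed: int = 0
    n_participants: int = 20
    images_per_participant: int = 6
    defect_rates: dict[str, float] = field(default_factory=dict)
    landmark_noise_sigma_px: float = 2.0
    k_folds: int = 5
    hpo_budget: int = 0  # 0 = skip HPO, use the default model config
    min_images_for_average: int = 9
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    warnings: WarningConfig = field(default_factory=WarningConfig)
    model: ModelConfig = field(default_factory=ModelConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        for key, sub in (
            ("generator", GeneratorConfig),
            ("warnings", WarningConfig),
            ("model", ModelConfig),
        ):
            if key in data and isinstance(data[key], dict):
                kwargs = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in data[key].items()
                }
                data[key] = sub(**kwargs)
        return cls(**data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def write_manifest(path: str | Path, config: RunConfig, command: str) -> None:
    """Record seed, config hash and versions next to a run's outputs."""
    import numpy
    import sklearn

    manifest = {
        "command": command,
        "seed": config.seed,
        "config_digest": config.digest(),
        "config": config.to_dict(),
        "versions": {
            "python": platform.python_version(),
            "numpy": numpy.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
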