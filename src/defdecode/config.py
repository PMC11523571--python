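"""Schema-validated pipeline configuration (YAML-backed)."""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FilterConfig(_Strict):
    band_low_hz: float = 1.0
    band_high_hz: float = 150.0
    order: int = 3
    line_freq_hz: float = 60.0
    notch_q: float = 30.0


class WindowConfig(_Strict):
    length_s: float = 1.0
    step_s: float = 0.2


class ArtifactConfig(_Strict):
    enabled: bool = False
    z_thresh: float = 8.0
    pad_s: float = 0.5


class FeatureToggles(_Strict):
    families: list[str] | None = None  # None = all 17
    symmetric_combinations: bool = False
    entropy_m: int = 2
    entropy_r_factor: float = 0.2
    lag_steps: list[int] = Field(default_factory=lambda: [0])


class SplitConfig(_Strict):
    test_fraction: float = 0.2
    purge_gap_windows: int = 0


class DecoderConfig(_Strict):
    n_estimators: int = 500
    learning_rate: float = 0.05
    num_leaves: int = 31
    min_child_samples: int = 20
    early_stopping_rounds: int = 50
    num_threads: int = 1

    def to_params(self) -> dict:
        return self.model_dump()


class SelectionConfig(_Strict):
    enabled: bool = True
    sizes: list[int] | None = None  # None = the default evaluation grid
    alpha: float = 0.05
    shap_on: Literal["val", "train", "all"] = "val"


class PipelineConfig(_Strict):
    """Resolved configuration for one decoding run."""

    bundle: str | None = None
    events: str | None = None
    freezing: str | None = None
    simulate: bool = False
    duration_s: float = 600.0
    behavior: Literal["jerk", "press_rate", "freezing"] = "jerk"
    seed: int = 0
    bands: list[tuple[str, float, float]] | None = None
    filter: FilterConfig = Field(default_factory=FilterConfig)
    window: WindowConfig = Field(default_factory=WindowConfig)
    artifacts: ArtifactConfig = Field(default_factory=ArtifactConfig)
    features: FeatureToggles = Field(default_factory=FeatureToggles)
    split: SplitConfig = Field(default_factory=SplitConfig)
    decoder: DecoderConfig = Field(default_factory=DecoderConfig)
    selection: SelectionConfig = Field(default_factory=SelectionConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        return cls.model_validate(yaml.safe_load(text) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(), sort_keys=True))
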