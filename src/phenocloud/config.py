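"""Strictly validated pipeline configuration (JSON-friendly)."""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["PipelineConfig"]


class PipelineConfig(BaseModel):
    """Every knob of the simplify -> denoise -> traits chain.

    Unknown keys are rejected so a typo in a config file fails before any
    I/O happens.
    """

    model_config = ConfigDict(extra="forbid")

    knn: int = Field(default=15, ge=1)
    gamma: float = Field(default=0.1, gt=0)
    beta_detail: float = Field(default=1.0, gt=0)
    beta_nondetail: float = Field(default=2.0, gt=0)

    denoise_method: str = Field(default="bilateral",
                                pattern="^(bilateral|laplace|none)$")
    denoise_iterations: int = Field(default=1, ge=1)
    laplace_lambda: float = Field(default=0.5, gt=0, le=1)

    vertical_axis: str = Field(default="y", pattern="^[xyz]$")
    breadth_axis: str = Field(default="x", pattern="^[xyz]$")
    stem_window: tuple[float, float] | None = None
    apex_quantile: float = Field(default=1.0, gt=0, le=1)
    base_search_radius: float = Field(default=30.0, gt=0)
    height_tolerance: float = Field(default=10.0, gt=0)
    r_gate_factor: float = Field(default=3.0, gt=0)

    skip_simplify: bool = False
    skip_denoise: bool = False
    seed: int = 0
    verbosity: int = Field(default=1, ge=0, le=2)

    @model_validator(mode="after")
    def _check(self):
        if self.beta_detail >= self.beta_nondetail:
            raise ValueError("beta_detail must be < beta_nondetail")
        if self.vertical_axis == self.breadth_axis:
            raise ValueError("vertical and breadth axes must differ")
        if self.stem_window is not None and not (
                self.stem_window[0] < self.stem_window[1]):
            raise ValueError("stem_window must satisfy low < high")
        return self
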