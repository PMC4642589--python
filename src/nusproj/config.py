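"""Validated run configuration (JSON in, unknown keys rejected)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, model_validator

from .acquisition import (ExperimentGeometry, geometry_600_6d, geometry_800_6d,
                          geometry_800_7d)
from .spin_model import default_axes
from .transfer import DEFAULT_DELTA_NCA

__all__ = ["RunConfig", "GeometryConfig", "PRESETS"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    """Evolution times (s) and bandwidths (Hz) of one experiment."""

    dimensionality: Literal[5, 6, 7] = 6
    t1max_n: float = 0.030
    t2max_co: float = 0.025
    t3max_co: float = 0.025
    t4max_n: float = 0.030
    t5max_h: float | None = 0.020
    t6max_ca: float | None = None
    sw_n: float = 2000.0
    sw_co: float = 1500.0
    sw_hn: float = 1600.0
    sw_ca: float = 4800.0
    direct_points: int = 128
    direct_sw: float = 1600.0

    @model_validator(mode="after")
    def _check_coevolved(self) -> "GeometryConfig":
        if self.dimensionality >= 6 and not self.t5max_h:
            raise ValueError("6D/7D geometry requires t5max_h")
        if self.dimensionality == 7 and not self.t6max_ca:
            raise ValueError("7D geometry requires t6max_ca")
        return self

    def build(self) -> ExperimentGeometry:
        d = self.dimensionality
        return ExperimentGeometry(
            dimensionality=d,
            t1max_n=self.t1max_n, t2max_co=self.t2max_co,
            t3max_co=self.t3max_co, t4max_n=self.t4max_n,
            t5max_h=(self.t5max_h or 0.0) if d >= 6 else 0.0,
            t6max_ca=(self.t6max_ca or 0.0) if d == 7 else 0.0,
            sw_n=self.sw_n, sw_co=self.sw_co, sw_hn=self.sw_hn, sw_ca=self.sw_ca,
            direct_points=self.direct_points, direct_sw=self.direct_sw)


class ChainConfig(_Strict):
    n_residues: int = 140
    seed: int = 1
    proline_at: list[int] = []
    exchange_broadened_prefix: int = 0
    gly_fraction: float = 0.12


class ScheduleConfig(_Strict):
    n_points: int = 5000
    seed: int = 2


class SignalConfig(_Strict):
    noise_sigma: float = 0.0
    noise_seed: int = 3
    decay_t2: float = 0.1
    include_auto: bool = False
    delta_nca: float = DEFAULT_DELTA_NCA


class ProcessingConfig(_Strict):
    grid_n1: int | None = None    # None: sized from the projected bandwidth
    grid_n2: int = 128
    peak_threshold: float = 0.15
    apodization: Literal["cosine"] | None = "cosine"


class LinkingConfig(_Strict):
    tol_n_hz: float = 6.0
    tol_hn_hz: float = 8.0
    tol_co_hz: float = 6.0
    greedy: bool = False


class RunConfig(_Strict):
    """Complete, reproducible description of one pipeline run."""

    field_mhz: float = 800.13
    geometry: GeometryConfig = GeometryConfig()
    chain: ChainConfig = ChainConfig()
    schedule: ScheduleConfig = ScheduleConfig()
    signal: SignalConfig = SignalConfig()
    processing: ProcessingConfig = ProcessingConfig()
    linking: LinkingConfig = LinkingConfig()
    output_dir: str = "nusproj_run"
    save_datasets: bool = False

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))

    def axes(self):
        return default_axes(self.field_mhz)

    @classmethod
    def preset(cls, name: str, **overrides) -> "RunConfig":
        """Named experiment presets with the published evolution times."""
        try:
            geo, field = PRESETS[name]
        except KeyError:
            raise ValueError(f"unknown preset {name!r}; "
                             f"choose from {sorted(PRESETS)}") from None
        g = GeometryConfig(
            dimensionality=geo.dimensionality,
            t1max_n=geo.t1max_n, t2max_co=geo.t2max_co, t3max_co=geo.t3max_co,
            t4max_n=geo.t4max_n, t5max_h=geo.t5max_h or None,
            t6max_ca=geo.t6max_ca or None)
        n_points = 6000 if geo.dimensionality == 7 else 5000
        base = dict(field_mhz=field, geometry=g,
                    schedule=ScheduleConfig(n_points=n_points))
        base.update(overrides)
        return cls(**base)


PRESETS: dict[str, tuple[ExperimentGeometry, float]] = {
    "800MHz-7D": (geometry_800_7d(), 800.13),
    "800MHz-6D": (geometry_800_6d(), 800.13),
    "600MHz-6D": (geometry_600_6d(), 600.13),
}
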