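"""Resolved run configuration: every tunable of the simulation pipeline.

A :class:`RunConfig` gathers the tissue baselines, personalisation
coefficients, grid resolution, solver settings, fiber geometry, drive
waveform and scoring constants into one serialisable object.  Outputs of
a run embed the config hash and seed for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import yaml

from .cable import BiphasicWaveform, FiberGeometry
from .field import GridResolution
from .scoring import DEFAULT_K_PER_MV, DEFAULT_V_TH_MV, EPSILON
from .tissue import (
    DEFAULT_EFFECTIVE_FREQUENCY_HZ,
    DEFAULT_LATERAL_EXTENT_MM,
    DEFAULT_LAYERS,
    ColeColeParams,
    PersonalizationCoefficients,
    TissueLayer,
)

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    layers: tuple[TissueLayer, ...] = DEFAULT_LAYERS
    personalization: PersonalizationCoefficients = field(
        default_factory=PersonalizationCoefficients
    )
    effective_frequency_hz: float = DEFAULT_EFFECTIVE_FREQUENCY_HZ
    lateral_extent_mm: tuple[float, float] = DEFAULT_LATERAL_EXTENT_MM
    resolution: GridResolution = field(default_factory=GridResolution)
    solver_tol: float = 1e-8
    solver_method: str = "cg"
    # Middle-row left electrode (index 2) is the single driven channel
    # for feature extraction; its position moves with the pitch D + Q.
    active_electrodes: tuple[int, ...] = (2,)
    amplitude_ma: float = 2.0
    fiber: FiberGeometry = field(default_factory=FiberGeometry)
    waveform: BiphasicWaveform = field(default_factory=BiphasicWaveform)
    dt_s: float = 1e-6
    duration_s: float = 1e-3
    region: str = "below_stratum_corneum"
    v_th_mv: float = DEFAULT_V_TH_MV
    k_per_mv: float = DEFAULT_K_PER_MV
    epsilon: float = EPSILON
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw = dict(raw)
        if "layers" in kw:
            kw["layers"] = tuple(
                TissueLayer(
                    name=l["name"],
                    thickness_mm=l["thickness_mm"],
                    cole_cole=ColeColeParams(**l["cole_cole"]),
                    rel_permittivity=l.get("rel_permittivity", 1.0e4),
                )
                for l in kw["layers"]
            )
        if "personalization" in kw:
            kw["personalization"] = PersonalizationCoefficients(**kw["personalization"])
        if "resolution" in kw:
            res = dict(kw["resolution"])
            if "cells_per_layer" in res:
                res["cells_per_layer"] = tuple(res["cells_per_layer"])
            kw["resolution"] = GridResolution(**res)
        if "fiber" in kw:
            kw["fiber"] = FiberGeometry(**kw["fiber"])
        if "waveform" in kw:
            kw["waveform"] = BiphasicWaveform(**kw["waveform"])
        if "lateral_extent_mm" in kw:
            kw["lateral_extent_mm"] = tuple(kw["lateral_extent_mm"])
        if "active_electrodes" in kw:
            kw["active_electrodes"] = tuple(kw["active_electrodes"])
        return cls(**kw)

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=int(seed))
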