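"""Run configuration: one structured object covering every pipeline default.

Band sets and trend families contain callables, so YAML serialization goes
through a named registry (``short_wave`` / ``long_wave``) plus the numeric
fields; the numeric content round-trips bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import yaml

from .preprocess import VALID_METHODS, PreprocessSpec
from .synthetic import (
    SpectralGeneratorConfig,
    StudyDesign,
    VolatileGeneratorConfig,
)

RANGE_NAMES = ("900-1700", "1300-2500")

_SPECTRAL_FACTORIES = {
    "short_wave": SpectralGeneratorConfig.short_wave,
    "long_wave": SpectralGeneratorConfig.long_wave,
}

_RANGE_TO_FACTORY = {"900-1700": "short_wave", "1300-2500": "long_wave"}


@dataclass
class Thresholds:
    vip: float = 1.0
    vip_highlight: float = 2.0
    rpd_excellent: float = 3.0
    q2_intercept: float = 0.05
    n_permutations: int = 200
    lv_min: int = 1
    lv_max: int = 10
    cv_k_pls: int = 5
    cv_k_classify: int = 10
    split_ratio: float = 0.8

    def __post_init__(self) -> None:
        numeric = (self.vip, self.vip_highlight, self.rpd_excellent,
                   self.q2_intercept, self.split_ratio)
        if any(v <= 0 for v in numeric):
            raise ValueError("all thresholds must be positive")


@dataclass
class RunConfig:
    """Everything a full run needs; all randomness funnels through seed."""

    seed: int = 20250901
    design: StudyDesign = None
    spectral_names: tuple = ("short_wave", "long_wave")
    spectral_overrides: dict = field(default_factory=dict)
    volatile: VolatileGeneratorConfig = field(default_factory=VolatileGeneratorConfig)
    preprocess_methods: tuple = VALID_METHODS
    sg_window: int = 11
    sg_polyorder: int = 2
    thresholds: Thresholds = field(default_factory=Thresholds)

    def __post_init__(self) -> None:
        if self.design is None:
            self.design = StudyDesign(seed=self.seed)
        elif self.design.seed != self.seed:
            self.design = replace(self.design, seed=self.seed)

    def spectral_config(self, name: str) -> SpectralGeneratorConfig:
        factory = _SPECTRAL_FACTORIES[name]
        return factory(**self.spectral_overrides.get(name, {}))

    def spectral_config_for_range(self, range_name: str) -> SpectralGeneratorConfig:
        return self.spectral_config(_RANGE_TO_FACTORY[range_name])

    @property
    def range_names(self) -> list:
        inv = {v: k for k, v in _RANGE_TO_FACTORY.items()}
        return [inv[n] for n in self.spectral_names]

    def preprocess_specs(self) -> list:
        return [
            PreprocessSpec(method=m, sg_window=self.sg_window, sg_polyorder=self.sg_polyorder)
            for m in self.preprocess_methods
        ]

    @property
    def lv_grid(self) -> range:
        return range(self.thresholds.lv_min, self.thresholds.lv_max + 1)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "design": {
                "sample_labels": list(self.design.sample_labels),
                "storage_months": list(self.design.storage_months),
                "n_subsamples": self.design.n_subsamples,
                "n_scans_per_subsample": self.design.n_scans_per_subsample,
                "n_gcims_replicates": self.design.n_gcims_replicates,
            },
            "spectral_names": list(self.spectral_names),
            "spectral_overrides": {
                k: dict(v) for k, v in self.spectral_overrides.items()
            },
            "volatile": {
                "class_counts": dict(self.volatile.class_counts),
                "trend_families": dict(self.volatile.trend_families),
                "dimer_fraction": self.volatile.dimer_fraction,
                "dimer_ratio_range": list(self.volatile.dimer_ratio_range),
                "replicate_cv": self.volatile.replicate_cv,
                "injection_effect_sd": self.volatile.injection_effect_sd,
                "internal_standard_volume": self.volatile.internal_standard_volume,
            },
            "preprocess_methods": list(self.preprocess_methods),
            "sg_window": self.sg_window,
            "sg_polyorder": self.sg_polyorder,
            "thresholds": asdict(self.thresholds),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        design_kw = dict(payload.get("design", {}))
        for key in ("sample_labels", "storage_months"):
            if key in design_kw:
                design_kw[key] = tuple(design_kw[key])
        seed = payload.get("seed", 20250901)
        vol_kw = dict(payload.get("volatile", {}))
        if "dimer_ratio_range" in vol_kw:
            vol_kw["dimer_ratio_range"] = tuple(vol_kw["dimer_ratio_range"])
        return cls(
            seed=seed,
            design=StudyDesign(seed=seed, **design_kw),
            spectral_names=tuple(payload.get("spectral_names", ("short_wave", "long_wave"))),
            spectral_overrides=payload.get("spectral_overrides", {}),
            volatile=VolatileGeneratorConfig(**vol_kw),
            preprocess_methods=tuple(payload.get("preprocess_methods", VALID_METHODS)),
            sg_window=payload.get("sg_window", 11),
            sg_polyorder=payload.get("sg_polyorder", 2),
            thresholds=Thresholds(**payload.get("thresholds", {})),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def checksum(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
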