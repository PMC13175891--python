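"""Pipeline configuration: YAML in, validated dataclass out.

Defaults reproduce the published filter thresholds exactly; every rule of
every cascade is overridable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .germline import GERMLINE_RULES
from .somatic import SOMATIC_RULES
from .synthetic_data import CohortConfig

STAGES = (
    "simulate",
    "preprocess",
    "germline",
    "somatic",
    "deleteriousness",
    "burden",
    "focality",
)

#: Stage -> stages it depends on.
STAGE_DEPS = {
    "simulate": (),
    "preprocess": ("simulate",),
    "germline": ("preprocess",),
    "somatic": ("preprocess",),
    "deleteriousness": ("germline", "somatic"),
    "burden": ("deleteriousness",),
    "focality": ("somatic",),
}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 1
    outdir: str = "run"
    stages: tuple = STAGES
    cohort: CohortConfig = field(default_factory=CohortConfig)
    germline_rules: dict = field(default_factory=lambda: dict(GERMLINE_RULES))
    somatic_rules: dict = field(default_factory=lambda: dict(SOMATIC_RULES))
    contamination_min_matches: int = 5

    def child_seed(self, stage: str) -> int:
        """Stable per-stage child seed fanned out from the global seed."""
        idx = STAGES.index(stage)
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(idx,))
        return int(ss.generate_state(1)[0] % (2**31))

    def validate(self) -> None:
        bad = []
        for s in self.stages:
            if s not in STAGES:
                bad.append(f"stages: unknown stage {s!r}")
        for k in self.germline_rules:
            if k not in GERMLINE_RULES:
                bad.append(f"germline_rules: unknown key {k!r}")
        for k in self.somatic_rules:
            if k not in SOMATIC_RULES:
                bad.append(f"somatic_rules: unknown key {k!r}")
        enabled = set(self.stages)
        for s in self.stages:
            for dep in STAGE_DEPS[s]:
                if dep not in enabled:
                    bad.append(f"stages: {s!r} requires {dep!r} which is toggled off")
        if bad:
            raise ConfigError("invalid configuration: " + "; ".join(bad))


def load_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"invalid configuration: unknown keys {sorted(unknown)}")
    if "cohort" in raw:
        cohort_known = {f.name for f in dataclasses.fields(CohortConfig)}
        bad = set(raw["cohort"]) - cohort_known
        if bad:
            raise ConfigError(f"invalid configuration: unknown cohort keys {sorted(bad)}")
        cohort = raw["cohort"]
        if "regions" in cohort:
            cohort["regions"] = tuple(cohort["regions"])
        if "somatic_vaf_tiers" in cohort:
            cohort["somatic_vaf_tiers"] = tuple(cohort["somatic_vaf_tiers"])
        raw["cohort"] = CohortConfig(**cohort)
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg
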