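"""Run configuration: schema-validated settings for the simulation pipeline.

Defaults reproduce the threshold-study design: three interleaved colour
channels at eccentricities 0/10/20 degrees, channel contrasts 0.96 (Ach),
0.23 (RG) and 0.89 (YV), QUEST tracks of 30–50 trials stopping at a
posterior SD of 0.07 log10 units, and triplet-repeated trials.  Unknown
keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import model as rmodel


class QuestSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    grid_min: float = 0.3
    grid_max: float = 2.3
    grid_step: float = 0.01
    beta: float = 10.0
    delta: float = 0.01
    prior_mean: float = 1.778151250383644  # log10(60)
    prior_sd: float = 0.6


class SessionSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    min_trials: int = 30
    max_trials: int = 50
    sd_stop: float = 0.07
    repeats: int = 3
    aggregate_repeats: bool = False


class PsychometricSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    slope: float = 10.0
    lapse: float = 0.01
    outlier_cutoff: float = 3.5


class PopulationKnot(BaseModel):
    model_config = ConfigDict(extra="forbid")

    eccentricity_deg: float
    mu_ppd: float = Field(gt=0)
    sigma_ppd: float = Field(ge=0)


class RunConfig(BaseModel):
    """Full configuration of a synthetic study run."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_observers: int = 18
    channels: list[str] = ["Ach", "RG", "YV"]
    eccentricities: list[float] = [0.0, 10.0, 20.0]
    contrasts: dict[str, float] = dict(rmodel.DEFAULT_CONTRASTS)
    quest: QuestSettings = QuestSettings()
    session: SessionSettings = SessionSettings()
    psychometric: PsychometricSettings = PsychometricSettings()
    population_knots: dict[str, list[PopulationKnot]] | None = None
    out_dir: str = "visres_out"

    @field_validator("channels")
    @classmethod
    def _known_channels(cls, v: list[str]) -> list[str]:
        bad = set(v) - set(rmodel.CHANNELS)
        if bad:
            raise ValueError(f"unknown channel(s) {sorted(bad)}; expected {rmodel.CHANNELS}")
        return v

    def population_models(self) -> dict[str, rmodel.PopulationModel]:
        from . import synthetic

        if self.population_knots is None:
            return {
                c: m for c, m in synthetic.default_population_models().items()
                if c in self.channels
            }
        return {
            chan: rmodel.PopulationModel(
                channel=chan,
                knots=tuple(
                    (k.eccentricity_deg, k.mu_ppd, k.sigma_ppd)
                    for k in sorted(knots, key=lambda k: k.eccentricity_deg)
                ),
            )
            for chan, knots in self.population_knots.items()
            if chan in self.channels
        }

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded,
        so the same experiment written to two directories hashes alike)."""
        payload = json.dumps(
            self.model_dump(exclude={"out_dir"}), sort_keys=True, default=str
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML/JSON config file; an empty or missing file yields the
    full default configuration.  Schema violations list the offending keys."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return RunConfig(**data)
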