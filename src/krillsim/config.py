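"""Configuration loading and campaign presets.

A campaign is described by a flat YAML file with these sections (all keys
optional; omitted keys fall back to model defaults)::

    recruitment: {r_mean: 4.0e6, release_schedule: {11: 0.25, 12: 0.5, 1: 0.25}}
    mortality:   {M_monthly: 8.0}
    growth:      {l_inf: 60.0, k_annual: 0.45, init_mean: 21.742, init_sd: 2.0,
                  sv_phase: 2, sv_amplitude: 1.0}
    selectivity: {l50_mm: 35.5, sr_mm: 7.0}
    n_years: 10
    campaign:    {rvar_levels: [10, ..., 100], n_sims: 2000, scale_factor: 1.0}

``scale_factor`` multiplies ``r_mean``; proportional indices and the
power-law slope are invariant to it while the intercept shifts by
``ln(scale_factor)``, so the "desk" preset (scale 0.01, 200 replicates)
reproduces full-scale statistical behaviour in minutes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .demography import GrowthParams, MortalityParams
from .selectivity import SelectivityParams
from .simulation import RecruitmentParams, SimulationConfig

__all__ = ["CampaignSpec", "load_config", "preset", "config_to_dict"]

_FULL_LEVELS = tuple(range(10, 101, 10))


@dataclass(frozen=True)
class CampaignSpec:
    """A simulation config plus campaign-level settings."""

    config: SimulationConfig = field(default_factory=SimulationConfig)
    rvar_levels: Sequence[float] = _FULL_LEVELS
    n_sims: int = 2000
    scale_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError(f"scale_factor must be > 0, got {self.scale_factor}")
        for rv in self.rvar_levels:
            if not 0 < rv <= 100:
                raise ValueError(f"rvar level {rv} outside (0, 100]")

    def scaled_config(self) -> SimulationConfig:
        """The simulation config with ``r_mean`` multiplied by ``scale_factor``."""
        rec = replace(
            self.config.recruitment,
            r_mean=self.config.recruitment.r_mean * self.scale_factor,
        )
        return replace(self.config, recruitment=rec)


#: named presets: the full-scale study design and a desk-scale analogue
_PRESETS: Mapping[str, dict] = {
    "full": dict(n_sims=2000, scale_factor=1.0),
    "desk": dict(n_sims=200, scale_factor=0.01),
}


def preset(name: str, seed: int = 0) -> CampaignSpec:
    """Return a named campaign preset ('full' or 'desk')."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; expected one of {sorted(_PRESETS)}")
    return CampaignSpec(seed=seed, **_PRESETS[name])


def _build_section(cls, data: Mapping, section: str):
    try:
        return cls(**data)
    except TypeError as exc:
        raise ValueError(f"bad key in config section {section!r}: {exc}") from None


def load_config(path: str | Path, seed: int = 0) -> CampaignSpec:
    """Parse a YAML campaign config into a :class:`CampaignSpec`."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {"recruitment", "mortality", "growth", "selectivity", "n_years", "campaign"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    rec_raw = dict(raw.get("recruitment", {}))
    if "release_schedule" in rec_raw:
        rec_raw["release_schedule"] = {
            int(k): float(v) for k, v in rec_raw["release_schedule"].items()
        }
    cfg = SimulationConfig(
        recruitment=_build_section(RecruitmentParams, rec_raw, "recruitment"),
        mortality=_build_section(MortalityParams, raw.get("mortality", {}), "mortality"),
        growth=_build_section(GrowthParams, raw.get("growth", {}), "growth"),
        selectivity=_build_section(
            SelectivityParams, raw.get("selectivity", {}), "selectivity"
        ),
        n_years=int(raw.get("n_years", 10)),
    )
    camp = raw.get("campaign", {})
    return CampaignSpec(
        config=cfg,
        rvar_levels=tuple(camp.get("rvar_levels", _FULL_LEVELS)),
        n_sims=int(camp.get("n_sims", 2000)),
        scale_factor=float(camp.get("scale_factor", 1.0)),
        seed=seed,
    )


def config_to_dict(spec: CampaignSpec) -> dict:
    """JSON-serialisable echo of a campaign spec (for run manifests)."""
    d = asdict(spec)
    d["config"]["recruitment"]["release_schedule"] = dict(
        spec.config.recruitment.release_schedule
    )
    d["rvar_levels"] = list(spec.rvar_levels)
    return d
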