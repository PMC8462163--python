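"""Pipeline configuration.

All defaults are the published parameter values for the seed--carabid
system: pitfall activity-density exponent -0.51 (single trap, 21 degC),
mean seed energy density 18.77 kJ/g, guild feeding rates 0.51 / 0.18 /
0.00 mg seed per mg carabid body mass per day, and the dry-mass--length
allometry ln(M) = -3.4 + 2.6 ln(L).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import yaml

GUILDS = ("granivore", "omnivore", "carnivore")

#: Published allometric exponent range for pitfall correction (15--27 degC).
PITFALL_EXPONENT_RANGE = (-0.55, -0.45)


def _default_feeding_rates() -> dict[str, float]:
    return {"granivore": 0.51, "omnivore": 0.18, "carnivore": 0.00}


@dataclass
class PipelineConfig:
    """Tunable parameters of the inference pipeline.

    Parameters
    ----------
    pitfall_exponent
        Exponent beta of the activity-density correction D_j = n_j * M_j**beta.
        Dimensionless; valid range covers the published 15--27 degC span
        unless ``allow_pitfall_out_of_range`` is set.
    default_energy_density_kJ_per_g
        Energy density imputed for seed taxa with no literature value (kJ/g).
    guild_feeding_rates
        Daily seed intake per unit body mass by feeding guild
        (mg seed / mg carabid / day).
    allometry_intercept, allometry_slope
        Coefficients of ln(dry mass, mg) = a + b * ln(body length, mm).
    energy_mode
        ``"energy"``: the intake chain runs in kJ (per-seed energy E_i,
        requirement E_j in kJ/day). ``"mass"``: it runs in mg (per-seed
        mass M_i, requirement in mg/day). Both conserve their own budget.
    reference_energy
        ``"fixed"``: convert the mass-based feeding rate to kJ/day with the
        constant default energy density. ``"field_mean"``: use the
        abundance-weighted mean energy density of the field's seed rain.
    include_carnivores_in_metrics
        Whether carnivorous carabids (which can hold no seed links) count
        toward the node total S used by connectance metrics.
    link_floor
        Interaction strengths at or below this value are pruned from webs.
    extrapolation_threshold_mg
        Seed masses above this trigger an extrapolation warning from the
        cost model (largest seed in the source feeding trials: 8.9 mg).
    """

    pitfall_exponent: float = -0.51
    default_energy_density_kJ_per_g: float = 18.77
    guild_feeding_rates: dict[str, float] = field(default_factory=_default_feeding_rates)
    allometry_intercept: float = -3.4
    allometry_slope: float = 2.6
    energy_mode: str = "energy"
    reference_energy: str = "fixed"
    include_carnivores_in_metrics: bool = False
    link_floor: float = 0.0
    extrapolation_threshold_mg: float = 8.9
    rng_seed: int = 0
    allow_pitfall_out_of_range: bool = False

    def __post_init__(self) -> None:
        lo, hi = PITFALL_EXPONENT_RANGE
        if not self.allow_pitfall_out_of_range and not (lo <= self.pitfall_exponent <= hi):
            raise ValueError(
                f"pitfall_exponent {self.pitfall_exponent} outside the published "
                f"range [{lo}, {hi}]; set allow_pitfall_out_of_range=True to override"
            )
        for guild in GUILDS:
            if guild not in self.guild_feeding_rates:
                raise ValueError(f"guild_feeding_rates missing guild {guild!r}")
            if self.guild_feeding_rates[guild] < 0:
                raise ValueError(f"feeding rate for {guild!r} must be >= 0")
        if self.energy_mode not in ("energy", "mass"):
            raise ValueError("energy_mode must be 'energy' or 'mass'")
        if self.reference_energy not in ("fixed", "field_mean"):
            raise ValueError("reference_energy must be 'fixed' or 'field_mean'")
        if self.default_energy_density_kJ_per_g <= 0:
            raise ValueError("default_energy_density_kJ_per_g must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
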