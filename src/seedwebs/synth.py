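"""Synthetic censuses, trait tables and cafeteria experiments.

Emulates the statistical structure of an arable-field survey: per-field
species subsets drawn from regional pools via Bernoulli occupancy,
log-normal abundances rounded to integer counts, log-normal trait
distributions, and cafeteria consumption generated by inverting the cost
model (x = E / h with ln h = prediction + study offset + Gaussian noise),
so that parameter-recovery tests know the truth.

Default pool sizes and occupancy are set so the median inferred network
size (seed genera + carabid species per field) lands near 17, the scale
of real arable assemblages. Everything is deterministic given
``rng_seed`` (numpy PCG64 streams keyed on (seed, purpose, index)).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .config import PipelineConfig
from .cost_model import CostModelCoefficients
from .traits import FieldCensus

# stream tags so each purpose gets an independent substream of rng_seed
_POOL, _FIELD, _CAFETERIA = 101, 202, 303


def _default_guild_mix() -> dict[str, float]:
    return {"granivore": 0.30, "omnivore": 0.40, "carnivore": 0.30}


@dataclass
class CafeteriaSpec:
    """Shape of synthetic feeding-trial data."""

    n_studies: int = 3
    records_per_study: int = 40
    noise_sd: float = 0.3  # sd of Gaussian noise on ln h
    study_offset_sd: float = 0.5  # sd of the between-study intercepts
    seed_mass_lognormal: tuple[float, float] = (-0.5, 1.0)  # mg, trials span ~0.1-8.9
    carabid_mass_lognormal: tuple[float, float] = (2.8, 0.45)  # mg, ~8-37


@dataclass
class SynthSpec:
    """Parameters of the synthetic community generator."""

    n_fields: int = 50
    n_seed_genera: int = 30
    n_carabid_species: int = 40
    seed_occupancy: float = 0.28
    carabid_occupancy: float = 0.22
    seed_abundance_lognormal: tuple[float, float] = (4.0, 1.5)  # season seed-rain counts
    carabid_abundance_lognormal: tuple[float, float] = (2.0, 1.2)  # pitfall counts
    seed_mass_lognormal: tuple[float, float] = (-0.5, 1.0)  # mg
    carabid_length_lognormal: tuple[float, float] = (2.05, 0.35)  # mm
    energy_density_lognormal: tuple[float, float] = (2.93, 0.12)  # kJ/g, ~18.8 median
    p_energy_missing: float = 0.25  # fraction of genera lacking energy data
    guild_mix: dict[str, float] = field(default_factory=_default_guild_mix)
    cafeteria: CafeteriaSpec = field(default_factory=CafeteriaSpec)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.guild_mix.values()) - 1.0) > 1e-9:
            raise ValueError("guild_mix proportions must sum to 1")
        for name in ("n_fields",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_seed_genera", "n_carabid_species"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for mu, sd in (self.seed_abundance_lognormal, self.carabid_abundance_lognormal,
                       self.seed_mass_lognormal, self.carabid_length_lognormal):
            if sd < 0:
                raise ValueError("log-normal sigma must be >= 0")
        if isinstance(self.cafeteria, dict):
            self.cafeteria = CafeteriaSpec(**self.cafeteria)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SynthSpec":
        with open(path, encoding="utf-8") as fh:
            return cls(**(yaml.safe_load(fh) or {}))


# Real tribes drive guild assignment downstream, so synthetic carabids get
# a tribe consistent with their intended guild.
_GUILD_TRIBES = {
    "granivore": ("Harpalini", "Zabrini"),
    "omnivore": ("Sphodrini", "Trechini"),
    "carnivore": ("Carabini", "Nebriini", "Bembidiini"),
}


def generate_trait_pools(spec: SynthSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Regional seed and carabid trait tables (the CSV schemas of the I/O layer).

    Returns (seed_traits, carabid_traits); seed energy densities are
    missing for a fraction of genera, exercising the imputation path.
    """
    rng = np.random.default_rng([spec.rng_seed, _POOL])
    mu_m, sd_m = spec.seed_mass_lognormal
    masses = np.exp(rng.normal(mu_m, sd_m, spec.n_seed_genera))
    mu_e, sd_e = spec.energy_density_lognormal
    energies = np.exp(rng.normal(mu_e, sd_e, spec.n_seed_genera))
    missing = rng.random(spec.n_seed_genera) < spec.p_energy_missing
    seed_traits = pd.DataFrame(
        {
            "genus": [f"Seedgenus{i:03d}" for i in range(spec.n_seed_genera)],
            "species": [f"Seedgenus{i:03d} sp." for i in range(spec.n_seed_genera)],
            "seed_mass_mg": masses,
            "energy_kJ_per_g": np.where(missing, np.nan, energies),
        }
    )

    mu_l, sd_l = spec.carabid_length_lognormal
    lengths = np.exp(rng.normal(mu_l, sd_l, spec.n_carabid_species))
    spread = rng.uniform(1.05, 1.25, spec.n_carabid_species)
    guild_names = list(spec.guild_mix)
    guilds = rng.choice(guild_names, size=spec.n_carabid_species,
                        p=[spec.guild_mix[g] for g in guild_names])
    tribes = [
        _GUILD_TRIBES[g][int(rng.integers(len(_GUILD_TRIBES[g])))] for g in guilds
    ]
    carabid_traits = pd.DataFrame(
        {
            "species": [f"Carabid{j:03d}" for j in range(spec.n_carabid_species)],
            "tribe": tribes,
            "genus": [f"Genus{j:03d}" for j in range(spec.n_carabid_species)],
            "length_min_mm": lengths / spread,
            "length_max_mm": lengths * spread,
        }
    )
    return seed_traits, carabid_traits


def generate_field_census(spec: SynthSpec, field_index: int) -> FieldCensus:
    """One field's census: Bernoulli occupancy, log-normal integer counts.

    Counts for included taxa are log-normal draws rounded to integers with
    a floor of 1 (a sampled taxon was seen at least once).
    """
    rng = np.random.default_rng([spec.rng_seed, _FIELD, field_index])

    def draw(n_pool, occupancy, lognorm, labels):
        present = rng.random(n_pool) < occupancy
        mu, sd = lognorm
        counts = np.maximum(1, np.rint(np.exp(rng.normal(mu, sd, n_pool)))).astype(int)
        return {labels[i]: int(counts[i]) for i in range(n_pool) if present[i]}

    seed_labels = [f"Seedgenus{i:03d}" for i in range(spec.n_seed_genera)]
    carabid_labels = [f"Carabid{j:03d}" for j in range(spec.n_carabid_species)]
    return FieldCensus(
        field_id=f"F{field_index:04d}",
        seed_counts=draw(spec.n_seed_genera, spec.seed_occupancy,
                         spec.seed_abundance_lognormal, seed_labels),
        carabid_counts=draw(spec.n_carabid_species, spec.carabid_occupancy,
                            spec.carabid_abundance_lognormal, carabid_labels),
    )


def generate_censuses(spec: SynthSpec) -> list[FieldCensus]:
    return [generate_field_census(spec, i) for i in range(spec.n_fields)]


def census_frame(censuses: list[FieldCensus]) -> pd.DataFrame:
    """Long-form census table matching the I/O schema."""
    rows = []
    for c in censuses:
        for taxon, count in sorted(c.seed_counts.items()):
            rows.append((c.field_id, "seed", taxon, count))
        for taxon, count in sorted(c.carabid_counts.items()):
            rows.append((c.field_id, "carabid", taxon, count))
    return pd.DataFrame(rows, columns=["field_id", "taxon_type", "taxon_id", "count"])


def generate_cafeteria(
    spec: SynthSpec,
    coefs: Optional[CostModelCoefficients] = None,
    config: Optional[PipelineConfig] = None,
    study_offsets: Optional[list[float]] = None,
) -> pd.DataFrame:
    """Cafeteria records drawn from a known cost model.

    Per record: ln h = prediction + study offset + N(0, noise_sd); the
    observed consumption is x = E / h. True masses and energies are
    carried in the table, so re-fitting can be checked against the
    generating coefficients. ``study_offsets`` overrides the random
    between-study intercepts (use [0, ...] or ``study_offset_sd = 0`` for
    a single-scale dataset).
    """
    coefs = coefs or CostModelCoefficients()
    config = config or PipelineConfig()
    caf = spec.cafeteria
    rng = np.random.default_rng([spec.rng_seed, _CAFETERIA])
    if study_offsets is None:
        study_offsets = rng.normal(0.0, caf.study_offset_sd, caf.n_studies).tolist()
    elif len(study_offsets) != caf.n_studies:
        raise ValueError("study_offsets length must equal n_studies")
    rows = []
    for k in range(caf.n_studies):
        mu_i, sd_i = caf.seed_mass_lognormal
        mu_j, sd_j = caf.carabid_mass_lognormal
        mi = np.exp(rng.normal(mu_i, sd_i, caf.records_per_study))
        mj = np.exp(rng.normal(mu_j, sd_j, caf.records_per_study))
        ei = mi / 1000.0 * config.default_energy_density_kJ_per_g
        u, v = np.cbrt(mi), np.log(mj)
        log_h = (coefs.b0 + coefs.b1 * u + coefs.b2 * v + coefs.b3 * u * v
                 + study_offsets[k]
                 + rng.normal(0.0, caf.noise_sd, caf.records_per_study))
        x = ei / np.exp(log_h)
        for idx in range(caf.records_per_study):
            rows.append(
                {
                    "study_id": f"study{k}",
                    "carabid_species": f"CafCarabid{k}_{idx:03d}",
                    "carabid_mass_mg": mj[idx],
                    "seed_species": f"CafSeed{k}_{idx:03d}",
                    "seed_mass_mg": mi[idx],
                    "seed_energy_kJ": ei[idx],
                    "consumption_per_day": x[idx],
                    "true_log_h": log_h[idx],
                    "true_study_offset": study_offsets[k],
                }
            )
    return pd.DataFrame(rows)


def fixture_community() -> tuple[pd.DataFrame, pd.DataFrame, FieldCensus]:
    """The small worked-example field used in docs and tests.

    One granivore, one omnivore, one carnivore; three seed genera spanning
    small to large (one with missing energy density).
    """
    seed_traits = pd.DataFrame(
        {
            "genus": ["Chenopodium", "Poa", "Viciafaba"],
            "species": ["Chenopodium album", "Poa annua", "Vicia faba"],
            "seed_mass_mg": [0.7, 0.3, 4.0],
            "energy_kJ_per_g": [20.1, np.nan, 19.0],
        }
    )
    carabid_traits = pd.DataFrame(
        {
            "species": ["Harpalus rufipes", "Pterostichus melanarius", "Nebria brevicollis"],
            "tribe": ["Harpalini", "Pterostichini", "Nebriini"],
            "genus": ["Harpalus", "Pterostichus", "Nebria"],
            "length_min_mm": [11.0, 12.0, 10.0],
            "length_max_mm": [16.0, 18.0, 14.0],
        }
    )
    census = FieldCensus(
        field_id="EX01",
        seed_counts={"Chenopodium": 120, "Poa": 300, "Viciafaba": 15},
        carabid_counts={"Harpalus rufipes": 12, "Pterostichus melanarius": 8,
                        "Nebria brevicollis": 5},
    )
    return seed_traits, carabid_traits, census
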