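"""Frequency-dependent diet composition and population-level flows.

Implements the chain from per-individual risk indices to a weighted web:

    F_ij = r_ij D_i / sum_i r_ij D_i      frequency of seed i in the diet of j
    E_j  = feeding_rate(guild) * M_j      daily intake requirement
    C_ij = F_ij E_j / sum_i F_ij E_i      seeds of type i eaten per individual per day
    I_ij = C_ij D_j                       population-level interaction strength
    P_i  = sum_j I_ij / D_i               predation pressure ratio per seed

Diets are frequency-dependent but without prey switching: the risk index
does not respond to density, density enters only through the F
normalization. The C step converts the mass-based energetic requirement
into numbers of seeds and conserves the budget exactly:
sum_i C_ij * E_i = E_j in whichever units (kJ or mg) the mode selects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .traits import CarabidTaxon

logger = logging.getLogger(__name__)


class EmptyDietError(ValueError):
    """No seed has positive risk x density; the carabid has nothing to eat."""


@dataclass
class DietProfile:
    """Per-individual diet of one carabid species in one field."""

    carabid_species: str
    requirement: float  # E_j: kJ/day (energy mode) or mg seed/day (mass mode)
    frequencies: pd.Series  # F_ij over seed taxa, sums to 1
    intake: pd.Series  # C_ij, seeds per individual per day


@dataclass
class InteractionMatrix:
    """Inferred flows for one field: I (seeds x carabids) and P per seed."""

    field_id: str
    I: pd.DataFrame
    P: pd.Series


def diet_frequencies(risk: pd.Series, seed_density: pd.Series) -> pd.Series:
    """F_ij = r_ij D_i normalized over the seeds available to carabid j.

    Raises :class:`EmptyDietError` when every r*D product is zero; the
    caller decides whether to drop the carabid from the web.
    """
    risk, seed_density = risk.align(seed_density, join="inner")
    if np.any(risk.values < 0) or np.any(seed_density.values < 0):
        raise ValueError("risk and density must be >= 0")
    prod = risk * seed_density
    total = prod.sum()
    if total <= 0:
        raise EmptyDietError("all risk x density products are zero")
    return prod / total


def energy_requirement(
    carabid: CarabidTaxon,
    config: Optional[PipelineConfig] = None,
    reference_energy_density_kJ_per_g: Optional[float] = None,
) -> float:
    """Daily intake requirement E_j of one individual.

    The literature feeding rates are mass-based (mg seed per mg body mass
    per day, by guild). Mass mode returns rate * M_j in mg/day; energy
    mode converts to kJ/day through a reference seed energy density
    (kJ/g), by default the configured constant. Carnivores have rate 0 and
    therefore E_j = 0.
    """
    config = config or PipelineConfig()
    rate = config.guild_feeding_rates[carabid.guild]
    mg_per_day = rate * carabid.mass_mg
    if config.energy_mode == "mass":
        return mg_per_day
    ebar = reference_energy_density_kJ_per_g
    if ebar is None:
        ebar = config.default_energy_density_kJ_per_g
    return mg_per_day * ebar / 1000.0  # mg -> g -> kJ


def seed_intake(
    frequencies: pd.Series, requirement: float, per_seed_value: pd.Series
) -> pd.Series:
    """C_ij = F_ij E_j / sum_i(F_ij E_i): seeds per individual per day.

    ``per_seed_value`` is E_i (kJ per seed, energy mode) or M_i (mg per
    seed, mass mode); conservation sum_i C_ij * value_i = E_j is exact by
    construction.
    """
    f, val = frequencies.align(per_seed_value, join="inner")
    if np.any(val.values[f.values > 0] <= 0):
        raise ValueError("per-seed value must be > 0 wherever F > 0")
    denom = float((f * val).sum())
    if requirement == 0:
        return pd.Series(0.0, index=f.index)
    if denom <= 0:
        raise EmptyDietError("diet value denominator is zero")
    return f * requirement / denom


def carabid_diet(
    carabid: CarabidTaxon,
    risk: pd.Series,
    seed_density: pd.Series,
    per_seed_value: pd.Series,
    config: Optional[PipelineConfig] = None,
    reference_energy_density_kJ_per_g: Optional[float] = None,
) -> DietProfile:
    """Full per-individual diet for one carabid: F, E_j and C."""
    config = config or PipelineConfig()
    f = diet_frequencies(risk, seed_density)
    ej = energy_requirement(carabid, config, reference_energy_density_kJ_per_g)
    c = seed_intake(f, ej, per_seed_value)
    return DietProfile(carabid.species_id, ej, f, c)


def interaction_strengths(
    intake: pd.DataFrame, carabid_density: pd.Series
) -> pd.DataFrame:
    """I_ij = C_ij D_j (seeds x carabids).

    Zero-density columns stay in the matrix as zeros; pruning is a
    web-level decision.
    """
    intake, dens = intake.align(carabid_density, axis=1, join="inner")
    if np.any(dens.values < 0):
        raise ValueError("carabid density must be >= 0")
    return intake.mul(dens, axis=1)


def predation_pressure(I: pd.DataFrame, seed_density: pd.Series) -> pd.Series:
    """P_i = (sum_j I_ij) / D_i, the per-day predation pressure ratio.

    Seeds with zero density are omitted from the result (logged).
    """
    totals = I.sum(axis=1)
    totals, dens = totals.align(seed_density, join="inner")
    zero = dens <= 0
    if zero.any():
        logger.info("omitting %d zero-density seed taxa from predation pressure",
                    int(zero.sum()))
    return totals[~zero] / dens[~zero]
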