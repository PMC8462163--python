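"""Per-field web assembly and network metrics.

`build_web` runs the whole inference chain for one field census: trait
resolution, density correction, risk indices from the cost model, diet
composition, and population-level interaction strengths, returning a
:class:`BipartiteWeb` with its metrics. Webs with no seeds or no
seed-feeding flow are flagged empty and excluded from summaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .cost_model import CostModelCoefficients, predict_log_h, risk_index
from .diet_model import (
    EmptyDietError,
    carabid_diet,
    interaction_strengths,
    predation_pressure,
)
from .traits import (
    CarabidTaxon,
    FieldCensus,
    SeedTaxon,
    correct_census_densities,
)

logger = logging.getLogger(__name__)


@dataclass
class BipartiteWeb:
    """An inferred weighted seed-carabid network for one field."""

    field_id: str
    seed_nodes: pd.DataFrame  # taxon, mass_mg, energy_kJ, density
    carabid_nodes: pd.DataFrame  # species, mass_mg, guild, count, density
    I: pd.DataFrame  # seeds x carabids interaction strengths
    P: pd.Series  # predation pressure per seed
    metrics: dict = field(default_factory=dict)
    empty: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def network_size(self) -> int:
        """Seed genera + carabid species present in the census."""
        return len(self.seed_nodes) + len(self.carabid_nodes)

    def to_networkx(self):
        """Bipartite graph with flow weights, for network tooling."""
        import networkx as nx

        g = nx.Graph()
        for row in self.seed_nodes.itertuples(index=False):
            g.add_node(f"seed:{row.taxon}", bipartite="seed",
                       mass_mg=row.mass_mg, density=row.density)
        for row in self.carabid_nodes.itertuples(index=False):
            g.add_node(f"carabid:{row.species}", bipartite="carabid",
                       mass_mg=row.mass_mg, guild=row.guild, density=row.density)
        for seed in self.I.index:
            for carabid in self.I.columns:
                w = float(self.I.loc[seed, carabid])
                if w > 0:
                    g.add_edge(f"seed:{seed}", f"carabid:{carabid}", weight=w)
        return g


def weighted_connectance(I: pd.DataFrame | np.ndarray,
                         n_nodes: Optional[int] = None) -> float:
    """Quantitative connectance of a flow matrix.

    Linkage density is the mean of two effective link counts, each the
    exponential of a flow-weighted average Shannon entropy: over columns
    (effective number of resources per consumer, H_N) and over rows
    (effective number of consumers per resource, H_P):

        LD_w = (H_N + H_P) / 2,   C_w = LD_w / S

    with S the number of network nodes (by default the matrix dimensions
    summed). A single-link web has C_w = 1/2 for S = 2.
    """
    M = np.asarray(I, dtype=float)
    total = M.sum()
    if total <= 0:
        raise ValueError("connectance undefined: all flows are zero")

    def effective(axis: int) -> float:
        sums = M.sum(axis=axis)
        mask = sums > 0
        P = M[:, mask] / sums[mask] if axis == 0 else (M[mask, :].T / sums[mask]).T
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(P > 0, P * np.log(P), 0.0)
        H = -plogp.sum(axis=0) if axis == 0 else -plogp.sum(axis=1)
        wts = sums[mask] / total
        return float(np.exp((wts * H).sum()))

    h_n = effective(axis=0)  # per-consumer diet diversity
    h_p = effective(axis=1)  # per-resource consumer diversity
    ld = 0.5 * (h_n + h_p)
    if n_nodes is None:
        n_nodes = M.shape[0] + M.shape[1]
    return ld / n_nodes


def binary_connectance(I: pd.DataFrame | np.ndarray) -> float:
    """Realized links / possible links of the flow matrix."""
    M = np.asarray(I, dtype=float)
    if M.size == 0:
        raise ValueError("connectance undefined for an empty matrix")
    return float((M > 0).sum() / M.size)


def build_web(
    census: FieldCensus,
    seed_table: Mapping[str, SeedTaxon],
    carabid_table: Mapping[str, CarabidTaxon],
    coefs: Optional[CostModelCoefficients] = None,
    config: Optional[PipelineConfig] = None,
) -> BipartiteWeb:
    """Infer the weighted web for one field census.

    Taxa absent from the trait tables are reported in ``web.warnings`` and
    skipped. A web with no resolvable seeds, no resolvable carabids, or no
    positive flow (e.g. carnivores only) is flagged ``empty``; its metrics
    are NaN and field summaries exclude it.
    """
    coefs = coefs or CostModelCoefficients()
    config = config or PipelineConfig()
    notes: list[str] = []

    seed_ids = sorted(t for t, c in census.seed_counts.items() if c > 0)
    unresolved_seeds = [t for t in seed_ids if t not in seed_table]
    for t in unresolved_seeds:
        notes.append(f"seed taxon {t!r} missing from trait table; skipped")
    seed_ids = [t for t in seed_ids if t in seed_table]

    carabid_ids = sorted(s for s, c in census.carabid_counts.items() if c > 0)
    unresolved_car = [s for s in carabid_ids if s not in carabid_table]
    for s in unresolved_car:
        notes.append(f"carabid species {s!r} missing from trait table; skipped")
    carabid_ids = [s for s in carabid_ids if s in carabid_table]

    census = correct_census_densities(census, carabid_table, config)

    seed_nodes = pd.DataFrame(
        {
            "taxon": seed_ids,
            "mass_mg": [seed_table[t].mass_mg for t in seed_ids],
            "energy_kJ": [seed_table[t].energy_per_seed_kJ for t in seed_ids],
            "density": [census.seed_counts[t] for t in seed_ids],
        }
    )
    carabid_nodes = pd.DataFrame(
        {
            "species": carabid_ids,
            "mass_mg": [carabid_table[s].mass_mg for s in carabid_ids],
            "guild": [carabid_table[s].guild for s in carabid_ids],
            "count": [census.carabid_counts[s] for s in carabid_ids],
            "density": [census.carabid_densities[s] for s in carabid_ids],
        }
    )

    web = BipartiteWeb(
        field_id=census.field_id,
        seed_nodes=seed_nodes,
        carabid_nodes=carabid_nodes,
        I=pd.DataFrame(index=pd.Index(seed_ids, name="seed"),
                       columns=pd.Index(carabid_ids, name="carabid"),
                       dtype=float).fillna(0.0),
        P=pd.Series(dtype=float),
        warnings=notes,
    )

    if not seed_ids or not carabid_ids:
        web.empty = True
        web.metrics = _nan_metrics(web)
        return web

    seed_density = pd.Series(
        seed_nodes["density"].values, index=seed_ids, dtype=float
    )
    seed_mass = pd.Series(seed_nodes["mass_mg"].values, index=seed_ids, dtype=float)
    seed_energy = pd.Series(seed_nodes["energy_kJ"].values, index=seed_ids, dtype=float)
    per_seed_value = seed_energy if config.energy_mode == "energy" else seed_mass

    ebar = None
    if config.energy_mode == "energy" and config.reference_energy == "field_mean":
        # abundance-weighted mean energy density (kJ/g) of the seed rain
        dens_kj_g = seed_energy / (seed_mass / 1000.0)
        ebar = float((dens_kj_g * seed_density).sum() / seed_density.sum())

    intake = {}
    dropped = []
    for sp in carabid_ids:
        taxon = carabid_table[sp]
        if taxon.guild == "carnivore":
            intake[sp] = pd.Series(0.0, index=seed_ids)
            continue
        log_h = predict_log_h(
            seed_mass.values, taxon.mass_mg, coefs,
            extrapolation_threshold_mg=config.extrapolation_threshold_mg,
        )
        r = pd.Series(risk_index(seed_energy.values, np.exp(log_h)), index=seed_ids)
        try:
            diet = carabid_diet(taxon, r, seed_density, per_seed_value,
                                config, reference_energy_density_kJ_per_g=ebar)
        except EmptyDietError:
            dropped.append(sp)
            continue
        intake[sp] = diet.intake
    if dropped:
        notes.append(f"{len(dropped)} carabid(s) with empty diets dropped: {dropped}")

    C = pd.DataFrame(intake).reindex(index=seed_ids).fillna(0.0)
    C.index.name, C.columns.name = "seed", "carabid"
    dens = pd.Series(
        {sp: census.carabid_densities[sp] for sp in C.columns}, dtype=float
    )
    I = interaction_strengths(C, dens)
    if config.link_floor > 0:
        I = I.where(I > config.link_floor, 0.0)
    web.I = I
    if float(I.values.sum()) <= 0:
        web.empty = True
        web.metrics = _nan_metrics(web)
        return web
    web.P = predation_pressure(I, seed_density)
    web.metrics = _metrics(web, config)
    return web


def _nan_metrics(web: BipartiteWeb) -> dict:
    return {
        "network_size": web.network_size,
        "weighted_connectance": float("nan"),
        "binary_connectance": float("nan"),
        "total_flow": 0.0,
    }


def _metrics(web: BipartiteWeb, config: PipelineConfig) -> dict:
    I = web.I
    if not config.include_carnivores_in_metrics:
        feeders = web.carabid_nodes.loc[
            web.carabid_nodes["guild"] != "carnivore", "species"
        ]
        I = I[[c for c in I.columns if c in set(feeders)]]
    s = I.shape[0] + I.shape[1]
    return {
        "network_size": web.network_size,
        "weighted_connectance": weighted_connectance(I, n_nodes=s),
        "binary_connectance": binary_connectance(I),
        "total_flow": float(I.values.sum()),
    }


def summarize_fields(
    webs: Iterable[BipartiteWeb],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy per-field metric and per-seed predation-pressure tables.

    Empty-flagged webs contribute no rows. The pressure table carries seed
    mass and density so size--pressure relationships can be examined
    directly.
    """
    metric_rows, pressure_rows = [], []
    for web in webs:
        if web.empty:
            continue
        metric_rows.append({"field_id": web.field_id, **web.metrics})
        masses = dict(zip(web.seed_nodes["taxon"], web.seed_nodes["mass_mg"]))
        dens = dict(zip(web.seed_nodes["taxon"], web.seed_nodes["density"]))
        for taxon, p in web.P.items():
            pressure_rows.append(
                {
                    "field_id": web.field_id,
                    "seed_taxon": taxon,
                    "seed_mass_mg": masses[taxon],
                    "D_i": dens[taxon],
                    "P_i": float(p),
                }
            )
    metrics = pd.DataFrame(
        metric_rows,
        columns=["field_id", "network_size", "weighted_connectance",
                 "binary_connectance", "total_flow"],
    )
    pressure = pd.DataFrame(
        pressure_rows,
        columns=["field_id", "seed_taxon", "seed_mass_mg", "D_i", "P_i"],
    )
    return metrics, pressure
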