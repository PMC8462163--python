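"""CSV schemas, validated readers, deterministic writers, run manifests.

All tables are UTF-8 comma-separated with a header row. Floats are
written with 9 significant digits so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .traits import FieldCensus
from .webs import BipartiteWeb

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.9g"

SEED_TRAIT_COLUMNS = {"genus", "seed_mass_mg"}
CARABID_TRAIT_COLUMNS = {"species", "tribe", "genus", "length_min_mm", "length_max_mm"}
CENSUS_COLUMNS = {"field_id", "taxon_type", "taxon_id", "count"}
CAFETERIA_COLUMNS = {"study_id", "carabid_species", "carabid_mass_mg",
                     "seed_species", "seed_mass_mg"}


class SchemaError(ValueError):
    """An input table violates its declared schema."""


def _read_csv(path, required: set[str], name: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{name} file {path} is empty (header row required)")
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{name} file {path} missing columns: {sorted(missing)}")
    return df


def read_seed_traits(path) -> pd.DataFrame:
    """Seed trait CSV: genus,species,seed_mass_mg,energy_kJ_per_g (last two optional)."""
    df = _read_csv(path, SEED_TRAIT_COLUMNS, "seed trait")
    bad = df.index[~(df["seed_mass_mg"] > 0)]
    if len(bad):
        raise SchemaError(f"seed trait rows with non-positive mass: lines "
                          f"{[int(i) + 2 for i in bad]}")
    return df


def read_carabid_traits(path) -> pd.DataFrame:
    """Carabid trait CSV: species,tribe,genus,length_min_mm,length_max_mm."""
    df = _read_csv(path, CARABID_TRAIT_COLUMNS, "carabid trait")
    bad = df.index[~((df["length_min_mm"] > 0)
                     & (df["length_min_mm"] <= df["length_max_mm"]))]
    if len(bad):
        raise SchemaError(f"carabid trait rows violating 0 < min <= max length: "
                          f"lines {[int(i) + 2 for i in bad]}")
    return df


def read_census(path) -> list[FieldCensus]:
    """Long-form census CSV: field_id,taxon_type{seed|carabid},taxon_id,count."""
    df = _read_csv(path, CENSUS_COLUMNS, "census")
    bad_type = df.index[~df["taxon_type"].isin(["seed", "carabid"])]
    if len(bad_type):
        raise SchemaError(f"census rows with taxon_type not in {{seed,carabid}}: "
                          f"lines {[int(i) + 2 for i in bad_type]}")
    bad_count = df.index[df["count"] < 0]
    if len(bad_count):
        raise SchemaError(f"census rows with negative counts: "
                          f"lines {[int(i) + 2 for i in bad_count]}")
    censuses = []
    for field_id, grp in df.groupby("field_id", sort=True):
        seeds = grp[grp["taxon_type"] == "seed"]
        carabids = grp[grp["taxon_type"] == "carabid"]
        censuses.append(
            FieldCensus(
                field_id=str(field_id),
                seed_counts=dict(zip(seeds["taxon_id"], seeds["count"].astype(float))),
                carabid_counts=dict(zip(carabids["taxon_id"],
                                        carabids["count"].astype(float))),
            )
        )
    return censuses


def read_cafeteria(path) -> pd.DataFrame:
    """Cafeteria CSV; derives consumption_per_day from (n_seeds_offered, ct50_days)
    where absent, and seed_energy_kJ from seed_energy_kJ_per_g where given."""
    df = _read_csv(path, CAFETERIA_COLUMNS, "cafeteria")
    if "consumption_per_day" not in df.columns:
        df["consumption_per_day"] = np.nan
    needs = df["consumption_per_day"].isna()
    if needs.any():
        if not {"n_seeds_offered", "ct50_days"} <= set(df.columns):
            raise SchemaError(
                "cafeteria rows lack consumption_per_day and no "
                "(n_seeds_offered, ct50_days) columns to derive it: lines "
                f"{[int(i) + 2 for i in df.index[needs]]}"
            )
        ok = needs & df["n_seeds_offered"].notna() & df["ct50_days"].notna()
        still = needs & ~ok
        if still.any():
            raise SchemaError(
                "cafeteria rows with neither consumption_per_day nor complete "
                f"(n_seeds_offered, ct50_days): lines {[int(i) + 2 for i in df.index[still]]}"
            )
        if (df.loc[ok, "ct50_days"] <= 0).any():
            raise SchemaError("ct50_days must be > 0")
        df.loc[ok, "consumption_per_day"] = (
            0.5 * df.loc[ok, "n_seeds_offered"] / df.loc[ok, "ct50_days"]
        )
    if "seed_energy_kJ" not in df.columns:
        if "seed_energy_kJ_per_g" not in df.columns:
            raise SchemaError("cafeteria file needs seed_energy_kJ or seed_energy_kJ_per_g")
        df["seed_energy_kJ"] = df["seed_mass_mg"] / 1000.0 * df["seed_energy_kJ_per_g"]
    if (df["consumption_per_day"] <= 0).any():
        raise SchemaError("consumption_per_day must be > 0 to derive costs")
    return df


def _write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_web_outputs(web: BipartiteWeb, out_dir) -> None:
    """Edge list, node table and adjacency matrix for one field."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    edges = (
        web.I.stack()
        .rename("I")
        .reset_index()
        .rename(columns={"seed": "seed_taxon", "carabid": "carabid_species"})
    )
    edges.insert(0, "field_id", web.field_id)
    _write_csv(edges, out / f"{web.field_id}_edges.csv")

    seed_nodes = web.seed_nodes.rename(columns={"taxon": "taxon"}).copy()
    seed_nodes.insert(0, "node_type", "seed")
    seed_nodes["guild"] = ""
    carabid_nodes = web.carabid_nodes.rename(columns={"species": "taxon"}).copy()
    carabid_nodes.insert(0, "node_type", "carabid")
    cols = ["field_id", "node_type", "taxon", "density", "mass_mg", "guild"]
    nodes = pd.concat([seed_nodes, carabid_nodes], ignore_index=True)
    nodes.insert(0, "field_id", web.field_id)
    _write_csv(nodes[cols], out / f"{web.field_id}_nodes.csv")

    adj = web.I.copy()
    adj.insert(0, "seed_taxon", adj.index)
    adj.to_csv(out / f"{web.field_id}_adjacency.csv", index=False,
               float_format=FLOAT_FMT)


def write_graphml(web: BipartiteWeb, path) -> None:
    import networkx as nx

    nx.write_graphml(web.to_networkx(), path)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir,
    config: PipelineConfig,
    inputs: Mapping[str, str],
    rng_seed: Optional[int] = None,
    warnings: Optional[Mapping[str, list[str]]] = None,
) -> Path:
    """Record config, input digests, package version and warnings."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "inputs": {name: sha256_of(p) for name, p in inputs.items()},
        "rng_seed": rng_seed,
        "warnings": dict(warnings or {}),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")
    return path
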