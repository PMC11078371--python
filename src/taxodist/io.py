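"""Readers and writers for the three input tables and pipeline artifacts.

Conventions: coordinates are decimal degrees, WGS84 assumed, west
longitudes negative.  Occurrence data may be long form (``station,
species`` columns, one row per occurrence) or a wide station x species
0/1 matrix; the reader auto-detects the layout from the header.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .taxonomy import RANKS, MissingSpeciesError, TaxonomyError, validate_taxonomy

__all__ = [
    "read_taxonomy",
    "read_occurrence",
    "read_stations",
    "read_square_matrix",
    "write_square_matrix",
    "cross_validate_inputs",
]

log = logging.getLogger("taxodist")

STATION_COLUMNS = ("latitude", "longitude")


def read_taxonomy(path) -> pd.DataFrame:
    """Read and validate a taxonomy CSV with species,genus,family,class."""
    table = pd.read_csv(path)
    table.columns = [c.strip().lower() for c in table.columns]
    extra = [c for c in table.columns if c not in RANKS]
    if extra:
        log.warning("taxonomy %s: ignoring extra columns %s", path, extra)
    return validate_taxonomy(table[[c for c in RANKS if c in table.columns]])


def read_occurrence(path) -> pd.DataFrame:
    """Read occurrences; returns a station x species 0/1 matrix.

    Long form is detected by a header consisting of exactly ``station``
    and ``species`` (case-insensitive); anything else is treated as a
    wide matrix whose first column holds station ids.
    """
    head = pd.read_csv(path, nrows=0)
    cols = [c.strip().lower() for c in head.columns]
    if sorted(cols) == ["species", "station"]:
        long = pd.read_csv(path)
        long.columns = cols if cols == ["station", "species"] else [
            c.strip().lower() for c in long.columns
        ]
        long["station"] = long["station"].astype(str).str.strip()
        long["species"] = long["species"].astype(str).str.strip()
        wide = (
            pd.crosstab(long["station"], long["species"])
            .clip(upper=1)
            .astype(int)
        )
        wide.index.name = "station"
        # preserve first-appearance order of stations and species
        wide = wide.loc[
            long["station"].drop_duplicates(), long["species"].drop_duplicates()
        ]
        return wide
    wide = pd.read_csv(path, index_col=0)
    wide.index = wide.index.astype(str).str.strip()
    wide.index.name = "station"
    wide.columns = [str(c).strip() for c in wide.columns]
    values = wide.to_numpy()
    if not np.isin(values, (0, 1)).all():
        bad = wide.index[(~np.isin(values, (0, 1))).any(axis=1)]
        raise ValueError(
            f"wide occurrence matrix must be 0/1; offending stations: {list(bad)}"
        )
    return wide.astype(int)


def read_stations(path) -> pd.DataFrame:
    """Read the station table (index station id, latitude/longitude + env)."""
    table = pd.read_csv(path, index_col=0)
    table.index = table.index.astype(str).str.strip()
    table.index.name = "station"
    table.columns = [c.strip().lower() for c in table.columns]
    missing = [c for c in STATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"station table missing columns: {missing}")
    for col in STATION_COLUMNS:
        bad = table.index[~np.isfinite(pd.to_numeric(table[col], errors="coerce"))]
        if len(bad):
            raise ValueError(f"malformed {col} in station rows: {list(bad)}")
    if (table["latitude"].abs() > 90).any():
        raise ValueError("latitude outside [-90, 90]")
    return table


def cross_validate_inputs(
    taxonomy: pd.DataFrame,
    community: pd.DataFrame,
    stations: pd.DataFrame,
) -> None:
    """Check referential integrity between the three tables."""
    known_species = set(taxonomy["species"])
    orphans = [s for s in community.columns if s not in known_species]
    if orphans:
        raise MissingSpeciesError(
            f"occurrence species absent from taxonomy: {sorted(orphans)}"
        )
    unknown_stations = [s for s in community.index if s not in set(stations.index)]
    if unknown_stations:
        raise TaxonomyError(
            f"occurrence stations absent from station table: {sorted(unknown_stations)}"
        )


def read_inputs(config) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Load and cross-validate the three input tables from a config."""
    taxonomy = read_taxonomy(config.taxonomy_path)
    community = read_occurrence(config.occurrence_path)
    stations = read_stations(config.stations_path)
    cross_validate_inputs(taxonomy, community, stations)
    stations = stations.loc[community.index]
    return taxonomy, community, stations


def write_square_matrix(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path)


def read_square_matrix(path) -> pd.DataFrame:
    frame = pd.read_csv(path, index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = [str(c) for c in frame.columns]
    if list(frame.index) != list(frame.columns):
        raise ValueError(f"{path}: square matrix must have matching row/column ids")
    return frame


def empty_station_filter(community: pd.DataFrame) -> pd.DataFrame:
    """Drop all-zero stations with a warning (needed before theta)."""
    empty = community.index[community.sum(axis=1) == 0]
    if len(empty):
        warnings.warn(f"dropping empty stations: {list(empty)}", stacklevel=2)
        return community.drop(index=empty)
    return community
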