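"""Synthetic taxonomies, stations, environments and communities.

Ground-truth test bed for the whole pipeline: a strict-tree taxonomy of
configurable shape, stations scattered over a bounding box with a
west-east environmental gradient plus a spatially autocorrelated random
field, and presence/absence communities produced by Gaussian niche
filtering combined with a distance-decaying dispersal kernel around a
species-specific home station.  Everything is deterministic given the
scenario seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .beta_decay import geo_distance_matrix

__all__ = [
    "EnvFieldParams",
    "SyntheticScenario",
    "SyntheticTruth",
    "gen_taxonomy",
    "gen_stations_env",
    "gen_communities",
    "write_scenario",
    "default_scenario",
]


@dataclass(frozen=True)
class EnvFieldParams:
    """Parameters of one synthetic environmental variable.

    The field is ``offset + gradient * (lon - lon_mid) + G + e`` where G
    is a zero-mean Gaussian field with exponential covariance
    ``sd**2 * exp(-d / range_km)`` and e is white noise.
    """

    offset: float = 0.0
    gradient_per_degree: float = 0.0  # west-east trend per degree longitude
    autocorr_sd: float = 1.0
    autocorr_range_km: float = 100.0
    noise_sd: float = 0.1
    logistic: bool = False  # squash through a logistic to [0, 1] (fractions)


@dataclass
class SyntheticScenario:
    """Everything needed to generate one synthetic data set."""

    n_species: int = 173
    n_genera: int = 110
    n_families: int = 40
    class_name: str = "Polychaeta"
    n_stations: int = 61
    # study-area-like bounding box: lon west negative
    lon_range: tuple[float, float] = (-97.1, -89.7)
    lat_range: tuple[float, float] = (18.5, 22.3)
    env_fields: dict[str, EnvFieldParams] = field(
        default_factory=lambda: {
            "depth": EnvFieldParams(
                offset=90.0, gradient_per_degree=5.0, autocorr_sd=30.0,
                autocorr_range_km=150.0, noise_sd=5.0,
            ),
            "temperature": EnvFieldParams(
                offset=24.0, gradient_per_degree=0.4, autocorr_sd=1.0,
                autocorr_range_km=200.0, noise_sd=0.2,
            ),
            "salinity": EnvFieldParams(
                offset=36.3, gradient_per_degree=0.05, autocorr_sd=0.25,
                autocorr_range_km=150.0, noise_sd=0.05,
            ),
            "sand": EnvFieldParams(
                offset=0.0, gradient_per_degree=0.6, autocorr_sd=0.8,
                autocorr_range_km=120.0, noise_sd=0.2, logistic=True,
            ),
        }
    )
    niche_tolerance: float | dict[str, float] = 2.0  # in env-sd units; inf = neutral
    dispersal_rate_per_km: float = 0.003  # 0 = no dispersal limitation
    baseline_logit: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_families <= self.n_genera <= self.n_species):
            raise ValueError("need n_families <= n_genera <= n_species, all >= 1")
        if self.n_stations < 1:
            raise ValueError("n_stations must be >= 1")
        if self.dispersal_rate_per_km < 0:
            raise ValueError("dispersal rate must be >= 0")
        tol = self.niche_tolerance
        tols = tol.values() if isinstance(tol, dict) else [tol]
        if any(t <= 0 for t in tols):
            raise ValueError("niche tolerances must be > 0")


@dataclass
class SyntheticTruth:
    """Generating parameters and latent quantities behind a data set."""

    scenario: SyntheticScenario
    region: pd.Series  # per-station label: terrigenous/transitional/carbonate
    occupancy_probability: pd.DataFrame  # station x species
    optima: pd.DataFrame  # species x variable (z-score units)
    home_station: pd.Series  # species -> station id


def default_scenario(**overrides) -> SyntheticScenario:
    """Scenario sized like the study system (61 stations, 173 species)."""
    return SyntheticScenario(**overrides)


def gen_taxonomy(scenario: SyntheticScenario) -> pd.DataFrame:
    """Random strict-tree taxonomy with the requested rank sizes."""
    rng = np.random.default_rng(scenario.seed)
    n_s, n_g, n_f = scenario.n_species, scenario.n_genera, scenario.n_families

    genera = [f"Genus{i + 1:03d}" for i in range(n_g)]
    families = [f"Family{i + 1:02d}" for i in range(n_f)]

    # every family gets at least one genus, every genus one species
    genus_family = np.concatenate(
        [np.arange(n_f), rng.integers(0, n_f, size=n_g - n_f)]
    )
    rng.shuffle(genus_family)
    species_genus = np.concatenate(
        [np.arange(n_g), rng.integers(0, n_g, size=n_s - n_g)]
    )
    rng.shuffle(species_genus)

    rows = []
    counter: dict[int, int] = {}
    for s in range(n_s):
        g = int(species_genus[s])
        counter[g] = counter.get(g, 0) + 1
        rows.append(
            {
                "species": f"{genera[g]} sp{counter[g]:02d}",
                "genus": genera[g],
                "family": families[int(genus_family[g])],
                "class": scenario.class_name,
            }
        )
    return pd.DataFrame(rows)


def _gaussian_field(
    dist_km: np.ndarray, sd: float, range_km: float, rng: np.random.Generator
) -> np.ndarray:
    if sd <= 0:
        return np.zeros(dist_km.shape[0])
    cov = sd**2 * np.exp(-dist_km / range_km)
    cov[np.diag_indices_from(cov)] += 1e-9 * sd**2
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal(dist_km.shape[0])


def gen_stations_env(scenario: SyntheticScenario) -> pd.DataFrame:
    """Station coordinates and environmental variables.

    Returns a DataFrame indexed by station id with ``latitude``,
    ``longitude`` and one column per environmental variable.
    """
    rng = np.random.default_rng(scenario.seed + 1)
    n = scenario.n_stations
    lon = rng.uniform(*scenario.lon_range, size=n)
    lat = rng.uniform(*scenario.lat_range, size=n)
    ids = [f"st{i + 1:03d}" for i in range(n)]
    out = pd.DataFrame({"latitude": lat, "longitude": lon}, index=ids)
    out.index.name = "station"

    dist = geo_distance_matrix(out).to_numpy()
    lon_mid = np.mean(scenario.lon_range)
    for name, p in scenario.env_fields.items():
        fieldv = (
            p.offset
            + p.gradient_per_degree * (lon - lon_mid)
            + _gaussian_field(dist, p.autocorr_sd, p.autocorr_range_km, rng)
            + p.noise_sd * rng.standard_normal(n)
        )
        out[name] = expit(fieldv) if p.logistic else fieldv
    return out


def _region_labels(stations: pd.DataFrame, scenario: SyntheticScenario) -> pd.Series:
    lo, hi = scenario.lon_range
    edges = [lo + (hi - lo) / 3, lo + 2 * (hi - lo) / 3]
    lab = np.where(
        stations["longitude"] < edges[0],
        "terrigenous",
        np.where(stations["longitude"] < edges[1], "transitional", "carbonate"),
    )
    return pd.Series(lab, index=stations.index, name="region")


def gen_communities(
    taxonomy: pd.DataFrame,
    stations: pd.DataFrame,
    scenario: SyntheticScenario,
    max_attempts: int = 10,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Presence/absence communities from niches plus dispersal limitation.

    Occupancy probability of species s at station k is

        logistic(baseline - sum_v (z_vk - opt_sv)^2 / (2 tol_v^2)
                 - rate * d(k, home_s))

    on z-scored environmental variables.  Draws are Bernoulli; if any
    station ends up empty the draw is repeated (scenario unchanged) up
    to ``max_attempts`` times.
    """
    rng = np.random.default_rng(scenario.seed + 2)
    species = list(taxonomy["species"])
    env_cols = [c for c in stations.columns if c not in ("latitude", "longitude")]
    env = stations[env_cols].to_numpy(dtype=float)
    sd = env.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (env - env.mean(axis=0)) / sd

    tol = scenario.niche_tolerance
    tols = np.array(
        [tol[c] if isinstance(tol, dict) else tol for c in env_cols], dtype=float
    )

    n_st, n_sp = len(stations), len(species)
    optima = rng.uniform(-2.0, 2.0, size=(n_sp, len(env_cols)))
    home_idx = rng.integers(0, n_st, size=n_sp)
    dist = geo_distance_matrix(stations).to_numpy()

    with np.errstate(over="ignore"):
        penalty = np.zeros((n_st, n_sp))
        finite = np.isfinite(tols)
        if finite.any():
            zf = z[:, finite]
            of = optima[:, finite]
            tf = tols[finite]
            penalty = (
                ((zf[:, None, :] - of[None, :, :]) ** 2) / (2 * tf**2)
            ).sum(axis=2)
    dispersal = scenario.dispersal_rate_per_km * dist[:, home_idx]
    prob = expit(scenario.baseline_logit - penalty - dispersal)

    occ = None
    for attempt in range(max_attempts):
        draw = (rng.random((n_st, n_sp)) < prob).astype(int)
        if draw.sum(axis=1).min() > 0:
            occ = draw
            break
        warnings.warn(
            f"attempt {attempt + 1}: empty station in community draw; redrawing",
            stacklevel=2,
        )
    if occ is None:
        raise RuntimeError(
            f"could not draw a community without empty stations in {max_attempts} tries"
        )

    community = pd.DataFrame(occ, index=stations.index, columns=species)
    truth = SyntheticTruth(
        scenario=scenario,
        region=_region_labels(stations, scenario),
        occupancy_probability=pd.DataFrame(
            prob, index=stations.index, columns=species
        ),
        optima=pd.DataFrame(optima, index=species, columns=env_cols),
        home_station=pd.Series(
            [stations.index[i] for i in home_idx], index=species, name="home_station"
        ),
    )
    return community, truth


def write_scenario(
    out_dir: str | Path,
    scenario: SyntheticScenario | None = None,
) -> dict[str, Path]:
    """Generate a full data set and write the three input CSVs + truth JSON."""
    scenario = scenario or default_scenario()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    taxonomy = gen_taxonomy(scenario)
    stations = gen_stations_env(scenario)
    community, truth = gen_communities(taxonomy, stations, scenario)

    paths = {
        "taxonomy": out / "taxonomy.csv",
        "stations": out / "stations.csv",
        "occurrence": out / "occurrence.csv",
        "truth": out / "truth.json",
    }
    taxonomy.to_csv(paths["taxonomy"], index=False)
    stations.to_csv(paths["stations"])
    community.to_csv(paths["occurrence"])
    payload = {
        "scenario": asdict(scenario),
        "region": truth.region.to_dict(),
        "home_station": truth.home_station.to_dict(),
    }
    paths["truth"].write_text(json.dumps(payload, indent=2, default=str))
    return paths
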