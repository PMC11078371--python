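"""Average taxonomic distinctness, its variation, and randomization funnels.

For a set of S species with pairwise path lengths ``omega``:

* the average distinctness is the mean of ``omega`` over all unordered
  pairs;
* its variation is the mean squared deviation of the pairwise path
  lengths from that average (the unsquared mean deviation is identically
  zero, so only the squared form carries information).

Both are undefined for fewer than two species.

The randomization funnel draws, for each subset size m, many random
species subsets from a master list, computes the statistic for each, and
records the empirical mean and central ``1 - alpha`` percentile band.
Observed stations are then classified as below / inside / above the band
at their own richness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .taxonomy import PathLengthMatrix

__all__ = [
    "UndefinedStatisticError",
    "delta_plus",
    "lambda_plus",
    "distinctness_table",
    "FunnelResult",
    "build_funnel",
    "classify_stations",
]

STATISTICS = ("delta_plus", "lambda_plus")


class UndefinedStatisticError(ValueError):
    """Raised when a distinctness statistic is requested for S < 2."""


def _pair_values(species_set, omega: PathLengthMatrix) -> np.ndarray:
    names = list(dict.fromkeys(species_set))  # de-duplicate, keep order
    if len(names) < 2:
        raise UndefinedStatisticError(
            f"need at least 2 distinct species, got {len(names)}"
        )
    sub = omega.submatrix(names)
    iu = np.triu_indices(len(names), k=1)
    return sub[iu]


def delta_plus(species_set, omega: PathLengthMatrix) -> float:
    """Mean pairwise taxonomic path length over all unordered pairs."""
    return float(_pair_values(species_set, omega).mean())


def lambda_plus(species_set, omega: PathLengthMatrix) -> float:
    """Mean squared deviation of pairwise path lengths from their mean."""
    w = _pair_values(species_set, omega)
    return float(((w - w.mean()) ** 2).mean())


def _stats_from_indices(idx: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    sub = values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    w = sub[iu]
    d = w.mean()
    return float(d), float(((w - d) ** 2).mean())


def distinctness_table(
    community: pd.DataFrame, omega: PathLengthMatrix
) -> pd.DataFrame:
    """Per-station richness and distinctness statistics.

    Parameters
    ----------
    community : DataFrame
        Station x species presence/absence matrix (0/1), stations as index.
    omega : PathLengthMatrix

    Returns
    -------
    DataFrame with columns ``S, delta_plus, lambda_plus`` indexed by
    station.  Stations with S < 2 get NaN statistics and are reported,
    not dropped.
    """
    cols = omega.indices(list(community.columns))
    values = omega.values
    records = []
    for station, row in community.iterrows():
        present = cols[row.to_numpy().astype(bool)]
        s = len(present)
        if s < 2:
            warnings.warn(
                f"station {station!r} has {s} species; "
                "distinctness undefined, reported as NaN",
                stacklevel=2,
            )
            records.append((station, s, np.nan, np.nan))
        else:
            d, lam = _stats_from_indices(present, values)
            records.append((station, s, d, lam))
    return pd.DataFrame.from_records(
        records, columns=["station", "S", "delta_plus", "lambda_plus"]
    ).set_index("station")


@dataclass
class FunnelResult:
    """Simulated null envelope of a distinctness statistic vs richness."""

    statistic: str
    m: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    full_value: float
    n_sim: int
    alpha: float
    seed: int | None
    master_size: int = field(default=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"m": self.m, "mean": self.mean, "lower": self.lower, "upper": self.upper}
        )


def build_funnel(
    omega: PathLengthMatrix,
    statistic: str = "delta_plus",
    m_grid=None,
    n_sim: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> FunnelResult:
    """Simulate the null envelope of a distinctness statistic.

    For each subset size m, draws ``n_sim`` subsets uniformly without
    replacement from the master species list behind ``omega`` and records
    the empirical mean and the central ``1 - alpha`` percentile band.
    Deterministic for a fixed ``seed``.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")
    s_total = len(omega.species)
    if m_grid is None:
        m_grid = np.arange(2, s_total + 1)
    m_grid = np.asarray(sorted(set(int(m) for m in m_grid)))
    if m_grid.min() < 2 or m_grid.max() > s_total:
        raise ValueError(
            f"m_grid must lie within [2, {s_total}], got "
            f"[{m_grid.min()}, {m_grid.max()}]"
        )
    if n_sim < 100:
        warnings.warn(f"n_sim={n_sim} < 100; funnel limits will be noisy", stacklevel=2)

    rng = np.random.default_rng(seed)
    values = omega.values
    which = 0 if statistic == "delta_plus" else 1
    full = _stats_from_indices(np.arange(s_total), values)[which]

    q = (100 * alpha / 2, 100 * (1 - alpha / 2))
    means, lowers, uppers = [], [], []
    for m in m_grid:
        if m == s_total:  # single possible subset: zero-width funnel
            means.append(full)
            lowers.append(full)
            uppers.append(full)
            continue
        sims = np.empty(n_sim)
        for k in range(n_sim):
            idx = rng.choice(s_total, size=m, replace=False)
            sims[k] = _stats_from_indices(idx, values)[which]
        lo, hi = np.percentile(sims, q)
        means.append(sims.mean())
        lowers.append(lo)
        uppers.append(hi)

    return FunnelResult(
        statistic=statistic,
        m=m_grid,
        mean=np.asarray(means),
        lower=np.asarray(lowers),
        upper=np.asarray(uppers),
        full_value=full,
        n_sim=n_sim,
        alpha=alpha,
        seed=seed,
        master_size=s_total,
    )


def classify_stations(
    results: pd.DataFrame, funnel: FunnelResult
) -> pd.Series:
    """Label each station below / inside / above the funnel band.

    ``results`` is the output of :func:`distinctness_table`.  Funnel
    limits are interpolated linearly between grid points.  Stations with
    undefined statistics (S < 2) are labelled NaN.
    """
    if funnel.statistic not in results.columns:
        raise ValueError(
            f"results lack column for funnel statistic {funnel.statistic!r}"
        )
    labels = {}
    for station, row in results.iterrows():
        s, v = row["S"], row[funnel.statistic]
        if not np.isfinite(v):
            labels[station] = np.nan
            continue
        if s < funnel.m.min() or s > funnel.m.max():
            raise ValueError(
                f"station {station!r} richness {s} outside funnel grid "
                f"[{funnel.m.min()}, {funnel.m.max()}]; rebuild the funnel "
                "with a wider m_grid"
            )
        lo = float(np.interp(s, funnel.m, funnel.lower))
        hi = float(np.interp(s, funnel.m, funnel.upper))
        labels[station] = "below" if v < lo else ("above" if v > hi else "inside")
    return pd.Series(labels, name=f"{funnel.statistic}_funnel")
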