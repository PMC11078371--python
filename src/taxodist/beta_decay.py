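"""Taxonomic dissimilarity between stations and its decay with distance.

The between-station dissimilarity is a presence/absence beta-diversity
coefficient: each species in one sample is matched to its taxonomically
nearest relative in the other sample, and the directed minima are pooled
over both samples,

    theta(A, B) = (sum_{i in A} min_{j in B} w_ij
                   + sum_{j in B} min_{i in A} w_ij) / (S_A + S_B).

Shared species contribute zero, so theta(A, A) = 0, and theta is bounded
by the maximum path length.  A ``mean_of_directed`` variant averaging the
two directed means is available as an option.

Distance decay is modelled as dissimilarity = a * exp(b * d): a Gaussian
GLM with log link fitted by iteratively reweighted least squares on all
unordered station pairs, with a station-level bootstrap for the
coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .taxonomy import PathLengthMatrix

__all__ = [
    "theta_plus",
    "theta_matrix",
    "haversine_km",
    "geo_distance_matrix",
    "DecayFit",
    "fit_decay",
    "bootstrap_decay",
    "pairs_long_form",
]

EARTH_RADIUS_KM = 6371.0


def theta_plus(
    sample_a,
    sample_b,
    omega: PathLengthMatrix,
    form: str = "pooled",
) -> float:
    """Taxonomic dissimilarity between two species sets.

    Parameters
    ----------
    sample_a, sample_b : iterable of str
        Species present in each sample; must be non-empty.
    form : {"pooled", "mean_of_directed"}
        ``pooled`` divides the summed directed minima by S_A + S_B;
        ``mean_of_directed`` averages the two directed means.
    """
    a = list(dict.fromkeys(sample_a))
    b = list(dict.fromkeys(sample_b))
    if not a or not b:
        raise ValueError("theta_plus undefined for an empty sample")
    ia = omega.indices(a)
    ib = omega.indices(b)
    cross = omega.values[np.ix_(ia, ib)]
    a_min = cross.min(axis=1)
    b_min = cross.min(axis=0)
    if form == "pooled":
        return float((a_min.sum() + b_min.sum()) / (len(a) + len(b)))
    if form == "mean_of_directed":
        return float((a_min.mean() + b_min.mean()) / 2)
    raise ValueError(f"unknown form {form!r}")


def theta_matrix(
    community: pd.DataFrame,
    omega: PathLengthMatrix,
    form: str = "pooled",
) -> pd.DataFrame:
    """Symmetric station x station dissimilarity matrix.

    ``community`` is a station x species 0/1 matrix.  Stations with no
    species raise, as the coefficient is undefined for empty samples.
    """
    occ = community.to_numpy().astype(bool)
    empty = community.index[~occ.any(axis=1)]
    if len(empty):
        raise ValueError(f"stations with no species: {list(empty)}")
    cols = omega.indices(list(community.columns))
    values = omega.values[np.ix_(cols, cols)]
    n = len(community)
    out = np.zeros((n, n))
    sets = [np.flatnonzero(occ[i]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            cross = values[np.ix_(sets[i], sets[j])]
            a_min = cross.min(axis=1)
            b_min = cross.min(axis=0)
            if form == "pooled":
                t = (a_min.sum() + b_min.sum()) / (len(sets[i]) + len(sets[j]))
            else:
                t = (a_min.mean() + b_min.mean()) / 2
            out[i, j] = out[j, i] = t
    return pd.DataFrame(out, index=community.index, columns=community.index)


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in km (Earth radius 6371.0 km).

    Accepts scalars or broadcastable arrays of decimal degrees.
    """
    lat1, lon1, lat2, lon2 = map(np.asarray, (lat1, lon1, lat2, lon2))
    for lat in (lat1, lat2):
        if np.any(np.abs(lat) > 90):
            raise ValueError("latitude outside [-90, 90]")
    for lon in (lon1, lon2):
        if np.any(np.abs(lon) > 360):
            raise ValueError("longitude outside [-360, 360]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return d if d.shape else float(d)


def geo_distance_matrix(stations: pd.DataFrame) -> pd.DataFrame:
    """Pairwise great-circle distances (km) from a station table.

    ``stations`` must have ``latitude`` and ``longitude`` columns in
    decimal degrees (west longitudes negative), stations as index.
    """
    lat = stations["latitude"].to_numpy()
    lon = stations["longitude"].to_numpy()
    d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    d = np.asarray(d)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=stations.index, columns=stations.index)


def pairs_long_form(
    dissim: pd.DataFrame, geo: pd.DataFrame
) -> pd.DataFrame:
    """Unordered station pairs with their dissimilarity and distance."""
    if list(dissim.index) != list(geo.index):
        raise ValueError("dissimilarity and distance matrices index mismatch")
    ids = list(dissim.index)
    iu = np.triu_indices(len(ids), k=1)
    return pd.DataFrame(
        {
            "station_i": [ids[i] for i in iu[0]],
            "station_j": [ids[j] for j in iu[1]],
            "dissimilarity": dissim.to_numpy()[iu],
            "distance_km": geo.to_numpy()[iu],
        }
    )


@dataclass
class DecayFit:
    """Exponential distance-decay fit y = a * exp(b * d)."""

    a: float
    b: float
    beta: np.ndarray  # (intercept, slope) on the log-link scale
    fitted: np.ndarray
    distance: np.ndarray
    response: np.ndarray
    stations: list
    converged: bool
    n_iter: int
    deviance: float
    # populated by bootstrap_decay
    boot_a: np.ndarray | None = None
    boot_b: np.ndarray | None = None
    ci_a: tuple[float, float] | None = None
    ci_b: tuple[float, float] | None = None
    n_boot: int = 0
    seed: int | None = None
    n_degenerate_redraws: int = 0

    def predict(self, distance) -> np.ndarray:
        return self.a * np.exp(self.b * np.asarray(distance, dtype=float))


class DecayConvergenceError(RuntimeError):
    pass


def _irls_log_gaussian(
    d: np.ndarray, y: np.ndarray, tol: float = 1e-12, max_iter: int = 200
) -> tuple[np.ndarray, bool, int, float]:
    """Gaussian GLM with log link, fitted by IRLS on (1, d)."""
    X = np.column_stack([np.ones_like(d), d])
    # start from OLS on log response, guarding non-positive values
    y0 = np.clip(y, max(y[y > 0].min() * 1e-3, 1e-12) if (y > 0).any() else 1e-12, None)
    beta, *_ = np.linalg.lstsq(X, np.log(y0), rcond=None)
    dev = np.inf
    for it in range(1, max_iter + 1):
        eta = X @ beta
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        # log link, Gaussian variance: weights mu^2, working response
        # eta + (y - mu) / mu
        z = eta + (y - mu) / mu
        w = mu**2
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        new_dev = float(((y - np.exp(np.clip(X @ beta_new, -30, 30))) ** 2).sum())
        step = beta_new - beta
        beta = beta_new
        if np.abs(step).max() < tol or abs(dev - new_dev) < tol * (abs(dev) + tol):
            return beta, True, it, new_dev
        dev = new_dev
    return beta, False, max_iter, dev


def fit_decay(
    dissim: pd.DataFrame, geo: pd.DataFrame, min_pairs: int = 10
) -> DecayFit:
    """Fit the exponential decay of dissimilarity with distance.

    Fits E[y] = exp(b0 + b1 * d) over all unordered station pairs by
    iteratively reweighted least squares (Gaussian error, log link) and
    reports the response-scale intercept a = exp(b0) and slope b = b1.
    """
    pairs = pairs_long_form(dissim, geo)
    if len(pairs) < min_pairs:
        raise ValueError(f"need at least {min_pairs} pairs, got {len(pairs)}")
    d = pairs["distance_km"].to_numpy(dtype=float)
    y = pairs["dissimilarity"].to_numpy(dtype=float)
    beta, converged, n_iter, dev = _irls_log_gaussian(d, y)
    if not converged:
        raise DecayConvergenceError(
            f"IRLS did not converge in {n_iter} iterations "
            f"(deviance {dev:.6g}, beta {beta})"
        )
    return DecayFit(
        a=float(np.exp(beta[0])),
        b=float(beta[1]),
        beta=beta,
        fitted=np.exp(np.column_stack([np.ones_like(d), d]) @ beta),
        distance=d,
        response=y,
        stations=list(dissim.index),
        converged=converged,
        n_iter=n_iter,
        deviance=dev,
    )


def bootstrap_decay(
    fit: DecayFit,
    dissim: pd.DataFrame,
    geo: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> DecayFit:
    """Station-level bootstrap of the decay coefficients.

    Stations are resampled with replacement and the induced set of
    unordered pairs (between distinct resampled slots) is refitted.
    Degenerate resamples with fewer than two distinct stations are
    redrawn and counted.  Returns a copy of ``fit`` with the bootstrap
    fields populated (percentile intervals at level ``1 - alpha``).
    """
    rng = np.random.default_rng(seed)
    ids = list(dissim.index)
    n = len(ids)
    dm = dissim.to_numpy()
    gm = geo.to_numpy()
    iu = np.triu_indices(n, k=1)
    boot_a = np.empty(n_boot)
    boot_b = np.empty(n_boot)
    redraws = 0
    for k in range(n_boot):
        while True:
            take = rng.integers(0, n, size=n)
            if len(np.unique(take)) >= 2:
                break
            redraws += 1
        # pairs between distinct source stations only: a station drawn
        # twice pairs with itself on the diagonal, which is not a pair
        keep = take[iu[0]] != take[iu[1]]
        d = gm[np.ix_(take, take)][iu][keep]
        y = dm[np.ix_(take, take)][iu][keep]
        beta, converged, _, _ = _irls_log_gaussian(d, y)
        if not converged:  # keep going; flag through NaN
            boot_a[k] = np.nan
            boot_b[k] = np.nan
            continue
        boot_a[k] = np.exp(beta[0])
        boot_b[k] = beta[1]
    q = (100 * alpha / 2, 100 * (1 - alpha / 2))
    out = DecayFit(**{f: getattr(fit, f) for f in (
        "a", "b", "beta", "fitted", "distance", "response", "stations",
        "converged", "n_iter", "deviance")})
    out.boot_a = boot_a
    out.boot_b = boot_b
    out.ci_a = tuple(np.nanpercentile(boot_a, q))
    out.ci_b = tuple(np.nanpercentile(boot_b, q))
    out.n_boot = n_boot
    out.seed = seed
    out.n_degenerate_redraws = redraws
    return out
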