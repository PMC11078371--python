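"""Spatial eigenvector analysis and constrained ordination.

Pieces, in pipeline order:

* ``build_dbmem`` — distance-based Moran eigenvector maps from station
  coordinates: great-circle distances, minimum-spanning-tree truncation,
  eigen-decomposition of the double-centered truncated weight matrix,
  retaining the eigenvectors with positive spatial autocorrelation.
* ``pcoa_embed`` — principal-coordinate embedding of a dissimilarity
  matrix (positive axes, optional Lingoes correction).
* ``dbrda`` — redundancy analysis of the embedding on a constraint
  matrix, with axis percentages relative to total inertia and an
  optional permutation test.
* ``forward_select`` — forward selection with the double stopping rule
  (per-variable permutation p and a cumulative adjusted-R2 cap at the
  global model).
* ``variation_partition`` — adjusted-R2 decomposition over up to four
  explanatory blocks into all exclusive fractions plus residual, with
  permutation tests for marginal and unique fractions.
* ``partial_dbrda`` — ordination of one block after partialling out
  others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from itertools import combinations
from scipy.sparse.csgraph import minimum_spanning_tree

from .beta_decay import geo_distance_matrix

__all__ = [
    "DbmemBasis",
    "build_dbmem",
    "PcoaResult",
    "pcoa_embed",
    "OrdinationResult",
    "dbrda",
    "SelectionResult",
    "forward_select",
    "PartitionResult",
    "variation_partition",
    "partial_dbrda",
    "adjusted_r2",
]

_EIG_TOL = 1e-9


# ---------------------------------------------------------------------------
# dbMEM


@dataclass
class DbmemBasis:
    """Spatial eigenvector basis from truncated between-site distances."""

    truncation_km: float
    eigenvalues: np.ndarray  # all non-null eigenvalues, decreasing
    vectors: pd.DataFrame  # station x MEM1..MEMq, orthonormal columns
    morans_i: np.ndarray  # Moran's I per eigenvector
    retained: list[str]  # MEM names with positive autocorrelation
    n_positive: int
    n_negative: int

    def retained_vectors(self) -> pd.DataFrame:
        return self.vectors[self.retained]


def build_dbmem(stations: pd.DataFrame, truncation: float | None = None) -> DbmemBasis:
    """Construct distance-based Moran eigenvector maps.

    Parameters
    ----------
    stations : DataFrame
        Needs ``latitude``/``longitude`` columns (decimal degrees).
    truncation : float, optional
        Connection threshold in km; defaults to the longest edge of the
        minimum spanning tree of the great-circle distance matrix.

    Notes
    -----
    Weights are ``1 - (d / (4 t))**2`` for connected pairs (d <= t), zero
    otherwise; the weight matrix is double-centered and eigen-decomposed.
    Retained eigenvectors have a positive eigenvalue and Moran's I above
    its null expectation -1/(n-1).
    """
    n = len(stations)
    if n < 4:
        raise ValueError("need at least 4 stations for dbMEM")
    d = geo_distance_matrix(stations).to_numpy()
    offdiag = d[np.triu_indices(n, k=1)]
    if np.allclose(offdiag, 0.0):
        raise ValueError("all stations co-located; dbMEM undefined")
    if (offdiag < 1e-9).any():
        warnings.warn("duplicate coordinates present", stacklevel=2)

    if truncation is None:
        mst = minimum_spanning_tree(d)
        truncation = float(mst.data.max())
    t = float(truncation)
    if t <= 0:
        raise ValueError("truncation must be positive")

    w = np.where((d > 0) & (d <= t), 1.0 - (d / (4.0 * t)) ** 2, 0.0)
    np.fill_diagonal(w, 0.0)

    h = np.eye(n) - np.ones((n, n)) / n
    b = h @ w @ h
    b = (b + b.T) / 2
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = _EIG_TOL * max(1.0, np.abs(eigval).max())
    keep = np.abs(eigval) > tol
    eigval, eigvec = eigval[keep], eigvec[:, keep]

    w_sum = w.sum()
    centered = eigvec - eigvec.mean(axis=0, keepdims=True)
    morans = np.array(
        [
            n / w_sum * (v @ w @ v) / (v @ v)
            for v in centered.T
        ]
    )

    names = [f"MEM{i + 1}" for i in range(eigvec.shape[1])]
    expectation = -1.0 / (n - 1)
    retained = [
        nm
        for nm, lam, mi in zip(names, eigval, morans)
        if lam > tol and mi > expectation
    ]
    return DbmemBasis(
        truncation_km=t,
        eigenvalues=eigval,
        vectors=pd.DataFrame(eigvec, index=stations.index, columns=names),
        morans_i=morans,
        retained=retained,
        n_positive=int((eigval > tol).sum()),
        n_negative=int((eigval < -tol).sum()),
    )


# ---------------------------------------------------------------------------
# PCoA embedding


@dataclass
class PcoaResult:
    """Principal-coordinate embedding of a dissimilarity matrix."""

    coordinates: pd.DataFrame  # station x retained axes, scaled by sqrt(eig)
    eigenvalues: np.ndarray  # full spectrum, decreasing
    total_inertia: float  # sum of retained (positive) eigenvalues
    correction: str | None = None


def pcoa_embed(dissim: pd.DataFrame, correction: str | None = None) -> PcoaResult:
    """Gower-centered eigen-embedding of a dissimilarity matrix.

    By default only positive-eigenvalue axes are kept; ``correction=
    "lingoes"`` adds the constant that makes all eigenvalues
    non-negative before retaining axes.
    """
    d = dissim.to_numpy(dtype=float)
    n = d.shape[0]
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")

    def _gower(dm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a = -0.5 * dm**2
        h = np.eye(n) - np.ones((n, n)) / n
        g = h @ a @ h
        g = (g + g.T) / 2
        ev, evec = np.linalg.eigh(g)
        order = np.argsort(ev)[::-1]
        return ev[order], evec[:, order]

    eigval, eigvec = _gower(d)
    if correction == "lingoes" and eigval[-1] < -_EIG_TOL:
        c = -eigval[-1]
        d2 = d**2 + 2 * c
        np.fill_diagonal(d2, 0.0)
        eigval, eigvec = _gower(np.sqrt(d2))
    elif correction not in (None, "lingoes"):
        raise ValueError(f"unknown correction {correction!r}")

    tol = _EIG_TOL * max(1.0, np.abs(eigval).max())
    pos = eigval > tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    axes = [f"PCo{i + 1}" for i in range(pos.sum())]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=dissim.index, columns=axes),
        eigenvalues=eigval,
        total_inertia=float(eigval[pos].sum()),
        correction=correction,
    )


# ---------------------------------------------------------------------------
# constrained ordination


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel adjustment for m predictors on n observations."""
    if n - m - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def _as_matrix(x) -> np.ndarray:
    arr = x.to_numpy(dtype=float) if isinstance(x, pd.DataFrame) else np.asarray(x, float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=0, keepdims=True)


def _fit_r2(y: np.ndarray, x: np.ndarray, total: float) -> tuple[np.ndarray, float, int]:
    """Project y on span of centered x; return fitted values, R2, rank."""
    xc = _center(x)
    q, r = np.linalg.qr(xc)
    diag = np.abs(np.diag(r))
    rank_tol = max(xc.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0)
    keep = diag > rank_tol
    q = q[:, keep]
    fitted = q @ (q.T @ y)
    return fitted, float((fitted**2).sum() / total), int(keep.sum())


@dataclass
class OrdinationResult:
    """Constrained ordination of a dissimilarity embedding."""

    eigenvalues: np.ndarray  # constrained axis eigenvalues
    axis_percent: np.ndarray  # % of total inertia per constrained axis
    site_scores: pd.DataFrame
    biplot_scores: pd.DataFrame
    r2: float
    adj_r2: float
    total_inertia: float
    rank: int
    pseudo_f: float | None = None
    p: float | None = None
    n_perm: int = 0
    seed: int | None = None
    conditioned_r2: float = 0.0


def _constrained_axes(fitted: np.ndarray, total: float):
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    eig = s**2
    keep = eig > _EIG_TOL * max(1.0, eig.max() if eig.size else 1.0)
    u, s, eig = u[:, keep], s[keep], eig[keep]
    return u, s, eig, 100.0 * eig / total


def dbrda(
    dissim_or_embedding,
    constraints: pd.DataFrame,
    n_perm: int | None = None,
    seed: int | None = None,
) -> OrdinationResult:
    """Distance-based redundancy analysis.

    The dissimilarity matrix is embedded by PCoA (positive axes) and the
    embedding regressed on the centered constraint matrix; constrained
    axes are the principal axes of the fitted values, with percentages
    relative to the embedding's total inertia.  If ``n_perm`` is given, a
    permutation test of the pseudo-F statistic (free row permutation) is
    run.
    """
    emb = (
        dissim_or_embedding
        if isinstance(dissim_or_embedding, PcoaResult)
        else pcoa_embed(dissim_or_embedding)
    )
    y = emb.coordinates.to_numpy()
    total = emb.total_inertia
    x = _as_matrix(constraints)
    n = y.shape[0]
    if x.shape[0] != n:
        raise ValueError("constraints do not match stations")
    if x.shape[1] > n - 1:
        raise ValueError(f"more constraints ({x.shape[1]}) than stations - 1")

    fitted, r2, rank = _fit_r2(y, x, total)
    if r2 > 1 - 1e-10:
        warnings.warn("constraints saturate the embedding", stacklevel=2)
    u, s, eig, pct = _constrained_axes(fitted, total)

    axes = [f"dbRDA{i + 1}" for i in range(len(eig))]
    site = pd.DataFrame(u * s, index=emb.coordinates.index, columns=axes)
    xc = _center(x)
    with np.errstate(invalid="ignore", divide="ignore"):
        bip = np.array(
            [
                [np.corrcoef(xc[:, j], site[a])[0, 1] if xc[:, j].std() > 0 else 0.0
                 for a in axes]
                for j in range(x.shape[1])
            ]
        )
    cols = list(constraints.columns) if isinstance(constraints, pd.DataFrame) else [
        f"x{j + 1}" for j in range(x.shape[1])
    ]
    result = OrdinationResult(
        eigenvalues=eig,
        axis_percent=pct,
        site_scores=site,
        biplot_scores=pd.DataFrame(bip, index=cols, columns=axes),
        r2=r2,
        adj_r2=adjusted_r2(r2, n, rank),
        total_inertia=total,
        rank=rank,
    )
    if n_perm:
        denom_df = n - rank - 1
        f_obs = (r2 / rank) / ((1 - r2) / denom_df) if denom_df > 0 else np.inf
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            yp = y[rng.permutation(n)]
            _, r2p, _ = _fit_r2(yp, x, total)
            fp = (r2p / rank) / ((1 - r2p) / denom_df) if denom_df > 0 else np.inf
            if fp >= f_obs - 1e-12:
                count += 1
        result.pseudo_f = f_obs
        result.p = (1 + count) / (n_perm + 1)
        result.n_perm = n_perm
        result.seed = seed
    return result


# ---------------------------------------------------------------------------
# forward selection


@dataclass
class SelectionResult:
    selected: list[str]
    table: pd.DataFrame  # variable, r2_cum, adj_r2_cum, p
    global_r2: float
    global_adj_r2: float
    global_p: float


def _partial_f(y, x_sel: np.ndarray | None, cand: np.ndarray, total: float):
    """Partial pseudo-F of cand given selected, and the two R2 values."""
    n = y.shape[0]
    if x_sel is None or x_sel.shape[1] == 0:
        r2_old, m_old = 0.0, 0
        x_new = cand
    else:
        _, r2_old, m_old = _fit_r2(y, x_sel, total)
        x_new = np.column_stack([x_sel, cand])
    _, r2_new, m_new = _fit_r2(y, x_new, total)
    df = n - m_new - 1
    if df <= 0 or r2_new >= 1 - 1e-12:
        return np.inf, r2_new, m_new
    f = ((r2_new - r2_old) / (m_new - m_old)) / ((1 - r2_new) / df)
    return f, r2_new, m_new


def forward_select(
    dissim_or_embedding,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
    use_adj_r2_cap: bool = True,
) -> SelectionResult:
    """Forward selection of constraints with the double stopping rule.

    The global model is tested first; selection only proceeds if its
    permutation p <= alpha.  At each step the candidate giving the
    largest cumulative fit enters if its partial permutation p <= alpha
    and (optionally) the cumulative adjusted R2 stays at or below the
    global model's.  Candidates nearly collinear with the current set
    (R2 > 0.999) are skipped with a warning.
    """
    emb = (
        dissim_or_embedding
        if isinstance(dissim_or_embedding, PcoaResult)
        else pcoa_embed(dissim_or_embedding)
    )
    y = emb.coordinates.to_numpy()
    total = emb.total_inertia
    n = y.shape[0]
    rng = np.random.default_rng(seed)

    glob = dbrda(emb, candidates, n_perm=n_perm, seed=int(rng.integers(2**31)))
    if glob.p is not None and glob.p > alpha:
        return SelectionResult(
            selected=[],
            table=pd.DataFrame(columns=["variable", "r2_cum", "adj_r2_cum", "p"]),
            global_r2=glob.r2,
            global_adj_r2=glob.adj_r2,
            global_p=glob.p,
        )

    remaining = list(candidates.columns)
    selected: list[str] = []
    rows = []
    while remaining:
        x_sel = candidates[selected].to_numpy(dtype=float) if selected else None

        best = None
        usable: list[str] = []
        for name in remaining:
            cand = candidates[[name]].to_numpy(dtype=float)
            if x_sel is not None and x_sel.shape[1]:
                _, c_r2, _ = _fit_r2(cand, x_sel, float((_center(cand) ** 2).sum()) or 1.0)
                if c_r2 > 0.999:
                    warnings.warn(
                        f"candidate {name!r} collinear with selected set; skipped",
                        stacklevel=2,
                    )
                    continue
            usable.append(name)
            f, r2_new, m_new = _partial_f(y, x_sel, cand, total)
            if best is None or r2_new > best[2]:
                best = (name, f, r2_new, m_new)
        if best is None:
            break
        name, f_obs, r2_new, m_new = best

        # permutation test under the reduced model; the null statistic is
        # the MAX partial F over candidates, accounting for picking the
        # best one (otherwise the step-wise error rate inflates)
        if x_sel is not None and x_sel.shape[1]:
            q, _, _ = np.linalg.svd(_center(x_sel), full_matrices=False)
            proj = q @ (q.T @ y)
            y_res = y - proj
        else:
            proj = None
            y_res = y
        cand_mats = {nm: candidates[[nm]].to_numpy(dtype=float) for nm in usable}
        count = 0
        for _ in range(n_perm):
            yp = y_res[rng.permutation(n)]
            if proj is not None:
                yp = yp + proj
            fp_max = -np.inf
            for nm in usable:
                fp, _, _ = _partial_f(yp, x_sel, cand_mats[nm], total)
                if fp > fp_max:
                    fp_max = fp
            if fp_max >= f_obs - 1e-12:
                count += 1
        p = (1 + count) / (n_perm + 1)
        adj = adjusted_r2(r2_new, n, m_new)

        if p > alpha:
            break
        selected.append(name)
        remaining.remove(name)
        rows.append((name, r2_new, adj, p))
        # significant variables enter; selection stops once the
        # cumulative adjusted R2 reaches the global model's
        if use_adj_r2_cap and adj > glob.adj_r2 + 1e-12:
            break

    return SelectionResult(
        selected=selected,
        table=pd.DataFrame(rows, columns=["variable", "r2_cum", "adj_r2_cum", "p"]),
        global_r2=glob.r2,
        global_adj_r2=glob.adj_r2,
        global_p=glob.p if glob.p is not None else np.nan,
    )


# ---------------------------------------------------------------------------
# variation partitioning


@dataclass
class PartitionResult:
    """Adjusted-R2 decomposition over explanatory blocks.

    ``fractions`` holds one row per exclusive cell (unique fractions and
    every shared intersection, named by the blocks joined with ``&``)
    plus ``residual``; testable rows carry a permutation p.  ``unions``
    holds the adjusted R2 of every union of blocks actually fitted.
    """

    fractions: pd.DataFrame
    unions: pd.DataFrame
    block_names: list[str]

    def unique(self, block: str) -> float:
        return float(self.fractions.loc[block, "adj_r2"])


def variation_partition(
    dissim_or_embedding,
    blocks: dict[str, pd.DataFrame],
    n_perm: int = 999,
    seed: int | None = None,
) -> PartitionResult:
    """Partition explained variation among explanatory blocks.

    Fits a dbRDA for every non-empty union of blocks, converts the
    R2 values to adjusted R2, and solves for all exclusive fractions by
    inclusion-exclusion.  Marginal fractions (each block alone) and
    unique fractions (each block given all others) get permutation p
    values; shared fractions are not individually testable.
    """
    blocks = {k: v for k, v in blocks.items() if v is not None and v.shape[1] > 0}
    names = list(blocks)
    if not names:
        raise ValueError("no non-empty blocks given")
    emb = (
        dissim_or_embedding
        if isinstance(dissim_or_embedding, PcoaResult)
        else pcoa_embed(dissim_or_embedding)
    )
    y = emb.coordinates.to_numpy()
    total = emb.total_inertia
    n = y.shape[0]
    rng = np.random.default_rng(seed)

    # adjusted R2 for every union of blocks
    adj: dict[frozenset, float] = {frozenset(): 0.0}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            x = np.column_stack([_as_matrix(blocks[b]) for b in combo])
            _, r2, rank = _fit_r2(y, x, total)
            if rank < x.shape[1]:
                warnings.warn(
                    f"rank-deficient union {combo}: rank {rank} < {x.shape[1]} columns",
                    stacklevel=2,
                )
            a = adjusted_r2(r2, n, rank)
            if not np.isfinite(a):
                raise ValueError(f"union {combo} leaves no residual degrees of freedom")
            adj[frozenset(combo)] = a

    full = frozenset(names)
    a_full = adj[full]

    # g(W) = variation explained by cells lying entirely within W
    def g(w: frozenset) -> float:
        return a_full - adj[full - w] if w else 0.0

    fractions: dict[str, float] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            t = frozenset(combo)
            val = 0.0
            for rr in range(0, len(combo) + 1):
                for sub in combinations(combo, rr):
                    val += (-1) ** (len(combo) - rr) * g(frozenset(sub))
            fractions["&".join(combo)] = val

    rows = []
    for key, val in fractions.items():
        parts = key.split("&")
        p = np.nan
        if len(parts) == 1:
            b = parts[0]
            others = [nm for nm in names if nm != b]
            if others:
                res = partial_dbrda(
                    emb,
                    blocks[b],
                    {nm: blocks[nm] for nm in others},
                    n_perm=n_perm,
                    seed=int(rng.integers(2**31)),
                )
                p = res.p
            else:
                res = dbrda(emb, blocks[b], n_perm=n_perm, seed=int(rng.integers(2**31)))
                p = res.p
        rows.append((key, val, p))
    rows.append(("residual", 1.0 - a_full, np.nan))
    frac_df = pd.DataFrame(rows, columns=["fraction", "adj_r2", "p"]).set_index(
        "fraction"
    )

    union_rows = []
    for combo_set, val in adj.items():
        if combo_set:
            res_m = None
            if len(combo_set) == 1:
                res_m = dbrda(
                    emb, blocks[next(iter(combo_set))],
                    n_perm=n_perm, seed=int(rng.integers(2**31)),
                )
            union_rows.append(
                (
                    "&".join(sorted(combo_set, key=names.index)),
                    val,
                    res_m.p if res_m else np.nan,
                )
            )
    unions_df = pd.DataFrame(
        union_rows, columns=["union", "adj_r2", "p"]
    ).set_index("union")

    return PartitionResult(fractions=frac_df, unions=unions_df, block_names=names)


def partial_dbrda(
    dissim_or_embedding,
    focal: pd.DataFrame,
    conditioning: dict[str, pd.DataFrame] | pd.DataFrame | None,
    n_perm: int | None = None,
    seed: int | None = None,
) -> OrdinationResult:
    """dbRDA of a focal block after partialling out conditioning blocks.

    The embedding and the focal block are residualized on the
    conditioning variables; the reported R2 is semipartial (share of the
    original total inertia) and the adjusted R2 is the unique fraction
    adjR2(focal + conditioning) - adjR2(conditioning).  The permutation
    test permutes residuals of the reduced (conditioning-only) model.
    """
    emb = (
        dissim_or_embedding
        if isinstance(dissim_or_embedding, PcoaResult)
        else pcoa_embed(dissim_or_embedding)
    )
    y = emb.coordinates.to_numpy()
    total = emb.total_inertia
    n = y.shape[0]

    if conditioning is None:
        z = None
    elif isinstance(conditioning, dict):
        mats = [_as_matrix(v) for v in conditioning.values() if v is not None]
        z = np.column_stack(mats) if mats else None
    else:
        z = _as_matrix(conditioning)

    if z is None or z.shape[1] == 0:
        return dbrda(emb, focal, n_perm=n_perm, seed=seed)

    x = _as_matrix(focal)
    zc = _center(z)
    qz, rz = np.linalg.qr(zc)
    diag = np.abs(np.diag(rz))
    rank_tol = max(zc.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0)
    qz = qz[:, diag > rank_tol]
    m_z = qz.shape[1]

    y_fit_z = qz @ (qz.T @ y)
    y_res = y - y_fit_z
    xc = _center(x)
    x_res = xc - qz @ (qz.T @ xc)
    # zero out focal columns absorbed by the conditioning variables
    col_scale = np.linalg.norm(xc, axis=0)
    col_scale[col_scale == 0] = 1.0
    absorbed = np.linalg.norm(x_res, axis=0) < 1e-8 * col_scale
    if absorbed.any():
        warnings.warn("focal block collinear with conditioning", stacklevel=2)
        x_res[:, absorbed] = 0.0

    r2_z = float((y_fit_z**2).sum() / total)
    fitted, r2_sp, rank_x = _fit_r2(y_res, x_res, total)

    u, s, eig, pct = _constrained_axes(fitted, total)
    axes = [f"dbRDA{i + 1}" for i in range(len(eig))]
    site = pd.DataFrame(u * s, index=emb.coordinates.index, columns=axes)
    cols = list(focal.columns) if isinstance(focal, pd.DataFrame) else [
        f"x{j + 1}" for j in range(x.shape[1])
    ]
    with np.errstate(invalid="ignore", divide="ignore"):
        bip = np.array(
            [
                [np.corrcoef(x_res[:, j], site[a])[0, 1] if x_res[:, j].std() > 0 else 0.0
                 for a in axes]
                for j in range(x.shape[1])
            ]
        ) if len(axes) else np.zeros((x.shape[1], 0))

    adj_unique = adjusted_r2(r2_z + r2_sp, n, m_z + rank_x) - adjusted_r2(r2_z, n, m_z)

    result = OrdinationResult(
        eigenvalues=eig,
        axis_percent=pct,
        site_scores=site,
        biplot_scores=pd.DataFrame(bip, index=cols, columns=axes),
        r2=r2_sp,
        adj_r2=adj_unique,
        total_inertia=total,
        rank=rank_x,
        conditioned_r2=r2_z,
    )
    if n_perm:
        df = n - m_z - rank_x - 1
        f_obs = (
            (r2_sp / max(rank_x, 1)) / ((1 - r2_z - r2_sp) / df) if df > 0 else np.inf
        )
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            yp = y_fit_z + y_res[rng.permutation(n)]
            yp_fit_z = qz @ (qz.T @ yp)
            yp_res = yp - yp_fit_z
            r2_zp = float((yp_fit_z**2).sum() / total)
            _, r2_spp, _ = _fit_r2(yp_res, x_res, total)
            fp = (
                (r2_spp / max(rank_x, 1)) / ((1 - r2_zp - r2_spp) / df)
                if df > 0
                else np.inf
            )
            if fp >= f_obs - 1e-12:
                count += 1
        result.pseudo_f = f_obs
        result.p = (1 + count) / (n_perm + 1)
        result.n_perm = n_perm
        result.seed = seed
    return result
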