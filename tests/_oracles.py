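"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written with plain Python loops and
direct formulas, separate from the package implementation paths.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def omega_equal_steps(lineage_a: tuple, lineage_b: tuple, scale_max: float = 100.0) -> float:
    """Path length for equal step weights: (genus, family) lineages."""
    if lineage_a == lineage_b and lineage_a[0] == lineage_b[0]:
        pass
    if lineage_a[0] == lineage_b[0]:
        steps = 1
    elif lineage_a[1] == lineage_b[1]:
        steps = 2
    else:
        steps = 3
    return steps * scale_max / 3.0


def delta_brute(species: list, omega_lookup) -> float:
    pairs = list(combinations(species, 2))
    total = 0.0
    for a, b in pairs:
        total += omega_lookup(a, b)
    return total / len(pairs)


def lambda_brute(species: list, omega_lookup) -> float:
    pairs = list(combinations(species, 2))
    d = delta_brute(species, omega_lookup)
    total = 0.0
    for a, b in pairs:
        total += (omega_lookup(a, b) - d) ** 2
    return total / len(pairs)


def theta_brute(sample_a: list, sample_b: list, omega_lookup) -> float:
    total = 0.0
    for a in sample_a:
        total += min(omega_lookup(a, b) for b in sample_b)
    for b in sample_b:
        total += min(omega_lookup(a, b) for a in sample_a)
    return total / (len(sample_a) + len(sample_b))


def midranks(values: np.ndarray) -> np.ndarray:
    """Midranks computed by explicit tie grouping."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def anosim_r_brute(dist: np.ndarray, labels: np.ndarray) -> float:
    n = dist.shape[0]
    vals, within = [], []
    for i in range(n):
        for j in range(i + 1, n):
            vals.append(dist[i, j])
            within.append(labels[i] == labels[j])
    ranks = midranks(np.asarray(vals))
    within = np.asarray(within)
    m = len(vals)
    return (ranks[~within].mean() - ranks[within].mean()) / (m / 2)


def gaussian_log_deviance(beta: np.ndarray, d: np.ndarray, y: np.ndarray) -> float:
    return float(((y - np.exp(beta[0] + beta[1] * d)) ** 2).sum())


def rda_axis_percents(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Classical RDA axis percentages by direct least squares + eigen."""
    yc = y - y.mean(axis=0)
    xc = x - x.mean(axis=0)
    coef, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    fitted = xc @ coef
    eig = np.linalg.eigvalsh(fitted.T @ fitted)[::-1]
    eig = eig[eig > 1e-10]
    total = (yc**2).sum()
    return 100.0 * eig / total
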