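"""Mantel and partial Mantel permutation tests.

The Mantel statistic is the Pearson correlation of the off-diagonal
(upper-triangle) entries of two labelled distance matrices. The null
distribution is built by jointly permuting the rows and columns of one
matrix, which preserves the within-matrix dependence structure while
breaking the between-matrix association. For small matrices (n <= 7 sites,
n! <= 5040) the full permutation set is enumerated instead of sampled, so
the p-value is exact.

The partial Mantel statistic controls a third matrix C:

    r_12.C = (r_12 - r_1C r_2C) / sqrt((1 - r_1C^2)(1 - r_2C^2))

with the null built by permuting the first matrix and recomputing the
partial correlation (Smouse-Long-Sokal scheme).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as iter_permutations

import numpy as np

from .distmat import DistanceMatrix

__all__ = ["MantelResult", "mantel", "partial_mantel", "EXHAUSTIVE_MAX_N"]

EXHAUSTIVE_MAX_N = 7


@dataclass
class MantelResult:
    r_observed: float
    p_value: float
    n_permutations: int
    tail: str
    method: str
    controlled_matrix_label: str | None = None

    def as_dict(self) -> dict:
        return {
            "r": self.r_observed, "p": self.p_value,
            "n_permutations": self.n_permutations, "tail": self.tail,
            "method": self.method, "control": self.controlled_matrix_label,
        }


def _check_pair(d1: DistanceMatrix, d2: DistanceMatrix) -> None:
    if d1.labels != d2.labels:
        raise ValueError("distance matrices must share labels in the same order")
    if d1.n < 3:
        raise ValueError("Mantel test needs at least 3 labels")


def _triangle(values: np.ndarray, iu) -> np.ndarray:
    return values[iu]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in distance-matrix triangle")
    return float((xc * yc).sum() / (sx * sy))


def _tail_count(r_perm: np.ndarray, r_obs: float, tail: str) -> int:
    if tail == "greater":
        return int(np.sum(r_perm >= r_obs))
    if tail == "two_sided":
        return int(np.sum(np.abs(r_perm) >= abs(r_obs)))
    raise ValueError(f"unknown tail {tail!r}")


def _perm_iter(n: int, n_permutations: int, method: str, rng: np.random.Generator):
    """Yield index permutations for the null. Exhaustive includes identity."""
    if method == "exhaustive":
        yield from (np.asarray(p) for p in iter_permutations(range(n)))
    else:
        for _ in range(n_permutations):
            yield rng.permutation(n)


def _resolve_method(n: int, method: str) -> str:
    if method == "auto":
        return "exhaustive" if n <= EXHAUSTIVE_MAX_N else "sampled"
    if method not in ("exhaustive", "sampled"):
        raise ValueError(f"unknown method {method!r}")
    return method


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, n_permutations: int = 9999,
           tail: str = "greater", seed: int | None = None,
           method: str = "auto") -> MantelResult:
    """Mantel test between two labelled distance matrices.

    ``method='auto'`` enumerates all n! row/column permutations when
    n <= 7, otherwise samples ``n_permutations`` of them. The sampled
    p-value uses the add-one convention (1 + exceedances)/(perms + 1) so
    it is never zero; the exhaustive p-value is the exact tail fraction
    (the identity permutation guarantees p >= 1/n!).
    """
    _check_pair(d1, d2)
    n = d1.n
    method = _resolve_method(n, method)
    iu = np.triu_indices(n, k=1)
    x = _triangle(d1.values, iu)
    r_obs = _pearson(x, _triangle(d2.values, iu))

    rng = np.random.default_rng(seed)
    r_perm = np.fromiter(
        (_pearson(x, _triangle(d2.values[np.ix_(p, p)], iu))
         for p in _perm_iter(n, n_permutations, method, rng)),
        dtype=float,
    )
    exceed = _tail_count(r_perm, r_obs, tail)
    if method == "exhaustive":
        p = exceed / len(r_perm)
    else:
        p = (1 + exceed) / (n_permutations + 1)
    return MantelResult(r_obs, float(p), len(r_perm), tail, method)


def _partial_r(r12: float, r1c: float, r2c: float) -> float:
    denom = (1 - r1c ** 2) * (1 - r2c ** 2)
    if denom <= 0:
        raise ValueError("degenerate control matrix (|r| = 1 with a variable)")
    return (r12 - r1c * r2c) / np.sqrt(denom)


def partial_mantel(d1: DistanceMatrix, d2: DistanceMatrix,
                   d_control: DistanceMatrix, n_permutations: int = 9999,
                   tail: str = "greater", seed: int | None = None,
                   method: str = "auto") -> MantelResult:
    """Partial Mantel test of d1 vs d2 controlling for d_control.

    The null permutes d1's labels; r(d2, control) is unchanged under that
    permutation, so only r(d1, d2) and r(d1, control) are recomputed.
    """
    _check_pair(d1, d2)
    _check_pair(d1, d_control)
    n = d1.n
    method = _resolve_method(n, method)
    iu = np.triu_indices(n, k=1)
    x = _triangle(d1.values, iu)
    y = _triangle(d2.values, iu)
    c = _triangle(d_control.values, iu)
    r2c = _pearson(y, c)
    r_obs = _partial_r(_pearson(x, y), _pearson(x, c), r2c)

    rng = np.random.default_rng(seed)

    def perm_stat(p: np.ndarray) -> float:
        xp = _triangle(d1.values[np.ix_(p, p)], iu)
        return _partial_r(_pearson(xp, y), _pearson(xp, c), r2c)

    r_perm = np.fromiter(
        (perm_stat(p) for p in _perm_iter(n, n_permutations, method, rng)),
        dtype=float,
    )
    exceed = _tail_count(r_perm, r_obs, tail)
    if method == "exhaustive":
        p = exceed / len(r_perm)
    else:
        p = (1 + exceed) / (n_permutations + 1)
    return MantelResult(float(r_obs), float(p), len(r_perm), tail, method,
                        controlled_matrix_label=d_control.metric_name)
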