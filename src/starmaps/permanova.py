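"""One-way PERMANOVA on Euclidean coordinates.

The segregation engine behind every component test: Anderson's pseudo-F on
Euclidean distances, which for point coordinates reduces to the classical
between/within sums-of-squares ratio (centroid identity). Significance comes
from permuting group labels, either by exhaustive enumeration of the distinct
label assignments or by Monte Carlo sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

__all__ = ["PermanovaResult", "pseudo_f", "permanova", "n_distinct_assignments"]

# relative tolerance for counting permuted statistics as ">= observed";
# protects tie detection against floating-point jitter (e.g. after an
# orthogonal change of basis upstream)
_TIE_RTOL = 1e-9


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    mode: str  # "sampled" | "exhaustive"
    seed: int | None = None


def _encode_labels(labels: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """Labels -> integer codes (first-appearance order) and group sizes."""
    labels = np.asarray(labels)
    uniq, codes = np.unique(labels, return_inverse=True)
    sizes = np.bincount(codes, minlength=len(uniq))
    return codes, sizes


def _validate(coords: np.ndarray, codes: np.ndarray, sizes: np.ndarray) -> None:
    n = coords.shape[0]
    a = len(sizes)
    if codes.shape[0] != n:
        raise ValueError("labels length does not match number of rows")
    if a < 2:
        raise ValueError("need at least 2 groups")
    if np.any(sizes == 0):
        raise ValueError("every group needs at least one sample")
    if n <= a:
        raise ValueError("need more samples than groups")


def _f_from_group_sums(
    group_sums: np.ndarray, sizes: np.ndarray, grand_mean: np.ndarray, ss_total: float, n: int
) -> np.ndarray:
    """Vectorized pseudo-F from per-assignment group sums.

    group_sums: (m, a, k) sums of coordinates per group for m assignments.
    """
    a = len(sizes)
    means = group_sums / sizes[None, :, None]
    dev = means - grand_mean[None, None, :]
    ss_between = np.einsum("gak,gak,a->g", dev, dev, sizes.astype(float))
    ss_within = ss_total - ss_between
    df_b = a - 1
    df_w = n - a
    scale = max(ss_total, 1.0)
    f = np.empty(len(ss_between))
    degenerate = ss_within < 1e-12 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
    f[degenerate & (ss_between > 1e-12 * scale)] = np.inf
    f[degenerate & ~(ss_between > 1e-12 * scale)] = 0.0
    return f


def _stats_for_assignments(coords: np.ndarray, assignments: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Pseudo-F for each row of an (m, n) integer assignment matrix."""
    n, _ = coords.shape
    a = len(sizes)
    grand_mean = coords.mean(axis=0)
    ss_total = float(((coords - grand_mean) ** 2).sum())
    m = assignments.shape[0]
    group_sums = np.empty((m, a, coords.shape[1]))
    for g in range(a):
        group_sums[:, g, :] = (assignments == g).astype(float) @ coords
    return _f_from_group_sums(group_sums, sizes, grand_mean, ss_total, n)


def pseudo_f(coords: np.ndarray, labels: Sequence) -> float:
    """One-way PERMANOVA pseudo-F on Euclidean coordinates.

    F = (SS_between / (a-1)) / (SS_within / (n-a)). Returns ``inf`` when the
    within-group scatter is zero but groups differ, and 0 when all points
    coincide.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[0] == 1:
        coords = coords.T
    codes, sizes = _encode_labels(labels)
    _validate(coords, codes, sizes)
    return float(_stats_for_assignments(coords, codes[None, :], sizes)[0])


def n_distinct_assignments(sizes: Sequence[int]) -> int:
    """Number of distinct label assignments: multinomial(n; n_1..n_a)."""
    n = int(sum(sizes))
    out = math.factorial(n)
    for s in sizes:
        out //= math.factorial(int(s))
    return out


def _iter_assignments(sizes: np.ndarray) -> Iterator[np.ndarray]:
    """Yield every distinct assignment of the label multiset, each once."""
    n = int(sizes.sum())
    assignment = np.empty(n, dtype=np.intp)

    def rec(positions: tuple[int, ...], group: int) -> Iterator[np.ndarray]:
        if group == len(sizes) - 1:
            for p in positions:
                assignment[p] = group
            yield assignment
            return
        import itertools

        for chosen in itertools.combinations(positions, int(sizes[group])):
            for p in chosen:
                assignment[p] = group
            remaining = tuple(p for p in positions if p not in set(chosen))
            yield from rec(remaining, group + 1)

    yield from rec(tuple(range(n)), 0)


def permanova(
    coords: np.ndarray,
    labels: Sequence,
    n_perm: int = 10000,
    seed: int | None = None,
    exhaustive: bool | str = "auto",
) -> PermanovaResult:
    """Permutation test of group segregation on Euclidean coordinates.

    Exhaustive mode enumerates every distinct group-label assignment exactly
    once and reports the exact fraction with pseudo-F >= observed. Sampled
    mode draws ``n_perm`` uniform label permutations and reports
    (1 + #{F* >= F_obs}) / (n_perm + 1), counting the observed assignment in
    the null so p can never be 0. ``exhaustive="auto"`` switches to
    enumeration whenever the number of distinct assignments is <= n_perm.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[0] == 1:
        coords = coords.T
    codes, sizes = _encode_labels(labels)
    _validate(coords, codes, sizes)

    f_obs = float(_stats_for_assignments(coords, codes[None, :], sizes)[0])
    if np.isinf(f_obs):
        cutoff = np.inf
    else:
        cutoff = f_obs - _TIE_RTOL * max(1.0, abs(f_obs))

    n_exhaustive = n_distinct_assignments(sizes)
    use_exhaustive = exhaustive is True or (exhaustive == "auto" and n_exhaustive <= n_perm)

    if use_exhaustive:
        batch = np.vstack([a.copy() for a in _iter_assignments(sizes)])
        f_all = _stats_for_assignments(coords, batch, sizes)
        p = float(np.count_nonzero(f_all >= cutoff)) / n_exhaustive
        return PermanovaResult(f_obs, p, n_exhaustive, "exhaustive", seed)

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(codes, (n_perm, 1)), axis=1)
    f_perm = _stats_for_assignments(coords, perms, sizes)
    p = (1.0 + np.count_nonzero(f_perm >= cutoff)) / (n_perm + 1.0)
    return PermanovaResult(f_obs, float(p), n_perm, "sampled", seed)
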