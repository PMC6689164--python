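"""Compositional preprocessing: counts -> strictly positive compositions -> log-ratio space.

Sequencing counts carry only relative information (the library size is an
instrument artifact), so all analysis happens in the Aitchison geometry.
Zeros are handled once, at the count level, by the Dirichlet point estimate
with a uniform prior offset; every later step assumes strictly positive
relative abundances.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import helmert

__all__ = [
    "CountTable",
    "CompositionTable",
    "IlrCoordinates",
    "default_ilr_basis",
    "dirichlet_point_estimate",
    "clr_transform",
    "ilr_transform",
    "aggregate_to_level",
    "DEFAULT_RANKS",
]

DEFAULT_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


def _sample_seed(base_seed: int, sample_id: str) -> np.random.SeedSequence:
    """Per-sample RNG substream keyed by the sample identifier.

    Keying on the identifier (rather than the column position) makes the
    Monte Carlo point estimate invariant to the order in which samples are
    stored, while remaining fully deterministic for a given table seed.
    """
    return np.random.SeedSequence([int(base_seed), zlib.crc32(sample_id.encode("utf-8"))])


@dataclass
class CountTable:
    """Taxon-by-sample table of non-negative integer counts with group labels.

    ``counts`` has shape (n_taxa, n_samples); column j belongs to
    ``sample_ids[j]`` and ``groups[sample_ids[j]]`` names its group.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    groups: dict[str, str]
    level: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n_taxa, n_samples = self.counts.shape
        if len(self.taxon_ids) != n_taxa or len(self.sample_ids) != n_samples:
            raise ValueError("counts shape does not match identifier lists")
        if n_taxa == 0 or n_samples == 0:
            raise ValueError("empty count table")
        if len(set(self.taxon_ids)) != n_taxa:
            raise ValueError("duplicate taxon_ids")
        if len(set(self.sample_ids)) != n_samples:
            raise ValueError("duplicate sample_ids")
        if not np.issubdtype(self.counts.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if np.any(self.counts != np.floor(self.counts)):
            raise ValueError("non-integral counts")
        missing = [s for s in self.sample_ids if s not in self.groups]
        if missing:
            raise ValueError(f"samples missing group labels: {missing}")

    # -- helpers ----------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def labels(self) -> np.ndarray:
        """Group label per sample, aligned with column order."""
        return np.array([self.groups[s] for s in self.sample_ids])

    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.groups[s], None)
        return list(seen)

    def subset_groups(self, group_pair: Sequence[str]) -> "CountTable":
        """Restrict to the samples of the named groups (order preserved)."""
        wanted = set(group_pair)
        unknown = wanted - set(self.groups[s] for s in self.sample_ids)
        if unknown:
            raise ValueError(f"unknown group name(s): {sorted(unknown)}")
        keep = [j for j, s in enumerate(self.sample_ids) if self.groups[s] in wanted]
        sample_ids = [self.sample_ids[j] for j in keep]
        return CountTable(
            taxon_ids=list(self.taxon_ids),
            sample_ids=sample_ids,
            counts=self.counts[:, keep].copy(),
            groups={s: self.groups[s] for s in sample_ids},
            level=self.level,
        )


@dataclass
class CompositionTable:
    """Strictly positive per-sample relative abundances (taxa x samples)."""

    taxon_ids: list[str]
    sample_ids: list[str]
    rel_abund: np.ndarray

    def __post_init__(self) -> None:
        self.rel_abund = np.asarray(self.rel_abund, dtype=float)
        if self.rel_abund.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValueError("rel_abund shape does not match identifier lists")
        if np.any(self.rel_abund <= 0):
            raise ValueError("compositions must be strictly positive")
        if np.any(np.abs(self.rel_abund.sum(axis=0) - 1.0) > 1e-9):
            raise ValueError("composition columns must sum to 1")


@dataclass
class IlrCoordinates:
    """Samples in ILR (Euclidean) coordinates plus the contrast basis used."""

    sample_ids: list[str]
    coords: np.ndarray  # (n_samples, D-1)
    basis: np.ndarray  # (D, D-1), orthonormal columns orthogonal to 1


def default_ilr_basis(n_parts: int) -> np.ndarray:
    """Deterministic orthonormal ILR contrast matrix (D x D-1).

    A Helmert-type sequential binary partition in taxon order. Any valid
    basis gives the same Aitchison distances (the transform is an isometry),
    so every downstream statistic is invariant to this choice.
    """
    if n_parts < 2:
        raise ValueError("need at least 2 parts for an ILR basis")
    return helmert(n_parts).T


def _check_basis(basis: np.ndarray, n_parts: int) -> np.ndarray:
    basis = np.asarray(basis, dtype=float)
    if basis.shape != (n_parts, n_parts - 1):
        raise ValueError(f"basis must have shape ({n_parts}, {n_parts - 1})")
    if not np.allclose(basis.T @ basis, np.eye(n_parts - 1), atol=1e-8):
        raise ValueError("basis columns are not orthonormal")
    if not np.allclose(basis.sum(axis=0), 0.0, atol=1e-8):
        raise ValueError("basis columns must be orthogonal to the all-ones vector")
    return basis


def dirichlet_point_estimate(
    table: CountTable,
    n_draws: int = 1000,
    offset: float = 0.5,
    seed: int | None = None,
    exact: bool = False,
) -> CompositionTable:
    """Point estimate of relative abundance from counts.

    For each sample, the estimate is the Monte Carlo mean of ``n_draws``
    draws from Dirichlet(counts + offset). ``exact=True`` returns the
    closed-form mean of that Dirichlet, (c_i + offset) / sum_j (c_j + offset),
    which is the n_draws -> infinity limit of the Monte Carlo mode.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if offset <= 0:
        raise ValueError("offset must be positive")
    alpha = table.counts.astype(float) + offset  # (D, n)
    if exact:
        rel = alpha / alpha.sum(axis=0, keepdims=True)
        return CompositionTable(list(table.taxon_ids), list(table.sample_ids), rel)
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
    rel = np.empty_like(alpha)
    for j, sid in enumerate(table.sample_ids):
        rng = np.random.default_rng(_sample_seed(seed, sid))
        g = rng.standard_gamma(alpha[:, j], size=(n_draws, table.n_taxa))
        g /= g.sum(axis=1, keepdims=True)
        rel[:, j] = g.mean(axis=0)
    # enforce exact closure against accumulated rounding
    rel /= rel.sum(axis=0, keepdims=True)
    return CompositionTable(list(table.taxon_ids), list(table.sample_ids), rel)


def clr_transform(comp: CompositionTable | np.ndarray) -> np.ndarray:
    """Centered log-ratio transform; returns (n_samples, D) rows summing to 0."""
    if isinstance(comp, CompositionTable):
        x = comp.rel_abund.T
    else:
        x = np.asarray(comp, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
    if np.any(x <= 0):
        raise ValueError("CLR requires strictly positive entries")
    logx = np.log(x)
    return logx - logx.mean(axis=1, keepdims=True)


def ilr_transform(comp: CompositionTable, basis: np.ndarray | None = None) -> IlrCoordinates:
    """Isometric log-ratio transform of a composition table.

    ``coords = CLR(comp) @ basis``; with an orthonormal contrast basis this is
    an isometry of the Aitchison geometry, so Euclidean distances between the
    returned rows equal Aitchison distances between the source compositions.
    """
    n_parts = len(comp.taxon_ids)
    if basis is None:
        basis = default_ilr_basis(n_parts)
    else:
        basis = _check_basis(basis, n_parts)
    coords = clr_transform(comp) @ basis
    return IlrCoordinates(list(comp.sample_ids), coords, basis)


def aggregate_to_level(
    table: CountTable,
    taxonomy: Mapping[str, str],
    level: str,
    ranks: Sequence[str] = DEFAULT_RANKS,
    delimiter: str = ";",
) -> CountTable:
    """Sum counts over taxa sharing the lineage prefix down to ``level``.

    ``taxonomy`` maps each taxon id to a delimited lineage string, ranks in
    descending order. Lineages shorter than the requested depth are padded
    with an "unclassified at <parent>" bucket. Per-sample totals are
    preserved exactly.
    """
    if level not in ranks:
        raise ValueError(f"unknown rank label {level!r}; known ranks: {list(ranks)}")
    depth = list(ranks).index(level) + 1
    new_ids: list[str] = []
    index: dict[str, int] = {}
    rows: list[np.ndarray] = []
    for i, tid in enumerate(table.taxon_ids):
        if tid not in taxonomy:
            raise ValueError(f"taxon {tid!r} missing from taxonomy")
        parts = [p.strip() for p in taxonomy[tid].split(delimiter) if p.strip()]
        while len(parts) < depth:
            parent = parts[-1] if parts else "root"
            parts.append(f"unclassified at {parent}")
        key = delimiter.join(parts[:depth])
        if key not in index:
            index[key] = len(new_ids)
            new_ids.append(key)
            rows.append(table.counts[i].astype(table.counts.dtype).copy())
        else:
            rows[index[key]] = rows[index[key]] + table.counts[i]
    return CountTable(
        taxon_ids=new_ids,
        sample_ids=list(table.sample_ids),
        counts=np.vstack(rows),
        groups=dict(table.groups),
        level=level,
    )
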