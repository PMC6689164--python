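"""The similarity test: does a second dataset reproduce the group-difference
pattern of a first?

Pipeline: match taxa to a shared union space, Dirichlet point estimates,
ILR, PCA fitted on the first dataset only, projection of the second dataset
through the same affine map, then three component tests combined by the
intersection-union principle (omnibus P = max of component P values):

1. the first dataset's samples segregate by group along the PC axes
   (PERMANOVA);
2. the second dataset's samples segregate along the *same* axes, checked
   against both a sample-label null and a taxon-matching null (the larger of
   the two P values stands);
3. the two group-difference directions are not perpendicular: the cosine of
   the angle between them is bootstrapped, and P estimates Pr(cos theta = 0).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .compositions import (
    CompositionTable,
    CountTable,
    IlrCoordinates,
    clr_transform,
    default_ilr_basis,
    dirichlet_point_estimate,
    ilr_transform,
    _check_basis,
)
from .permanova import PermanovaResult, permanova, pseudo_f, _TIE_RTOL

__all__ = [
    "MatchedPair",
    "ProjectionModel",
    "StarmapsResult",
    "CompareSettings",
    "match_taxa",
    "fit_projection",
    "project",
    "test1_ds1_segregation",
    "test2_ds2_segregation",
    "group_direction",
    "cos_theta",
    "test3_direction",
    "compare",
]


# ---------------------------------------------------------------------------
# matching


@dataclass
class MatchedPair:
    """Two count tables aligned on the union of their taxa.

    Rows present in only one dataset are zero-filled in the other; the
    ``presence`` flag records ``ds1_only`` / ``ds2_only`` / ``both`` per
    union taxon. Union order: ds1 taxa first (their order), then the taxa
    new to ds2 (their order).
    """

    union_taxa: list[str]
    ds1: CountTable
    ds2: CountTable
    presence: list[str]

    @property
    def n_shared(self) -> int:
        return sum(1 for p in self.presence if p == "both")


def match_taxa(ds1: CountTable, ds2: CountTable) -> MatchedPair:
    """Align two count tables on the union of their taxon identifiers."""
    set1 = set(ds1.taxon_ids)
    set2 = set(ds2.taxon_ids)
    union = list(ds1.taxon_ids) + [t for t in ds2.taxon_ids if t not in set1]
    presence = [
        "both" if (t in set1 and t in set2) else ("ds1_only" if t in set1 else "ds2_only")
        for t in union
    ]

    def reindex(tbl: CountTable) -> CountTable:
        pos = {t: i for i, t in enumerate(tbl.taxon_ids)}
        counts = np.zeros((len(union), tbl.n_samples), dtype=tbl.counts.dtype)
        for u, t in enumerate(union):
            if t in pos:
                counts[u] = tbl.counts[pos[t]]
        return CountTable(list(union), list(tbl.sample_ids), counts, dict(tbl.groups), tbl.level)

    return MatchedPair(union, reindex(ds1), reindex(ds2), presence)


# ---------------------------------------------------------------------------
# projection model


@dataclass
class ProjectionModel:
    """Affine map from ILR space to the PC axes of the first dataset.

    scores = (ilr - center) @ rotation, with ``center`` the ILR mean of ds1
    and ``rotation`` the orthonormal PCA loadings fitted on ds1 alone.
    Eigenvalues use the n-1 divisor and are trimmed at a 1e-10 relative
    tolerance, so the retained axes carry all of ds1's ILR variance.
    """

    center: np.ndarray  # (D-1,)
    rotation: np.ndarray  # (D-1, r)
    eigenvalues: np.ndarray  # (r,)
    basis: np.ndarray  # (D, D-1) shared ILR basis

    @property
    def n_axes(self) -> int:
        return self.rotation.shape[1]

    def transform(self, ilr_coords: np.ndarray) -> np.ndarray:
        ilr_coords = np.atleast_2d(np.asarray(ilr_coords, dtype=float))
        if ilr_coords.shape[1] != self.center.shape[0]:
            raise ValueError("ILR dimension does not match the fitted model")
        return (ilr_coords - self.center) @ self.rotation

    def truncate(self, n_axes: int | None) -> "ProjectionModel":
        if n_axes is None or n_axes >= self.n_axes:
            return self
        if n_axes < 1:
            raise ValueError("n_axes must be >= 1")
        return ProjectionModel(
            self.center, self.rotation[:, :n_axes], self.eigenvalues[:n_axes], self.basis
        )


def _fit_pca(ilr_coords: np.ndarray, basis: np.ndarray, rel_tol: float = 1e-10) -> ProjectionModel:
    x = np.asarray(ilr_coords, dtype=float)
    center = x.mean(axis=0)
    xc = x - center
    # economy SVD; eigenvalues of the covariance (n-1 divisor)
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    eig = s**2 / max(x.shape[0] - 1, 1)
    if eig.size and eig[0] > 0:
        keep = eig > rel_tol * eig[0]
    else:
        keep = np.zeros_like(eig, dtype=bool)
    r = max(int(keep.sum()), 1)
    return ProjectionModel(center, vt[:r].T.copy(), eig[:r].copy(), basis)


def fit_projection(
    pair: MatchedPair,
    n_draws: int = 1000,
    offset: float = 0.5,
    seed: int | None = None,
    basis: np.ndarray | None = None,
    exact: bool = False,
) -> tuple[ProjectionModel, np.ndarray]:
    """Fit the Dirichlet -> ILR -> PCA map on ds1 only; returns (model, scores1)."""
    if pair.ds1.n_samples < 3:
        raise ValueError("ds1 needs at least 3 samples to fit a projection")
    if len(pair.ds1.group_names()) < 2:
        raise ValueError("ds1 needs at least 2 groups")
    comp1 = dirichlet_point_estimate(pair.ds1, n_draws=n_draws, offset=offset, seed=seed, exact=exact)
    d = len(pair.union_taxa)
    basis = default_ilr_basis(d) if basis is None else _check_basis(basis, d)
    ilr1 = clr_transform(comp1) @ basis
    model = _fit_pca(ilr1, basis)
    return model, model.transform(ilr1)


def project(
    model: ProjectionModel,
    pair: MatchedPair,
    which: str = "ds2",
    n_draws: int = 1000,
    offset: float = 0.5,
    seed: int | None = None,
    exact: bool = False,
) -> np.ndarray:
    """Project either dataset of the pair through the fitted model."""
    tbl = {"ds1": pair.ds1, "ds2": pair.ds2}[which]
    comp = dirichlet_point_estimate(tbl, n_draws=n_draws, offset=offset, seed=seed, exact=exact)
    ilr = clr_transform(comp) @ model.basis
    return model.transform(ilr)


# ---------------------------------------------------------------------------
# component tests


def test1_ds1_segregation(
    scores1: np.ndarray,
    labels1: Sequence,
    n_perm: int = 10000,
    seed: int | None = None,
    exhaustive: bool | str = "auto",
) -> PermanovaResult:
    """PERMANOVA of the first dataset's groups on its own PC scores."""
    return permanova(scores1, labels1, n_perm=n_perm, seed=seed, exhaustive=exhaustive)


def _taxon_matching_null(
    clr2: np.ndarray,
    model: ProjectionModel,
    labels2: Sequence,
    f_obs: float,
    n_perm: int,
    seed: int | None,
) -> float:
    """Taxon-matching permutation P: randomize which union taxa the ds2
    profiles occupy, re-ILR and re-project through the unchanged model, and
    compare the resulting pseudo-F values with the observed one."""
    rng = np.random.default_rng(seed)
    d = clr2.shape[1]
    # CLR of a row-permuted composition is the column-permuted CLR, so the
    # whole re-ILR + centering + rotation collapses to one matmul per draw.
    m = model.basis @ model.rotation  # (D, r)
    shift = model.center @ model.rotation  # (r,)
    if np.isinf(f_obs):
        cutoff = np.inf
    else:
        cutoff = f_obs - _TIE_RTOL * max(1.0, abs(f_obs))
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(d)
        scores = clr2[:, perm] @ m - shift
        if pseudo_f(scores, labels2) >= cutoff:
            hits += 1
    return (1.0 + hits) / (n_perm + 1.0)


def test2_ds2_segregation(
    model: ProjectionModel,
    pair: MatchedPair,
    n_perm: int = 10000,
    seed: int | None = None,
    exhaustive: bool | str = "auto",
    n_draws: int = 1000,
    offset: float = 0.5,
    dirichlet_seed: int | None = None,
    comp2: CompositionTable | None = None,
) -> tuple[float, float, float]:
    """Both ds2 null tests; returns (p2_sample, p2_taxon, p2 = max of the two)."""
    if comp2 is None:
        comp2 = dirichlet_point_estimate(
            pair.ds2, n_draws=n_draws, offset=offset, seed=dirichlet_seed
        )
    clr2 = clr_transform(comp2)
    scores2 = model.transform(clr2 @ model.basis)
    labels2 = pair.ds2.labels()
    ss = np.random.SeedSequence(seed).spawn(2) if seed is not None else [None, None]
    seed_a = int(ss[0].generate_state(1)[0] % 2**31) if seed is not None else None
    seed_b = int(ss[1].generate_state(1)[0] % 2**31) if seed is not None else None
    res_sample = permanova(scores2, labels2, n_perm=n_perm, seed=seed_a, exhaustive=exhaustive)
    p_taxon = _taxon_matching_null(clr2, model, labels2, res_sample.pseudo_f, n_perm, seed_b)
    return res_sample.p_value, p_taxon, max(res_sample.p_value, p_taxon)


def group_direction(scores: np.ndarray, labels: Sequence, group_pair: Sequence[str]) -> np.ndarray:
    """Centroid(second group) - centroid(first group) in PC-score space."""
    labels = np.asarray(labels)
    a, b = group_pair
    for g in (a, b):
        if g not in labels:
            raise ValueError(f"unknown group name {g!r}")
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    return scores[labels == b].mean(axis=0) - scores[labels == a].mean(axis=0)


def cos_theta(dir1: np.ndarray, dir2: np.ndarray) -> float:
    """Cosine of the angle between the two group-difference directions.

    +1: same direction; -1: opposite; 0: perpendicular (not comparable).
    Elementwise-equal (or exactly negated) vectors short-circuit to exactly
    +/-1 so self-comparison is exact despite floating-point norms.
    """
    d1 = np.asarray(dir1, dtype=float)
    d2 = np.asarray(dir2, dtype=float)
    n1 = np.linalg.norm(d1)
    n2 = np.linalg.norm(d2)
    if n1 == 0 or n2 == 0:
        return float("nan")
    if np.array_equal(d1, d2):
        return 1.0
    if np.array_equal(d1, -d2):
        return -1.0
    return float(np.clip(np.dot(d1, d2) / (n1 * n2), -1.0, 1.0))


def _sorted_group_indices(labels: np.ndarray, sample_ids: Sequence[str], group_pair: Sequence[str]) -> list[np.ndarray]:
    """Per-group row indices, ordered by sample id so bootstrap draws do not
    depend on column order."""
    out = []
    sample_ids = np.asarray(sample_ids)
    for g in group_pair:
        idx = np.flatnonzero(labels == g)
        out.append(idx[np.argsort(sample_ids[idx])])
    return out


def test3_direction(
    ilr1: np.ndarray,
    ilr2: np.ndarray,
    labels1: np.ndarray,
    labels2: np.ndarray,
    sample_ids1: Sequence[str],
    sample_ids2: Sequence[str],
    groups1: Sequence[str],
    groups2: Sequence[str],
    model: ProjectionModel,
    n_boot: int = 10000,
    seed: int | None = None,
    refit: bool = True,
    n_axes: int | None = None,
) -> tuple[float, float]:
    """Bootstrap test of Pr(cos theta = 0); returns (observed cos theta, p3).

    Replicates resample samples with replacement within each group of each
    dataset and recompute both directions and their cosine. By default the
    PCA model is refit on each resampled first dataset (propagating the
    estimation uncertainty of the axes); ``refit=False`` holds the fitted
    model fixed (faster, documented approximation). p3 is the two-sided
    sign-crossing probability 2*min(Pr(cos* <= 0), Pr(cos* >= 0)), capped
    at 1. A degenerate zero-length direction yields p3 = 1.
    """
    scores1 = model.transform(ilr1)
    scores2 = model.transform(ilr2)
    obs = cos_theta(
        group_direction(scores1, labels1, groups1), group_direction(scores2, labels2, groups2)
    )
    if np.isnan(obs):
        return obs, 1.0

    idx1 = _sorted_group_indices(labels1, sample_ids1, groups1)
    idx2 = _sorted_group_indices(labels2, sample_ids2, groups2)
    if any(len(i) == 1 for i in idx1 + idx2):
        import logging

        logging.getLogger(__name__).warning(
            "a compared group has a single sample; its bootstrap is degenerate"
        )
    rng = np.random.default_rng(seed)
    cos_star = np.empty(n_boot)
    for b in range(n_boot):
        pick1 = [g[rng.integers(0, len(g), len(g))] for g in idx1]
        pick2 = [g[rng.integers(0, len(g), len(g))] for g in idx2]
        if refit:
            x1 = ilr1[np.concatenate(pick1)]
            m_b = _fit_pca(x1, model.basis).truncate(n_axes)
            cents1 = [m_b.transform(ilr1[p]).mean(axis=0) for p in pick1]
            cents2 = [m_b.transform(ilr2[p]).mean(axis=0) for p in pick2]
        else:
            cents1 = [scores1[p].mean(axis=0) for p in pick1]
            cents2 = [scores2[p].mean(axis=0) for p in pick2]
        cos_star[b] = cos_theta(cents1[1] - cents1[0], cents2[1] - cents2[0])
    valid = cos_star[~np.isnan(cos_star)]
    if valid.size == 0:
        return obs, 1.0
    p_le = np.count_nonzero(valid <= 0.0) / valid.size
    p_ge = np.count_nonzero(valid >= 0.0) / valid.size
    return obs, float(min(1.0, 2.0 * min(p_le, p_ge)))


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class CompareSettings:
    """Tunable knobs of a similarity run (seeds handled by ``compare``)."""

    n_perm: int = 10000
    n_boot: int = 10000
    n_draws: int = 1000
    offset: float = 0.5
    n_axes: int | None = None  # None -> all axes with nonzero eigenvalue
    exhaustive: bool | str = "auto"
    fast_bootstrap: bool = False
    exact_dirichlet: bool = False
    basis: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_perm < 1 or self.n_boot < 1 or self.n_draws < 1:
            raise ValueError("n_perm, n_boot and n_draws must be >= 1")
        if self.offset <= 0:
            raise ValueError("offset must be positive")


@dataclass
class StarmapsResult:
    """Component and omnibus P values, direction cosine, scores and settings."""

    p1: float
    p2_sample: float
    p2_taxon: float
    p2: float
    cos_theta: float
    p3: float
    omnibus_p: float
    scores1: np.ndarray
    scores2: np.ndarray
    n_axes: int
    settings: dict[str, Any] = field(default_factory=dict)

    def flat_dict(self) -> dict[str, Any]:
        return {
            "p1": self.p1,
            "p2_sample": self.p2_sample,
            "p2_taxon": self.p2_taxon,
            "p2": self.p2,
            "cos_theta": self.cos_theta,
            "p3": self.p3,
            "omnibus_p": self.omnibus_p,
            "n_axes": self.n_axes,
            "seed": self.settings.get("seed"),
        }

    def to_dict(self) -> dict[str, Any]:
        out = self.flat_dict()
        out["schema_version"] = 1
        out["scores1"] = np.asarray(self.scores1).tolist()
        out["scores2"] = np.asarray(self.scores2).tolist()
        out["settings"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in self.settings.items()
        }
        return out


def compare(
    ds1: CountTable,
    ds2: CountTable,
    groups1: Sequence[str],
    groups2: Sequence[str],
    seed: int | None = None,
    settings: CompareSettings | None = None,
) -> StarmapsResult:
    """Full similarity test between the ordered group pairs of two datasets.

    ``groups1`` and ``groups2`` are ordered (reference, test) pairs; the sign
    of cos theta is meaningful only under a consistent orientation. The
    omnibus P is the maximum of the component P values (intersection-union
    test), so similarity is called only when every component test rejects.
    """
    settings = settings or CompareSettings()
    if len(groups1) != 2 or len(groups2) != 2:
        raise ValueError("exactly two ordered groups per dataset are compared")
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
    seed = int(seed)

    ds1 = ds1.subset_groups(groups1)
    ds2 = ds2.subset_groups(groups2)
    for name, tbl in (("ds1", ds1), ("ds2", ds2)):
        sizes = [np.count_nonzero(tbl.labels() == g) for g in (groups1 if name == "ds1" else groups2)]
        if min(sizes) < 2:
            raise ValueError(f"{name}: each compared group needs >= 2 samples")

    pair = match_taxa(ds1, ds2)
    if pair.n_shared == 0:
        import logging

        logging.getLogger(__name__).warning(
            "no shared taxa between the datasets; the taxon-matching null is degenerate"
        )

    # deterministic sub-seeds: [root, k] streams
    def sub(k: int) -> int:
        return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % 2**31)

    dirichlet_seed = sub(0)
    comp1 = dirichlet_point_estimate(
        pair.ds1, settings.n_draws, settings.offset, dirichlet_seed, exact=settings.exact_dirichlet
    )
    comp2 = dirichlet_point_estimate(
        pair.ds2, settings.n_draws, settings.offset, dirichlet_seed, exact=settings.exact_dirichlet
    )
    d = len(pair.union_taxa)
    basis = default_ilr_basis(d) if settings.basis is None else _check_basis(settings.basis, d)
    ilr1 = clr_transform(comp1) @ basis
    ilr2 = clr_transform(comp2) @ basis

    model = _fit_pca(ilr1, basis).truncate(settings.n_axes)
    scores1 = model.transform(ilr1)
    scores2 = model.transform(ilr2)
    labels1 = pair.ds1.labels()
    labels2 = pair.ds2.labels()

    res1 = test1_ds1_segregation(
        scores1, labels1, n_perm=settings.n_perm, seed=sub(1), exhaustive=settings.exhaustive
    )
    res2_sample = permanova(
        scores2, labels2, n_perm=settings.n_perm, seed=sub(2), exhaustive=settings.exhaustive
    )
    p2_taxon = _taxon_matching_null(
        clr_transform(comp2), model, labels2, res2_sample.pseudo_f, settings.n_perm, sub(3)
    )
    p2 = max(res2_sample.p_value, p2_taxon)

    cos_obs, p3 = test3_direction(
        ilr1,
        ilr2,
        labels1,
        labels2,
        pair.ds1.sample_ids,
        pair.ds2.sample_ids,
        groups1,
        groups2,
        model,
        n_boot=settings.n_boot,
        seed=sub(4),
        refit=not settings.fast_bootstrap,
        n_axes=settings.n_axes,
    )

    omnibus = max(res1.p_value, p2, p3)
    return StarmapsResult(
        p1=res1.p_value,
        p2_sample=res2_sample.p_value,
        p2_taxon=p2_taxon,
        p2=p2,
        cos_theta=cos_obs,
        p3=p3,
        omnibus_p=omnibus,
        scores1=scores1,
        scores2=scores2,
        n_axes=model.n_axes,
        settings={
            "seed": seed,
            "n_perm": settings.n_perm,
            "n_boot": settings.n_boot,
            "n_draws": settings.n_draws,
            "offset": settings.offset,
            "exhaustive": settings.exhaustive,
            "fast_bootstrap": settings.fast_bootstrap,
            "exact_dirichlet": settings.exact_dirichlet,
            "groups1": list(groups1),
            "groups2": list(groups2),
            "n_union_taxa": d,
            "n_shared_taxa": pair.n_shared,
            "mode_test1": res1.mode,
            "mode_test2_sample": res2_sample.mode,
            "pseudo_f1": res1.pseudo_f,
            "pseudo_f2": res2_sample.pseudo_f,
            "eigenvalues": model.eigenvalues,
        },
    )
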