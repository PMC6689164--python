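"""Paired-dataset simulation and performance evaluation.

Generates pairs of taxon-count datasets with a known ground truth — either
the same 10% of species shifted in both datasets (similar) or two disjoint
species sets shifted (dissimilar) — then measures the similarity test's
sensitivity and specificity across omnibus-P thresholds (ROC).

The default template is parametric: a heavy-tailed (log-normal) rank
abundance over D species with log-normally distributed sequencing depths,
emulating the uneven fecal community and uneven library sizes of real 16S
surveys. Any user count table can be supplied as an empirical template
instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np

from .compositions import CountTable
from .core import CompareSettings, StarmapsResult, compare

__all__ = [
    "Template",
    "SimulationSpec",
    "SimulatedPair",
    "PerformanceSummary",
    "make_template",
    "template_from_table",
    "simulate_dataset",
    "simulate_pair",
    "shuffle_groups",
    "evaluate_performance",
]


@dataclass
class Template:
    """Species abundance distribution plus a sequencing-depth sampler."""

    species_ids: list[str]
    species_props: np.ndarray  # strictly positive, sums to 1
    depth_log_median: float = math.log(3e4)
    depth_log_sigma: float = 0.6
    depth_bounds: tuple[int, int] = (1000, 1_000_000)
    empirical_depths: np.ndarray | None = None  # overrides the parametric sampler

    def __post_init__(self) -> None:
        self.species_props = np.asarray(self.species_props, dtype=float)
        if np.any(self.species_props <= 0):
            raise ValueError("species proportions must be strictly positive")
        if abs(self.species_props.sum() - 1.0) > 1e-9:
            raise ValueError("species proportions must sum to 1")
        if len(self.species_ids) != self.species_props.size:
            raise ValueError("ids and proportions differ in length")

    @property
    def n_species(self) -> int:
        return self.species_props.size

    def sample_depths(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.empirical_depths is not None:
            depths = rng.choice(self.empirical_depths, size=n, replace=True)
        else:
            depths = np.exp(rng.normal(self.depth_log_median, self.depth_log_sigma, size=n))
        lo, hi = self.depth_bounds
        return np.clip(np.round(depths), lo, hi).astype(np.int64)


def make_template(
    n_species: int = 200,
    abundance_sigma: float = 2.0,
    depth_median: float = 3e4,
    depth_sigma: float = 0.6,
    depth_bounds: tuple[int, int] = (1000, 1_000_000),
    seed: int | None = None,
) -> Template:
    """Parametric template: log-normal rank abundance, log-normal depths.

    ``abundance_sigma`` controls how uneven the community is (2.0 gives a
    few dominant species and a long tail, typical of fecal communities);
    depths are truncated to ``depth_bounds`` by clipping.
    """
    if n_species < 10:
        raise ValueError("need at least 10 species")
    if abundance_sigma <= 0 or depth_sigma <= 0 or depth_median <= 0:
        raise ValueError("invalid shape parameters")
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(mean=0.0, sigma=abundance_sigma, size=n_species)
    props = np.sort(raw)[::-1]
    props = props / props.sum()
    width = len(str(n_species))
    ids = [f"sp{i + 1:0{width}d}" for i in range(n_species)]
    return Template(
        ids, props, math.log(depth_median), depth_sigma, (int(depth_bounds[0]), int(depth_bounds[1]))
    )


def template_from_table(table: CountTable) -> Template:
    """Empirical template: pooled proportions and observed depths of a table."""
    totals = table.counts.sum(axis=1).astype(float)
    keep = totals > 0
    if keep.sum() < 2:
        raise ValueError("template table needs at least 2 observed taxa")
    props = totals[keep] / totals[keep].sum()
    ids = [t for t, k in zip(table.taxon_ids, keep) if k]
    depths = table.counts.sum(axis=0).astype(np.int64)
    lo = max(int(depths.min()), 1)
    return Template(ids, props, empirical_depths=depths, depth_bounds=(lo, int(depths.max())))


def effective_proportions(
    template: Template, da_species: Sequence[str], log2fc: float | Sequence[float]
) -> np.ndarray:
    """Expected proportions after multiplying the selected species by
    2**log2fc and renormalizing (the fold-change scheme applied to group 2)."""
    pos = {t: i for i, t in enumerate(template.species_ids)}
    unknown = [t for t in da_species if t not in pos]
    if unknown:
        raise ValueError(f"species not in template: {unknown}")
    props = template.species_props.copy()
    fc = np.broadcast_to(np.asarray(log2fc, dtype=float), (len(da_species),))
    for t, f in zip(da_species, fc):
        props[pos[t]] *= 2.0**f
    return props / props.sum()


def simulate_dataset(
    template: Template,
    n_per_group: int,
    da_species: Sequence[str],
    log2fc: float | Sequence[float],
    seed: int | None = None,
    group_names: tuple[str, str] = ("g1", "g2"),
    sample_prefix: str = "s",
) -> CountTable:
    """Two groups of N multinomial samples; group 2 carries the fold changes.

    Each sample's depth is drawn from the template's depth sampler; counts
    are multinomial at that depth from the group's species proportions.
    """
    fc_arr = np.atleast_1d(np.asarray(log2fc, dtype=float))
    if len(da_species) == 0 and np.any(fc_arr != 0):
        raise ValueError("nonzero effect requested with an empty set of target species")
    rng = np.random.default_rng(seed)
    props1 = template.species_props
    props2 = effective_proportions(template, da_species, log2fc) if len(da_species) else props1
    depths = template.sample_depths(2 * n_per_group, rng)
    counts = np.empty((template.n_species, 2 * n_per_group), dtype=np.int64)
    sample_ids: list[str] = []
    groups: dict[str, str] = {}
    for j in range(2 * n_per_group):
        grp = group_names[0] if j < n_per_group else group_names[1]
        props = props1 if j < n_per_group else props2
        counts[:, j] = rng.multinomial(depths[j], props)
        sid = f"{sample_prefix}{grp}_{(j % n_per_group) + 1}"
        sample_ids.append(sid)
        groups[sid] = grp
    return CountTable(list(template.species_ids), sample_ids, counts, groups, level="species")


@dataclass
class SimulationSpec:
    """One cell of the simulation design."""

    n_per_group: int = 6
    log2fc_mean: float = 2.0
    log2fc_sd: float = 0.0  # s: spread of the per-species effect in ds2
    overlap: float = 1.0  # proportion of ds2 species matchable by name
    prop_da: float = 0.10
    n_pairs: int = 2000
    template: Template | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.prop_da < 1):
            raise ValueError("prop_da must be in (0, 1)")
        if not (0 < self.overlap <= 1):
            raise ValueError("overlap must be in (0, 1]")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.log2fc_sd < 0:
            raise ValueError("log2fc_sd must be >= 0")


@dataclass
class SimulatedPair:
    ds1: CountTable
    ds2: CountTable
    truth: str  # "similar" | "dissimilar"
    da_species1: list[str]
    da_species2: list[str]
    applied_log2fc1: np.ndarray
    applied_log2fc2: np.ndarray
    masked_species: list[str] = field(default_factory=list)


def simulate_pair(spec: SimulationSpec, truth: str, seed: int | None = None) -> SimulatedPair:
    """One pair of datasets with known similar/dissimilar group differences.

    ds1's selected species shift by a constant log2FC; ds2's by per-species
    Normal(log2fc_mean, log2fc_sd**2) draws (negative draws applied as
    drawn). ``truth="similar"`` reuses ds1's species set in ds2;
    "dissimilar" uses a disjoint set of the same size. A fraction
    (1 - overlap) of ds2's species names get an "xx" suffix so they cannot
    be matched across datasets.
    """
    if truth not in ("similar", "dissimilar"):
        raise ValueError("truth must be 'similar' or 'dissimilar'")
    template = spec.template if spec.template is not None else make_template(seed=0)
    d = template.n_species
    n_da = math.ceil(spec.prop_da * d)
    if n_da < 1:
        raise ValueError("prop_da * n_species < 1")
    if truth == "dissimilar" and 2 * n_da > d:
        raise ValueError("not enough species for disjoint differential sets")
    if seed is None:
        seed = spec.seed
    ss = np.random.SeedSequence([int(seed) if seed is not None else 0, 91]).spawn(3)
    rng = np.random.default_rng(ss[0])

    order = rng.permutation(d)
    da1 = [template.species_ids[i] for i in order[:n_da]]
    da2 = list(da1) if truth == "similar" else [template.species_ids[i] for i in order[n_da : 2 * n_da]]
    fc1 = np.full(n_da, spec.log2fc_mean)
    fc2 = rng.normal(spec.log2fc_mean, spec.log2fc_sd, size=n_da)

    ds1 = simulate_dataset(
        template, spec.n_per_group, da1, fc1,
        seed=int(ss[1].generate_state(1)[0] % 2**31), sample_prefix="a",
    )
    ds2 = simulate_dataset(
        template, spec.n_per_group, da2, fc2,
        seed=int(ss[2].generate_state(1)[0] % 2**31), sample_prefix="b",
    )

    masked: list[str] = []
    n_mask = int(round((1.0 - spec.overlap) * d))
    if n_mask:
        mask_idx = rng.choice(d, size=n_mask, replace=False)
        new_ids = list(ds2.taxon_ids)
        for i in mask_idx:
            masked.append(new_ids[i])
            new_ids[i] = new_ids[i] + "xx"
        ds2 = CountTable(new_ids, ds2.sample_ids, ds2.counts, ds2.groups, ds2.level)
    return SimulatedPair(ds1, ds2, truth, da1, da2, fc1, fc2, masked)


def shuffle_groups(table: CountTable, seed: int | None = None) -> CountTable:
    """Randomly reassign the existing group labels across samples (a null
    dataset with no group structure)."""
    rng = np.random.default_rng(seed)
    labels = table.labels()
    shuffled = labels[rng.permutation(len(labels))]
    groups = {s: g for s, g in zip(table.sample_ids, shuffled)}
    return CountTable(list(table.taxon_ids), list(table.sample_ids), table.counts, groups, table.level)


@dataclass
class PerformanceSummary:
    """Sensitivity/specificity of the similarity call across thresholds."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_similar: int
    n_dissimilar: int
    omnibus_p: np.ndarray
    truths: list[str]
    cos_thetas: np.ndarray
    spec_params: dict[str, Any] = field(default_factory=dict)

    def roc_points(self) -> np.ndarray:
        """(false positive fraction, true positive fraction) per threshold."""
        return np.column_stack([1.0 - self.specificity, self.sensitivity])

    def at_threshold(self, threshold: float) -> tuple[float, float]:
        """(sensitivity, specificity) of the call ``omnibus_p <= threshold``."""
        called = self.omnibus_p <= threshold
        truth = np.asarray(self.truths)
        sim = truth == "similar"
        sens = float(called[sim].mean()) if sim.any() else float("nan")
        spc = float((~called[~sim]).mean()) if (~sim).any() else float("nan")
        return sens, spc

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_version": 1,
            "thresholds": self.thresholds.tolist(),
            "sensitivity": self.sensitivity.tolist(),
            "specificity": self.specificity.tolist(),
            "n_similar": self.n_similar,
            "n_dissimilar": self.n_dissimilar,
            "omnibus_p": self.omnibus_p.tolist(),
            "truths": list(self.truths),
            "cos_thetas": self.cos_thetas.tolist(),
            "spec_params": self.spec_params,
        }


def _one_pair(spec: SimulationSpec, truth: str, pair_seed: int, compare_seed: int,
              settings: CompareSettings, null_ds2: bool) -> tuple[float, float]:
    pair = simulate_pair(spec, truth, seed=pair_seed)
    ds2 = pair.ds2
    if null_ds2:
        ds2 = shuffle_groups(ds2, seed=pair_seed + 1)
    res = compare(pair.ds1, ds2, ("g1", "g2"), ("g1", "g2"), seed=compare_seed, settings=settings)
    return res.omnibus_p, res.cos_theta


def evaluate_performance(
    spec: SimulationSpec,
    n_pairs: int | None = None,
    similar_fraction: float = 0.5,
    thresholds: np.ndarray | None = None,
    seed: int | None = None,
    settings: CompareSettings | None = None,
    workers: int = 1,
    null_ds2: bool = False,
) -> PerformanceSummary:
    """Run the similarity test over simulated pairs of known truth.

    Pairs alternate similar/dissimilar to hit ``similar_fraction`` (default
    an even 1:1 split); each pair gets its own derived seed so parallel and
    serial execution produce identical results. ``null_ds2=True`` shuffles
    ds2's group labels after simulation (for type-I-error studies; such
    pairs count as dissimilar for specificity).
    """
    n_pairs = int(spec.n_pairs if n_pairs is None else n_pairs)
    if n_pairs < 2:
        raise ValueError("need at least 2 pairs")
    seed = int(spec.seed if seed is None and spec.seed is not None else (seed or 0))
    settings = settings or CompareSettings()
    if thresholds is None:
        thresholds = np.round(np.linspace(0.0, 1.0, 201), 3)
    thresholds = np.asarray(thresholds, dtype=float)

    n_similar_target = int(round(n_pairs * similar_fraction))
    truths = ["similar" if i % 2 == 0 else "dissimilar" for i in range(n_pairs)]
    if not null_ds2:
        # trim to the requested fraction
        n_sim = sum(t == "similar" for t in truths)
        i = n_pairs - 1
        while n_sim > n_similar_target and i >= 0:
            if truths[i] == "similar":
                truths[i] = "dissimilar"
                n_sim -= 1
            i -= 1

    pair_seeds = [int(np.random.SeedSequence([seed, i, 7]).generate_state(1)[0] % 2**31) for i in range(n_pairs)]
    cmp_seeds = [int(np.random.SeedSequence([seed, i, 11]).generate_state(1)[0] % 2**31) for i in range(n_pairs)]

    jobs = list(zip(truths, pair_seeds, cmp_seeds))
    if workers > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=workers)(
            delayed(_one_pair)(spec, t, ps, cs, settings, null_ds2) for t, ps, cs in jobs
        )
    else:
        results = [_one_pair(spec, t, ps, cs, settings, null_ds2) for t, ps, cs in jobs]

    omnibus = np.array([r[0] for r in results])
    cosines = np.array([r[1] for r in results])
    truth_arr = np.asarray(truths)
    if null_ds2:
        truth_arr = np.asarray(["dissimilar"] * n_pairs)
    sim = truth_arr == "similar"
    sens = np.empty(len(thresholds))
    spc = np.empty(len(thresholds))
    for k, t in enumerate(thresholds):
        called = omnibus <= t
        sens[k] = called[sim].mean() if sim.any() else np.nan
        spc[k] = (~called[~sim]).mean() if (~sim).any() else np.nan
    return PerformanceSummary(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spc,
        n_similar=int(sim.sum()),
        n_dissimilar=int((~sim).sum()),
        omnibus_p=omnibus,
        truths=list(truth_arr),
        cos_thetas=cosines,
        spec_params={
            "n_per_group": spec.n_per_group,
            "log2fc_mean": spec.log2fc_mean,
            "log2fc_sd": spec.log2fc_sd,
            "overlap": spec.overlap,
            "prop_da": spec.prop_da,
            "n_pairs": n_pairs,
            "seed": seed,
            "null_ds2": null_ds2,
            "n_perm": settings.n_perm,
            "n_boot": settings.n_boot,
            "n_draws": settings.n_draws,
        },
    )
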