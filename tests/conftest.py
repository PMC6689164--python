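import numpy as np
import pytest

from starmaps import CountTable, SimulationSpec, make_template, simulate_pair


def build_table(counts, groups_per_sample, taxon_prefix="t", sample_prefix="s", level=None):
    """Small CountTable from a plain nested list and a list of group labels."""
    counts = np.asarray(counts)
    taxa = [f"{taxon_prefix}{i+1}" for i in range(counts.shape[0])]
    samples = [f"{sample_prefix}{j+1}" for j in range(counts.shape[1])]
    groups = {s: g for s, g in zip(samples, groups_per_sample)}
    return CountTable(taxa, samples, counts, groups, level=level)


@pytest.fixture(scope="session")
def small_template():
    """40-species parametric template shared by the cheaper simulation tests."""
    return make_template(n_species=40, seed=11)


@pytest.fixture(scope="session")
def separated_pair():
    """A strongly separated similar pair (log2FC = 4, N = 6).

    Uses a 100-species template: the taxon-matching null draws its power
    from the contrast between the observed matching and random matchings,
    which needs a taxon space much larger than the PC span.
    """
    template = make_template(n_species=100, seed=11)
    spec = SimulationSpec(
        n_per_group=6, log2fc_mean=4.0, template=template, seed=21, n_pairs=1
    )
    return simulate_pair(spec, "similar", seed=21)
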