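import numpy as np
import pytest

from sdpscan.alphabet import AA_INDEX, N_TYPES
from sdpscan.msa_io import ColumnProfile, GroupedAlignment, assign_groups, RawAlignment
from sdpscan.rate_model import load_rate_matrix
from sdpscan.synthetic import simulate_family


@pytest.fixture(scope="session")
def wag():
    return load_rate_matrix("wag")


def make_profile(freqs: dict[str, float], position=0, group="G1", n_counted=10):
    """ColumnProfile from a sparse {aa: frequency} map."""
    f = np.zeros(N_TYPES)
    for aa, v in freqs.items():
        f[AA_INDEX[aa]] = v
    return ColumnProfile(position=position, group=group, freq=f, n_counted=n_counted)


def make_grouped(columns_by_group: dict[str, list[str]]) -> GroupedAlignment:
    """GroupedAlignment from {group: [sequence strings]} (already aligned)."""
    ids, rows, gmap = [], [], {}
    for g, seqs in columns_by_group.items():
        for i, seq in enumerate(seqs):
            sid = f"{g}_{i}"
            ids.append(sid)
            rows.append(seq)
            gmap[sid] = g
    return assign_groups(RawAlignment(ids=tuple(ids), rows=tuple(rows)), gmap)


@pytest.fixture(scope="session")
def benchmark_family(wag):
    """The planted-signal benchmark family used across recovery tests."""
    return simulate_family(
        G=2,
        n_per_group=40,
        L=200,
        class_mixture={
            "determinant": 20,
            "discriminant": 20,
            "free": 80,
            "conserved_all": 80,
        },
        t_free=2.0,
        seed=7,
        model=wag,
    )


def random_distribution(rng, support=None):
    """Random distribution on the 20-letter alphabet (optionally on a support set)."""
    p = np.zeros(N_TYPES)
    if support is None:
        support = np.arange(N_TYPES)
    v = rng.random(len(support)) + 1e-3
    p[np.asarray(support)] = v / v.sum()
    return p
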