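"""Shared fixtures: generated genomes and panels (no on-disk data)."""

import pytest

from rrnscape import (
    AncestorSpec,
    EvolutionSpec,
    evolve_panel,
    make_ancestor,
    random_tree,
)
from rrnscape.skeleton import CoreOrder

#: scaled-down ancestor for unit tests that do not need the full skeleton
SMALL_SPEC = AncestorSpec(
    n_core=80,
    n_noncore_central=40,
    n_noncore_arm=90,
    n_trna=12,
    chromosome_length=600_000,
    seed=42,
)


@pytest.fixture(scope="session")
def ancestor_full():
    """Full-size ancestor (1017 core genes, 8 Mb) plus its core order."""
    genome, order = make_ancestor(AncestorSpec(seed=1))
    return genome, CoreOrder(tuple(order.group_id)), list(order.group_id)


@pytest.fixture(scope="session")
def ancestor_small():
    genome, order = make_ancestor(SMALL_SPEC)
    return genome, CoreOrder(tuple(order.group_id)), list(order.group_id)


@pytest.fixture(scope="session")
def small_panel(ancestor_small):
    """Six leaves evolved from the small ancestor (with ground truth)."""
    genome, order, core = ancestor_small
    tree = random_tree(6, seed=3)
    spec = EvolutionSpec(
        seed=7,
        inversion_rate=0.15,
        inversion_size_range=(80_000.0, 250_000.0),
        gene_gain_rate=2.0,
        gene_loss_rate=2.0,
    )
    panel, log = evolve_panel(genome, spec, tree)
    return panel, log, tree
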