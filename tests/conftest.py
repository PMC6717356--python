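"""Shared fixtures: synthetic genomes, trees, and alignments.

Everything is generated programmatically from fixed seeds; nothing binary is
read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from tm7pop import phylo
from tm7pop.mining import load_reference_panel, mine_genome
from tm7pop.mining.pipeline import query_panel_from_reference
from tm7pop.simulate import simulate_genome, simulate_two_pop


@pytest.fixture(scope="session")
def reference_panel():
    return load_reference_panel()


@pytest.fixture(scope="session")
def v1r_queries(reference_panel):
    return query_panel_from_reference(reference_panel, "v1r")


@pytest.fixture(scope="session")
def decoy_queries(reference_panel):
    return query_panel_from_reference(reference_panel, "decoy")


@pytest.fixture(scope="session")
def fixture_genome():
    """Genome with every classification branch represented."""
    return simulate_genome(
        seed=1, n_intact=3, n_partial=2, n_pseudo=4, n_short=1, n_decoys=2,
        scaffold_len=60_000,
    )


@pytest.fixture(scope="session")
def mined(fixture_genome, v1r_queries, reference_panel):
    genome, truth = fixture_genome
    candidates, log = mine_genome(genome, v1r_queries, reference=reference_panel)
    return candidates, log, truth


def random_ultrametric_newick(
    n_tips: int, seed: int, depth: float = 100.0
) -> tuple[str, list[str]]:
    """Deterministic random ultrametric binary tree; returns (newick, tips)."""
    rng = np.random.default_rng(seed)
    labels = [f"sp{i}" for i in range(n_tips)]

    def build(tips: list[str], height: float) -> str:
        if len(tips) == 1:
            return f"{tips[0]}:{height:.6f}"
        split = int(rng.integers(1, len(tips)))
        child_height = height * float(rng.uniform(0.3, 0.7))
        left = build(tips[:split], child_height)
        right = build(tips[split:], child_height)
        return f"({left},{right}):{height - child_height:.6f}"

    split = int(rng.integers(1, n_tips))
    child_height = depth * float(rng.uniform(0.3, 0.7))
    left = build(labels[:split], child_height)
    right = build(labels[split:], child_height)
    return f"({left},{right});", labels


@pytest.fixture(scope="session")
def tree24():
    """24-tip dated tree plus a lifestyle coding with 5 'subterranean' tips."""
    newick, tips = random_ultrametric_newick(24, seed=2024)
    tree = phylo.read_tree(newick)
    rng = np.random.default_rng(7)
    subterranean = set(rng.choice(tips, size=5, replace=False))
    lifestyle = {t: (0 if t in subterranean else 1) for t in tips}
    return tree, lifestyle


@pytest.fixture(scope="session")
def tree8():
    newick, _ = random_ultrametric_newick(8, seed=88)
    return phylo.read_tree(newick)


@pytest.fixture()
def twopop_panmictic():
    return simulate_two_pop(8, 8, 600, 5.0, 0.0, seed=5)[0]


@pytest.fixture()
def twopop_split():
    return simulate_two_pop(8, 8, 600, 5.0, 8.0, seed=6)[0]
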