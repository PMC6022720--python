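"""Shared fixtures: the packaged tree, a toy tree, and an independent
brute-force classification oracle used to cross-check the recursive
accumulator."""

from __future__ import annotations

import numpy as np
import pytest

from mitoclass import default_tree
from mitoclass.genotype_io import MISSING, SampleGenotypes
from mitoclass.tree_model import HaplogroupTree


@pytest.fixture(scope="session")
def tree() -> HaplogroupTree:
    return default_tree()


TOY_TREE_DOC = {
    "panel": [
        {"name": "MT100", "position": 100, "ancestral": "A", "derived": "G"},
        {"name": "MT200", "position": 200, "ancestral": "C", "derived": "T"},
        {"name": "MT300", "position": 300, "ancestral": "G", "derived": "A"},
        {"name": "MT400", "position": 400, "ancestral": "T", "derived": "C"},
    ],
    "nodes": [
        {"name": "ROOT", "parent": None, "lineage": "Macro", "genotypes": []},
        {"name": "P", "parent": "ROOT", "lineage": "Macro",
         "genotypes": [[100, "G"]]},
        {"name": "Q1", "parent": "P", "lineage": "European",
         "genotypes": [[200, "T"]]},
        {"name": "Q2", "parent": "P", "lineage": "African",
         "genotypes": [[300, "A"]]},
        # reversion: requires the ancestral state at 100 again
        {"name": "Q3", "parent": "P", "lineage": "European",
         "genotypes": [[400, "C"], [100, "A"]]},
    ],
}


@pytest.fixture()
def toy_tree() -> HaplogroupTree:
    return HaplogroupTree.from_dict(TOY_TREE_DOC)


def brute_force_classify(tree: HaplogroupTree, sample: SampleGenotypes) -> list[str]:
    """Independent oracle: evaluate every node's cumulative requirements
    (walking parent links directly, descendant allele overriding an
    ancestor's at the same position) and keep the maximal-depth satisfied
    non-root nodes, in tree-definition order."""
    satisfied: list[str] = []
    depths: dict[str, int] = {}
    for name, node in tree.nodes.items():
        chain = []
        cursor = node
        while cursor is not None:
            chain.append(cursor)
            cursor = cursor.parent
        depths[name] = len(chain) - 1
        cumulative: dict[int, str] = {}
        for ancestor in reversed(chain):  # root first, descendants override
            for position, allele in ancestor.required_genotypes:
                cumulative[position] = allele
        if all(sample.calls.get(p) == a for p, a in cumulative.items()):
            satisfied.append(name)
    non_root = [n for n in satisfied if n != tree.root.name]
    if not non_root:
        return []
    deepest = max(depths[n] for n in non_root)
    return [n for n in non_root if depths[n] == deepest]


@pytest.fixture(scope="session")
def oracle():
    return brute_force_classify


def random_sample(
    tree: HaplogroupTree,
    rng: np.random.Generator,
    sample_id: str = "R1",
    p_ancestral: float = 0.5,
    p_derived: float = 0.35,
) -> SampleGenotypes:
    """A stress-test genotype vector: each panel position independently
    ancestral, derived, or missing — deliberately off-manifold relative
    to real haplotypes so partial node satisfaction is exercised."""
    calls: dict[int, str | None] = {}
    for position in tree.panel_positions():
        snp = tree.panel[position]
        u = rng.random()
        if u < p_ancestral:
            calls[position] = snp.ancestral_allele
        elif u < p_ancestral + p_derived:
            calls[position] = snp.derived_allele
        else:
            calls[position] = MISSING
    return SampleGenotypes(family_id="RAND", individual_id=sample_id, calls=calls)
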