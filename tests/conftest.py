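"""Shared fixtures: toy trees, random instances and a small simulated bundle."""

import numpy as np
import pandas as pd
import pytest

from palinconv.model import (
    GenotypeMatrix,
    HaplogroupTree,
    Psv,
    PseudoGenotype,
    TreeNode,
)

HOM_ANC = PseudoGenotype.HOM_ANC
HET = PseudoGenotype.HET
HOM_DER = PseudoGenotype.HOM_DER
MISSING = PseudoGenotype.MISSING


def build_tree(newick: str, sample_map: dict) -> HaplogroupTree:
    return HaplogroupTree.from_newick(newick, sample_map)


def matrix_from(columns: dict, samples) -> GenotypeMatrix:
    """columns: psv_id -> {sample: PseudoGenotype}; absent cells MISSING."""
    df = pd.DataFrame(MISSING, index=list(samples), columns=list(columns), dtype=object)
    for psv_id, col in columns.items():
        for sample, state in col.items():
            df.at[sample, psv_id] = state
    return GenotypeMatrix(df)


@pytest.fixture
def psv_ga() -> Psv:
    """GC-informative PSV: G ancestral, A derived."""
    return Psv("PSV1", 1000, "G", "A")


@pytest.fixture
def fig_tree() -> HaplogroupTree:
    """Founder clade with three descendant haplogroups, one sample each,
    plus an outside haplogroup."""
    return build_tree(
        "((A,B,C)F,OUT)ROOT;",
        {"sA": "A", "sB": "B", "sC": "C", "sOut": "OUT"},
    )


def random_instance(rng: np.random.Generator, max_hg_leaves: int = 4):
    """Random rooted tree (<=8 tips total) and a random PSV column.

    Haplogroup leaves carry 1-2 samples; genotypes are drawn over all five
    codes so MISSING/EXCLUDED paths get exercised.
    """
    n_leaves = int(rng.integers(2, max_hg_leaves + 1))
    nodes = [TreeNode(f"L{i}") for i in range(n_leaves)]
    counter = 0
    while len(nodes) > 1:
        k = min(len(nodes), int(rng.integers(2, 4)))  # allow polytomies
        idx = rng.choice(len(nodes), size=k, replace=False)
        counter += 1
        parent = TreeNode(f"I{counter}")
        for i in sorted(idx, reverse=True):
            parent.add_child(nodes.pop(i))
        nodes.append(parent)
    root = nodes[0]
    root.name = "ROOT"
    sample_map = {}
    for leaf in [n for n in root.preorder() if n.is_leaf]:
        for j in range(int(rng.integers(1, 3))):
            if len(sample_map) >= 8:
                break
            sample_map[f"{leaf.name}s{j}"] = leaf.name
    tree = HaplogroupTree(root, sample_map)
    states = [HOM_ANC, HET, HOM_DER, MISSING, PseudoGenotype.EXCLUDED]
    probs = [0.3, 0.3, 0.25, 0.1, 0.05]
    column = {
        s: states[int(rng.choice(5, p=probs))] for s in tree.sample_map
    }
    return tree, column


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small simulated input bundle written to disk once per session."""
    from palinconv.simulate import SimParams, write_bundle

    outdir = tmp_path_factory.mktemp("bundle")
    params = SimParams(
        seed=11,
        n_haplogroups=12,
        samples_per_haplogroup=3,
        total_generations=120_000,
        arm_length=4000,
        spacer_length=2000,
    )
    write_bundle(outdir, params)
    return outdir, params
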