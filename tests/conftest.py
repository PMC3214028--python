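from __future__ import annotations

import numpy as np
import pytest

from barcoderich.io_formats import LocusAlignment
from barcoderich.njtree import BarcodeTree, Node

BASES = "ACGT"


def make_alignment(rows: dict[str, str], locus_id: str = "locus") -> LocusAlignment:
    return LocusAlignment(
        locus_id=locus_id,
        sample_ids=tuple(rows),
        rows=tuple(rows.values()),
    )


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, length))


def mutate(seq: str, positions: list[int], rng: np.random.Generator) -> str:
    chars = list(seq)
    for pos in positions:
        chars[pos] = BASES[(BASES.index(chars[pos]) + int(rng.integers(1, 4))) % 4]
    return "".join(chars)


def random_binary_tree(
    n_tips: int, rng: np.random.Generator, low: float = 0.05, high: float = 0.3
) -> BarcodeTree:
    """Random unrooted binary tree with positive lengths, built by attaching
    tips to random edges of a growing tree."""
    names = [f"t{i}" for i in range(n_tips)]

    def L() -> float:
        return float(rng.uniform(low, high))

    root = Node()
    for name in names[:3]:
        root.add_child(Node(name=name, length=L()))
    tree = BarcodeTree(root)
    for name in names[3:]:
        candidates = [n for n in tree.preorder() if n is not root]
        target = candidates[int(rng.integers(len(candidates)))]
        parent = next(p for p in tree.preorder() if target in p.children)
        mid = Node(length=float(rng.uniform(0, target.length)))
        target.length -= mid.length
        parent.children[parent.children.index(target)] = mid
        mid.add_child(target)
        mid.add_child(Node(name=name, length=L()))
        tree.invalidate()
    tree.invalidate()
    return tree


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260904)
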