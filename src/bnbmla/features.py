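"""Structural relevance features of a single DAG.

Given a network structure, a predictor X and a target Y, the dependency
types are purely graphical:

* direct relevance (DCR): an edge between X and Y in either direction;
* transitive relevance (TCR): a directed path of length >= 1 between X
  and Y (so a direct edge also counts as transitive; the ``mediated_only``
  flag isolates paths of length >= 2 with no direct edge);
* confounded relevance (ConfR): a proper common ancestor Z (directed
  paths of length >= 1 from Z to both X and Y, Z distinct from both);
* association: DCR or TCR or ConfR;
* pure interactionist relevance (PIR): X and Y share a child and have no
  direct edge — the epistasis-like, v-structure signal;
* strong relevance (SR): DCR or PIR, which is exactly membership of X in
  the Markov blanket of Y.

PIR is defined disjointly from DCR so that P(SR) = P(DCR) + P(PIR)
additively when averaged over structures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .scoring import DAGStructure

__all__ = [
    "PairwiseFeatureRecord",
    "MultiTargetFeatureRecord",
    "descendants_matrix",
    "markov_blanket",
    "markov_blanket_of_set",
    "pairwise_features",
    "multi_target_features",
]


@dataclass(frozen=True)
class PairwiseFeatureRecord:
    """Dependency-type indicators for an ordered pair (X, target Y)."""

    dcr: bool
    tcr: bool
    confr: bool
    assoc: bool
    pir: bool
    sr: bool
    mediated_only: bool


@dataclass(frozen=True)
class MultiTargetFeatureRecord:
    """Strong-relevance decomposition of X against a target set.

    ``exist[y]`` — SR to target y; ``only[y]`` — SR to y and to no other
    target; ``other_than[y]`` — SR to at least one target besides y;
    ``mt`` — SR to one or more targets; ``edge_to_any`` — a direct edge to
    some target.
    """

    targets: tuple[int, ...]
    exist: tuple[bool, ...]
    only: tuple[bool, ...]
    other_than: tuple[bool, ...]
    mt: bool
    edge_to_any: bool


def descendants_matrix(adj: np.ndarray) -> np.ndarray:
    """Strict reachability: R[i, j] iff a directed path i -> ... -> j (>=1 edge)."""
    n = adj.shape[0]
    reach = adj.astype(np.uint8) | np.eye(n, dtype=np.uint8)
    while True:
        nxt = ((reach @ reach) > 0).astype(np.uint8)
        if np.array_equal(nxt, reach):
            break
        reach = nxt
    out = reach.astype(bool)
    np.fill_diagonal(out, False)
    return out


def markov_blanket(g: DAGStructure, y: int) -> set[int]:
    """Parents, children and the children's other parents of ``y``."""
    adj = g.adj
    parents = set(np.flatnonzero(adj[:, y]))
    children = np.flatnonzero(adj[y, :])
    spouses = set()
    for c in children:
        spouses.update(np.flatnonzero(adj[:, c]))
    mb = parents | set(children) | spouses
    mb.discard(y)
    return mb


def markov_blanket_of_set(g: DAGStructure, targets: Iterable[int]) -> set[int]:
    """Union of the members' blankets minus the target set itself."""
    targets = set(targets)
    if not targets:
        raise ValueError("target set must be nonempty")
    mb: set[int] = set()
    for y in targets:
        mb |= markov_blanket(g, y)
    return mb - targets


def pairwise_features(
    g: DAGStructure, x: int, y: int, desc: np.ndarray | None = None
) -> PairwiseFeatureRecord:
    """Evaluate all dependency-type indicators for (x, y) on one structure."""
    if x == y:
        raise ValueError("x and y must differ")
    adj = g.adj
    if desc is None:
        desc = descendants_matrix(adj)
    dcr = bool(adj[x, y] or adj[y, x])
    tcr = bool(desc[x, y] or desc[y, x])
    # proper common ancestor: z with directed paths to both x and y
    confr = bool((desc[:, x] & desc[:, y]).any())
    common_child = bool((adj[x, :] & adj[y, :]).any())
    pir = common_child and not dcr
    assoc = dcr or tcr or confr
    sr = dcr or pir
    mediated_only = tcr and not dcr
    return PairwiseFeatureRecord(dcr, tcr, confr, assoc, pir, sr, mediated_only)


def multi_target_features(
    g: DAGStructure, x: int, targets: Sequence[int], desc: np.ndarray | None = None
) -> MultiTargetFeatureRecord:
    targets = tuple(targets)
    if x in targets:
        raise ValueError("x must not be a target")
    if desc is None:
        desc = descendants_matrix(g.adj)
    exist = tuple(pairwise_features(g, x, y, desc).sr for y in targets)
    only = tuple(
        e and not any(exist[j] for j in range(len(targets)) if j != i)
        for i, e in enumerate(exist)
    )
    other_than = tuple(
        any(exist[j] for j in range(len(targets)) if j != i)
        for i in range(len(targets))
    )
    mt = any(exist)
    edge_to_any = bool(any(g.adj[x, y] or g.adj[y, x] for y in targets))
    return MultiTargetFeatureRecord(targets, exist, only, other_than, mt, edge_to_any)
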