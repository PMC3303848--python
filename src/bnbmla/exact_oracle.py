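"""Exact structure posteriors by exhaustive DAG enumeration (small n).

Averaging a structural feature over the full posterior requires summing
over all labeled DAGs, which is super-exponential in the number of
variables; on domains of up to six variables the sum is tractable and
serves as ground truth for the sampler.  Enumeration assigns one of three
states (none, forward, backward) to each unordered node pair depth-first,
pruning cycles early through an incrementally maintained reachability
matrix, so graphs are produced one at a time without materializing the
space.

The oracle deliberately shares :mod:`bnbmla.scoring` with the sampler:
what it isolates and tests is the Monte Carlo approximation, not the
score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np
from scipy.special import logsumexp

from .features import (
    descendants_matrix,
    markov_blanket,
    markov_blanket_of_set,
    multi_target_features,
    pairwise_features,
)
from .scoring import DAGStructure, FamilyCountCache, ScoreConfig, dag_log_score

__all__ = ["enumerate_dags", "exact_feature_posterior", "exact_summary",
           "EnumerationResult"]

_MAX_ENUM_VARS = 6


def enumerate_dags(n: int, max_parents: int | None = None) -> Iterator[DAGStructure]:
    """Yield every labeled DAG on ``n`` nodes (respecting the parent limit).

    Counts without a parent limit follow the known sequence
    1, 3, 25, 543, 29281, ... for n = 2, 3, 4, 5, ...
    """
    if n > _MAX_ENUM_VARS:
        raise ValueError(f"enumeration supported for n <= {_MAX_ENUM_VARS}")
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    adj = np.zeros((n, n), dtype=bool)
    desc = np.eye(n, dtype=bool)  # reflexive reachability
    indeg = np.zeros(n, dtype=np.int64)

    def rec(k: int) -> Iterator[DAGStructure]:
        if k == len(pairs):
            yield DAGStructure(n, adj.copy())
            return
        nonlocal desc
        i, j = pairs[k]
        yield from rec(k + 1)  # pair unconnected
        for u, v in ((i, j), (j, i)):
            if desc[v, u]:
                continue  # would close a cycle
            if max_parents is not None and indeg[v] >= max_parents:
                continue
            saved = desc
            adj[u, v] = True
            indeg[v] += 1
            desc = desc | np.outer(desc[:, u], desc[v, :])
            yield from rec(k + 1)
            adj[u, v] = False
            indeg[v] -= 1
            desc = saved

    yield from rec(0)


def _posterior_weights(dags: Sequence[DAGStructure], cache: FamilyCountCache):
    logs = np.array([dag_log_score(g, None, cache=cache) for g in dags])
    return np.exp(logs - logsumexp(logs))


def exact_feature_posterior(
    data,
    feature: Callable[[DAGStructure], bool],
    score_cfg: ScoreConfig | None = None,
    max_parents: int | None = None,
) -> float:
    """Posterior probability of an arbitrary structural feature, exactly."""
    cache = FamilyCountCache(data, score_cfg)
    if max_parents is None:
        max_parents = cache.cfg.max_parents
    dags = list(enumerate_dags(cache.n_vars, max_parents))
    w = _posterior_weights(dags, cache)
    return float(sum(wi for g, wi in zip(dags, w) if feature(g)))


@dataclass
class EnumerationResult:
    """Exact posteriors from one exhaustive enumeration.

    ``pairwise[y]`` maps feature name -> length-n array of posteriors of
    that feature for (x, y); entries at x == y are 0.  ``mbs[y]`` and
    ``mbs_of_set`` map blanket sets (frozensets) to exact posterior mass.
    """

    n_dags: int
    edge_posterior: np.ndarray
    pairwise: dict[int, dict[str, np.ndarray]]
    mbs: dict[int, dict[frozenset, float]]
    mbs_of_set: dict[frozenset, float] | None = None
    multi_target: dict[str, np.ndarray] = field(default_factory=dict)


_PAIR_FEATURES = ("dcr", "tcr", "confr", "assoc", "pir", "sr", "mediated_only")


def exact_summary(
    data,
    targets: Sequence[int],
    score_cfg: ScoreConfig | None = None,
    max_parents: int | None = None,
) -> EnumerationResult:
    """Every feature the analysis reports, computed by exact summation."""
    cache = FamilyCountCache(data, score_cfg)
    if max_parents is None:
        max_parents = cache.cfg.max_parents
    n = cache.n_vars
    targets = tuple(targets)
    dags = list(enumerate_dags(n, max_parents))
    w = _posterior_weights(dags, cache)

    edge_post = np.zeros((n, n))
    pair = {y: {f: np.zeros(n) for f in _PAIR_FEATURES} for y in targets}
    mbs: dict[int, dict[frozenset, float]] = {y: {} for y in targets}
    mbs_of_set: dict[frozenset, float] = {}
    predictors = [x for x in range(n) if x not in targets]
    mt = {k: np.zeros(n) for k in ("mt", "edge_to_any")}
    mt.update({f"exist_{y}": np.zeros(n) for y in targets})
    mt.update({f"only_{y}": np.zeros(n) for y in targets})
    mt.update({f"other_than_{y}": np.zeros(n) for y in targets})

    for g, wi in zip(dags, w):
        edge_post += wi * g.adj
        desc = descendants_matrix(g.adj)
        for y in targets:
            for x in range(n):
                if x == y:
                    continue
                rec = pairwise_features(g, x, y, desc)
                for f in _PAIR_FEATURES:
                    pair[y][f][x] += wi * getattr(rec, f)
            s = frozenset(markov_blanket(g, y))
            mbs[y][s] = mbs[y].get(s, 0.0) + wi
        if len(targets) > 1:
            s = frozenset(markov_blanket_of_set(g, targets))
            mbs_of_set[s] = mbs_of_set.get(s, 0.0) + wi
        for x in predictors:
            rec = multi_target_features(g, x, targets, desc)
            mt["mt"][x] += wi * rec.mt
            mt["edge_to_any"][x] += wi * rec.edge_to_any
            for i, y in enumerate(targets):
                mt[f"exist_{y}"][x] += wi * rec.exist[i]
                mt[f"only_{y}"][x] += wi * rec.only[i]
                mt[f"other_than_{y}"][x] += wi * rec.other_than[i]

    return EnumerationResult(
        n_dags=len(dags),
        edge_posterior=edge_post,
        pairwise=pair,
        mbs=mbs,
        mbs_of_set=mbs_of_set if len(targets) > 1 else None,
        multi_target=mt,
    )
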